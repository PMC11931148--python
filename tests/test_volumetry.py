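import numpy as np
import pandas as pd
import pytest

from brainquant.imaging_core import (
    Hemisphere,
    LabelEntry,
    LabelMap3D,
    LabelScheme,
    Tissue,
    voxel_volume_ml,
)
from brainquant.volumetry import (
    AsymmetryDenominator,
    HemisphereAssignment,
    atlas_postprocess,
    lesion_free_volumes,
    region_volumes,
    relative_asymmetry,
    split_hemispheres,
    validate_report,
)


def simple_scheme():
    return LabelScheme(entries=(
        LabelEntry(1, "a", Tissue.GM),
        LabelEntry(2, "b", Tissue.WM),
    ))


class TestRegionVolumes:
    def test_thousand_voxels_one_ml(self):
        labels = np.zeros((10, 10, 11), dtype=np.int16)
        labels.ravel()[:1000] = 1
        lmap = LabelMap3D(labels, np.eye(4), simple_scheme())
        assert region_volumes(lmap)["a"] == pytest.approx(1.0)

    def test_sum_equals_foreground(self, small_phantom):
        vols = region_volumes(small_phantom.labels)
        vox = voxel_volume_ml(small_phantom.labels)
        fg = (small_phantom.labels.labels > 0).sum() * vox
        assert sum(vols.values()) == pytest.approx(fg, abs=1e-9)

    def test_phantom_thalamus_within_5pct_of_analytic(self):
        from brainquant.phantom import PhantomConfig, generate_phantom
        ph = generate_phantom(PhantomConfig(shape=(128, 128, 128),
                                            spacing_mm=(1.0, 1.0, 1.0), seed=0))
        vols = region_volumes(ph.labels)
        assert vols["thalamus_left"] == pytest.approx(
            ph.analytic_volumes_ml["thalamus_left"], rel=0.05)


class TestLesionFreeVolumes:
    def test_empty_mask(self, small_phantom):
        report = lesion_free_volumes(small_phantom.labels,
                                     np.zeros(small_phantom.labels.shape, bool))
        assert (report["lesion_ml"] == 0).all()
        assert np.allclose(report["lesion_free_ml"], report["total_ml"])

    def test_single_region_arithmetic(self):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels[:5] = 1   # 500 voxels of 'a'
        labels[5:] = 2
        affine = np.diag([2.0, 2.0, 2.5, 1.0])  # 0.01 mL per voxel
        lmap = LabelMap3D(labels, affine, simple_scheme())
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[:2] = True  # 200 lesion voxels, all inside region a
        report = lesion_free_volumes(lmap, mask).set_index("region")
        assert report.loc["a", "total_ml"] == pytest.approx(5.0)
        assert report.loc["a", "lesion_ml"] == pytest.approx(2.0)
        assert report.loc["a", "lesion_free_ml"] == pytest.approx(3.0)
        assert report.loc["b", "lesion_free_ml"] == pytest.approx(
            report.loc["b", "total_ml"])

    def test_matches_brute_force_intersections(self, small_phantom):
        report = lesion_free_volumes(
            small_phantom.labels,
            small_phantom.lesion_masks).set_index("region")
        union = small_phantom.union_lesion_mask()
        vox = voxel_volume_ml(small_phantom.labels)
        labels = small_phantom.labels.labels
        for e in small_phantom.scheme.entries:
            expected = int(((labels == e.id) & union).sum()) * vox
            assert report.loc[e.name, "lesion_ml"] == pytest.approx(
                expected, abs=1e-12)

    def test_background_lesion_warns(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[0, 0, 0] = 1
        lmap = LabelMap3D(labels, np.eye(4), simple_scheme())
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[3, 3, 3] = True  # background voxel
        with pytest.warns(UserWarning, match="background"):
            report = lesion_free_volumes(lmap, mask)
        assert (report["lesion_ml"] == 0).all()

    def test_conservation_validated(self):
        bad = pd.DataFrame([{"region": "x", "hemisphere": "NA",
                             "total_ml": 1.0, "lesion_ml": 0.2,
                             "lesion_free_ml": 0.9}])
        with pytest.raises(ValueError, match="conservation"):
            validate_report(bad)


class TestSplitHemispheres:
    def test_symmetric_phantom_balanced(self, clean_phantom):
        split = split_hemispheres(clean_phantom.labels)
        vols = region_volumes(split)
        for base in ("csf", "cortical_gm", "wm"):
            left = vols[f"{base}_left"]
            right = vols[f"{base}_right"]
            assert abs(left - right) <= 0.01 * max(left, right)

    def test_positive_x_is_right(self):
        scheme = simple_scheme()
        labels = np.ones((1, 1, 1), dtype=np.int16)
        affine = np.eye(4)
        affine[0, 3] = 3.2  # voxel centre world x = +3.2
        split = split_hemispheres(LabelMap3D(labels, affine, scheme))
        entry = split.scheme[int(split.labels[0, 0, 0])]
        assert entry.hemisphere is Hemisphere.RIGHT

    def test_degenerate_plane_all_midline(self):
        scheme = simple_scheme()
        labels = np.ones((1, 4, 4), dtype=np.int16)
        affine = np.eye(4)  # x index 0 -> world x = 0 exactly
        split = split_hemispheres(LabelMap3D(labels, affine, scheme))
        for v in np.unique(split.labels):
            assert split.scheme[int(v)].hemisphere is Hemisphere.MIDLINE

    def test_pretagged_keep_tag(self, clean_phantom):
        split = split_hemispheres(clean_phantom.labels)
        tid = clean_phantom.scheme.id_of("thalamus_left")
        assert split.scheme[tid].hemisphere is Hemisphere.LEFT
        assert np.array_equal(split.labels == tid,
                              clean_phantom.labels.labels == tid)

    def test_split_commutes_with_volumes(self, small_phantom):
        unsplit = region_volumes(small_phantom.labels)
        split = split_hemispheres(small_phantom.labels)
        vols = region_volumes(split)
        for base in ("csf", "cortical_gm", "wm"):
            total = sum(v for k, v in vols.items() if k.startswith(base))
            assert total == pytest.approx(unsplit[base], abs=1e-9)


def report_from(volumes: dict[tuple[str, str], float]) -> pd.DataFrame:
    rows = [{"region": f"{r}_{h.lower()}", "hemisphere": h, "total_ml": v,
             "lesion_ml": 0.0, "lesion_free_ml": v}
            for (r, h), v in volumes.items()]
    return pd.DataFrame(rows)


class TestRelativeAsymmetry:
    assignment = HemisphereAssignment(Hemisphere.LEFT)  # affected = RIGHT

    def test_equal_volumes_zero(self):
        report = report_from({("thal", "LEFT"): 2.0, ("thal", "RIGHT"): 2.0})
        asym = relative_asymmetry(report, self.assignment)
        assert asym["thal"] == pytest.approx(0.0)

    def test_shrink_factor_closed_form(self):
        report = report_from({("thal", "LEFT"): 1.0, ("thal", "RIGHT"): 0.512})
        asym = relative_asymmetry(report, self.assignment)
        assert asym["thal"] == pytest.approx(100 * (0.512 - 1) / 0.756, abs=0.01)
        assert asym["thal"] == pytest.approx(-64.55, abs=0.01)

    def test_antisymmetric_under_side_swap(self):
        report = report_from({("thal", "LEFT"): 1.3, ("thal", "RIGHT"): 0.7})
        a1 = relative_asymmetry(report, HemisphereAssignment(Hemisphere.LEFT))
        a2 = relative_asymmetry(report, HemisphereAssignment(Hemisphere.RIGHT))
        assert a1["thal"] == pytest.approx(-a2["thal"])

    def test_both_zero_missing(self):
        report = report_from({("thal", "LEFT"): 0.0, ("thal", "RIGHT"): 0.0})
        asym = relative_asymmetry(report, self.assignment)
        assert np.isnan(asym["thal"])

    def test_missing_hemisphere_errors(self):
        report = report_from({("thal", "LEFT"): 1.0})
        with pytest.raises(ValueError, match="thal"):
            relative_asymmetry(report, self.assignment)

    def test_less_affected_denominator(self):
        report = report_from({("thal", "LEFT"): 1.0, ("thal", "RIGHT"): 0.512})
        asym = relative_asymmetry(report, self.assignment,
                                  denominator=AsymmetryDenominator.LESS_AFFECTED)
        assert asym["thal"] == pytest.approx(-48.8, abs=0.01)

    def test_shrunk_phantom_all_negative(self, clean_phantom):
        from brainquant.phantom import shrink_hemisphere
        shrunk = shrink_hemisphere(clean_phantom, Hemisphere.RIGHT, 0.8)
        split = split_hemispheres(shrunk.labels)
        report = lesion_free_volumes(split, np.zeros(split.shape, bool))
        lateral = report[report["hemisphere"].isin(["LEFT", "RIGHT"])]
        # clinical side LEFT -> affected hemisphere RIGHT (the shrunk one)
        asym = relative_asymmetry(lateral, HemisphereAssignment(Hemisphere.LEFT))
        shrunk_regions = [r for r in asym.index
                          if r in ("thalamus", "caudate", "putamen", "pallidum")]
        assert shrunk_regions
        for region in shrunk_regions:
            assert asym[region] < 0


class TestAtlasPostprocess:
    def test_wm_voxel_gets_lobar_id(self, clean_phantom):
        labels = clean_phantom.labels.labels
        out = atlas_postprocess(labels == 3, labels == 2, clean_phantom.atlas)
        atlas = clean_phantom.atlas
        frontal_left = atlas.labels == atlas.scheme.id_of("frontal_left")
        target = (labels == 3) & frontal_left
        assert target.any()
        wm_fl = out.labels == out.scheme.id_of("wm_frontal_left")
        assert np.array_equal(wm_fl, target)

    def test_partition_conserves_wm_volume(self, clean_phantom):
        labels = clean_phantom.labels.labels
        wm_mask = labels == 3
        out = atlas_postprocess(wm_mask, labels == 2, clean_phantom.atlas)
        wm_ids = [e.id for e in out.scheme.entries if e.name.startswith("wm_")]
        assert np.isin(out.labels[wm_mask], wm_ids).all()
        assert int(np.isin(out.labels, wm_ids).sum()) == int(wm_mask.sum())

    def test_plic_counts_match_brute_force(self, clean_phantom):
        labels = clean_phantom.labels.labels
        wm_mask = labels == 3
        atlas = clean_phantom.atlas
        out = atlas_postprocess(wm_mask, labels == 2, atlas)
        for side in ("left", "right"):
            box = atlas.labels == atlas.scheme.id_of(f"plic_{side}")
            expected = int((wm_mask & box).sum())
            got = int((out.labels == out.scheme.id_of(f"wm_plic_{side}")).sum())
            assert got == expected

    def test_overlapping_masks_rejected(self, clean_phantom):
        labels = clean_phantom.labels.labels
        with pytest.raises(ValueError, match="overlap"):
            atlas_postprocess(labels == 3, labels == 3, clean_phantom.atlas)


class TestHemisphereAssignment:
    def test_contralateral(self):
        assert (HemisphereAssignment(Hemisphere.LEFT).affected_hemisphere
                is Hemisphere.RIGHT)
        assert (HemisphereAssignment(Hemisphere.RIGHT).affected_hemisphere
                is Hemisphere.LEFT)

    def test_invalid_side(self):
        with pytest.raises(ValueError):
            HemisphereAssignment(Hemisphere.MIDLINE)
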