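"""Pipeline orchestration: wires normalization, segmentation (trained models
or oracle label inputs), atlas postprocessing, volumetry and asymmetry into a
single seeded run that writes every intermediate plus a provenance manifest.

All computation lives in the stage modules; this module only sequences them
and handles I/O, so any stage can be re-run in isolation from the manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .imaging_core import (
    Hemisphere,
    LabelEntry,
    LabelMap3D,
    LabelScheme,
    Modality,
    Tissue,
    read_label_map,
    read_volume,
    write_volume,
)
from .preprocess import NormalizationParams, normalize
from .unet_seg import load_model, predict_labels, tissue_onehot
from .volumetry import (
    HemisphereAssignment,
    lesion_free_volumes,
    relative_asymmetry,
    split_hemispheres,
)

__all__ = ["PipelineError", "run_pipeline"]

_FLOAT_FMT = "%.9f"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str) -> None:
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _norm_params(block: dict | None) -> NormalizationParams:
    block = dict(block or {})
    if "spread_range" in block:
        block["spread_range"] = tuple(block["spread_range"])
    return NormalizationParams(**block)


def _load_config(config: dict | str | Path) -> tuple[dict, str]:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        return yaml.safe_load(text), text
    text = yaml.safe_dump(config, sort_keys=True)
    return config, text


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the quantification pipeline described by ``config`` (dict or
    YAML path) into ``out_dir``; returns the output directory.

    Required config keys: ``inputs.t1``, ``scheme`` and a ``structural``
    block with either ``labels`` (oracle segmentation path) or ``model``
    (checkpoint directory).  Optional: ``inputs.flair``, a ``lesion`` block
    (``masks`` list or ``model``), ``normalization``, ``volumetry.clinical_side``
    and ``seed``.
    """
    cfg, cfg_text = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": int(cfg.get("seed", 0)),
        "versions": {"brainquant": __version__, "numpy": np.__version__},
        "stages": {},
    }

    # -- inputs ----------------------------------------------------------
    inputs = cfg.get("inputs") or {}
    t1_path = inputs.get("t1")
    if not t1_path:
        raise PipelineError("inputs", "missing required input 't1'")
    try:
        t1 = read_volume(t1_path, Modality.T1)
    except Exception as exc:
        raise PipelineError("inputs", f"cannot read T1 {t1_path}: {exc}") from exc
    flair = None
    if inputs.get("flair"):
        try:
            flair = read_volume(inputs["flair"], Modality.FLAIR)
        except Exception as exc:
            raise PipelineError(
                "inputs", f"cannot read FLAIR {inputs['flair']}: {exc}") from exc
    scheme_path = cfg.get("scheme")
    if not scheme_path:
        raise PipelineError("inputs", "missing label 'scheme' path")
    scheme = LabelScheme.from_yaml(scheme_path)

    # -- normalization ---------------------------------------------------
    try:
        params = _norm_params(cfg.get("normalization"))
        t1_norm = normalize(t1, params)
        flair_norm = normalize(flair, params) if flair is not None else None
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc
    write_volume(t1_norm, out / "t1_norm.nii.gz")
    manifest["stages"]["normalize"] = {"t1": str(t1_path),
                                       "out": "t1_norm.nii.gz"}
    if flair_norm is not None:
        write_volume(flair_norm, out / "flair_norm.nii.gz")
        manifest["stages"]["normalize"]["flair"] = str(inputs["flair"])

    # -- structural segmentation ----------------------------------------
    structural = cfg.get("structural") or {}
    try:
        if "labels" in structural:
            labels = read_label_map(structural["labels"], scheme)
            manifest["stages"]["structural"] = {"mode": "oracle",
                                                "labels": str(structural["labels"])}
        elif "model" in structural:
            params_w, model_cfg = load_model(structural["model"])
            labels = predict_labels(params_w, t1_norm.data, model_cfg,
                                    affine=t1.affine, scheme=scheme)
            manifest["stages"]["structural"] = {"mode": "model",
                                                "model": str(structural["model"])}
        else:
            raise ValueError("structural block needs 'labels' or 'model'")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("structural", str(exc)) from exc
    write_volume(labels, out / "structural_labels.nii.gz")

    # -- lesion segmentation --------------------------------------------
    lesion_cfg = cfg.get("lesion") or {}
    lesion_union = np.zeros(labels.shape, dtype=bool)
    if lesion_cfg:
        try:
            if "masks" in lesion_cfg:
                for mpath in lesion_cfg["masks"]:
                    mask_map = read_volume(mpath)
                    lesion_union |= np.asarray(mask_map.data) > 0
                manifest["stages"]["lesion"] = {
                    "mode": "masks", "masks": [str(p) for p in lesion_cfg["masks"]]}
            elif "model" in lesion_cfg:
                if flair_norm is None:
                    raise ValueError(
                        "lesion segmentation model requires T1, FLAIR and "
                        "tissue channels: FLAIR input is missing")
                params_w, model_cfg = load_model(lesion_cfg["model"])
                tissues = tissue_onehot(labels.labels, [
                    sorted(scheme.ids_for_tissue(Tissue.CSF)),
                    sorted(scheme.ids_for_tissue(Tissue.GM)),
                    sorted(scheme.ids_for_tissue(Tissue.WM)),
                ])
                channels = np.concatenate(
                    [t1_norm.data[None], flair_norm.data[None], tissues])
                lesion_labels = predict_labels(params_w, channels, model_cfg)
                lesion_union = np.asarray(lesion_labels) > 0
                manifest["stages"]["lesion"] = {"mode": "model",
                                                "model": str(lesion_cfg["model"])}
            else:
                raise ValueError("lesion block needs 'masks' or 'model'")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("lesion", str(exc)) from exc
        lesion_map = LabelMap3D(
            lesion_union.astype(np.int16), labels.affine,
            LabelScheme((LabelEntry(1, "lesion", Tissue.LESION),)))
        write_volume(lesion_map, out / "lesion_union.nii.gz")

    # -- volumetry -------------------------------------------------------
    vol_cfg = cfg.get("volumetry") or {}
    try:
        split = split_hemispheres(labels)
        report = lesion_free_volumes(split, lesion_union)
    except Exception as exc:
        raise PipelineError("volumetry", str(exc)) from exc
    report.to_csv(out / "volume_report.csv", index=False, float_format=_FLOAT_FMT)
    report.to_json(out / "volume_report.json", orient="records", indent=2)
    manifest["stages"]["volumetry"] = {"report": "volume_report.csv"}

    side = vol_cfg.get("clinical_side")
    if side:
        try:
            assignment = HemisphereAssignment(Hemisphere[side.upper()])
            lateral = report[report["hemisphere"].isin(["LEFT", "RIGHT"])]
            asym = relative_asymmetry(lateral, assignment)
        except Exception as exc:
            raise PipelineError("asymmetry", str(exc)) from exc
        asym.to_csv(out / "asymmetry.csv", header=True, float_format=_FLOAT_FMT)
        manifest["stages"]["asymmetry"] = {
            "clinical_side": side,
            "affected_hemisphere": assignment.affected_hemisphere.value,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
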