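import numpy as np
import pandas as pd
import pytest

from brainquant.clinical_stats import (
    bootstrap_ci,
    icc_average_random_raters,
    mann_whitney_u,
    significance_stars,
    spearman_r,
    structure_function_table,
    wilcoxon_signed_rank,
)
from conftest import icc_oracle, mwu_oracle, spearman_oracle, wilcoxon_oracle


class TestSpearman:
    def test_monotone_increasing(self):
        x = np.arange(10.0)
        assert spearman_r(x, np.exp(x)) == pytest.approx(1.0)

    def test_negated(self):
        x = np.arange(8.0)
        assert spearman_r(x, -x) == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        rng = np.random.default_rng(123)
        x = rng.integers(0, 4, size=10).astype(float)
        y = rng.integers(0, 4, size=10).astype(float)
        if np.unique(x).size < 2:
            x[0] += 1
        if np.unique(y).size < 2:
            y[0] += 1
        assert spearman_r(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert spearman_r(np.exp(x), y ** 3) == pytest.approx(
            spearman_r(x, y), abs=1e-12)

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(ValueError):
            spearman_r([1.0, 2.0], [1.0, 2.0])


class TestBootstrap:
    def test_constant_statistic_degenerate_interval(self):
        data = np.arange(10.0)
        low, high = bootstrap_ci(lambda rows: 4.2, data, n_boot=100, seed=0)
        assert (low, high) == (4.2, 4.2)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 2))
        stat = lambda rows: spearman_r(rows[:, 0], rows[:, 1])
        ci1 = bootstrap_ci(stat, data, n_boot=500, seed=9)
        ci2 = bootstrap_ci(stat, data, n_boot=500, seed=9)
        assert ci1 == ci2

    def test_mostly_undefined_errors(self):
        def bad(rows):
            raise ValueError("nope")
        with pytest.raises(ValueError, match="undefined"):
            bootstrap_ci(bad, np.arange(5.0), n_boot=50, seed=0)

    def test_convergence_10k_vs_40k(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30) * 0.8
        data = np.column_stack([x, y])
        stat = lambda rows: spearman_r(rows[:, 0], rows[:, 1])
        lo1, hi1 = bootstrap_ci(stat, data, n_boot=10000, seed=1)
        lo2, hi2 = bootstrap_ci(stat, data, n_boot=40000, seed=2)
        assert abs(lo1 - lo2) < 0.01 and abs(hi1 - hi2) < 0.01


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [10.0, 11.0, 12.0, 13.0])
        assert u == 0.0
        assert p <= 0.1

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(x, list(x))
        assert u == pytest.approx(len(x) * len(x) / 2)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(45)
        x = rng.normal(size=4)
        y = rng.normal(loc=0.8, size=5)
        u, p = mann_whitney_u(x, y)
        u_ref, p_ref = mwu_oracle(x, y)
        assert u == pytest.approx(u_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(46)
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        u1, p1 = mann_whitney_u(x, y)
        u2, p2 = mann_whitney_u(y, x)
        assert u1 == pytest.approx(u2)
        assert p1 == pytest.approx(p2)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(47)
        x = rng.normal(size=30)
        y = rng.normal(loc=1.0, size=35)
        u, p = mann_whitney_u(x, y)
        from scipy import stats as sps
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, abs=0.02)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])

    def test_exact_type_i_error_conservative(self):
        # over the exhaustive null enumeration, P(p <= 0.05) <= 0.05
        import itertools
        values = np.arange(9.0)  # tie-free pooled sample, n=(4,5)
        rejections = 0
        total = 0
        for combo in itertools.combinations(range(9), 4):
            sel = np.zeros(9, dtype=bool)
            sel[list(combo)] = True
            _, p = mann_whitney_u(values[sel], values[~sel])
            rejections += p <= 0.05
            total += 1
        assert rejections / total <= 0.05


class TestWilcoxon:
    def test_all_positive(self):
        w, _ = wilcoxon_signed_rank([1.0, 2.0, 3.5])
        assert w == 0.0

    def test_antisymmetric_differences(self):
        d = [1.0, -1.5, 1.5, -1.0, 2.0, -2.5, 2.5, -2.0]
        w, _ = wilcoxon_signed_rank(d)
        ranks_total = 8 * 9 / 2
        assert w == pytest.approx(ranks_total / 2)

    def test_exact_matches_sign_flip_oracle(self):
        rng = np.random.default_rng(77)
        d = rng.normal(loc=0.5, size=8)
        w, p = wilcoxon_signed_rank(d)
        w_ref, p_ref = wilcoxon_oracle(d)
        assert w == pytest.approx(w_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_zeros_dropped(self):
        w1, p1 = wilcoxon_signed_rank([0.0, 1.0, 2.0, -0.5, 0.0])
        w2, p2 = wilcoxon_signed_rank([1.0, 2.0, -0.5])
        assert (w1, p1) == (w2, p2)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0])


class TestIcc:
    def test_identical_raters(self):
        subjects = np.arange(6.0)
        ratings = np.column_stack([subjects, subjects, subjects])
        assert icc_average_random_raters(ratings) == pytest.approx(1.0, abs=1e-9)

    def test_offset_penalized_vs_consistency(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=8)
        ratings = np.column_stack([base, base + 5.0])
        icc_abs = icc_average_random_raters(ratings)
        # consistency-type ICC ignores the offset entirely
        centered = ratings - ratings.mean(axis=0)
        icc_cons = icc_average_random_raters(centered + ratings.mean())
        assert icc_abs < icc_cons

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(8)
        ratings = rng.normal(size=(6, 2)) + np.arange(6)[:, None]
        assert icc_average_random_raters(ratings) == pytest.approx(
            icc_oracle(ratings), abs=1e-12)

    def test_matches_pingouin_icc2k(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        ratings = rng.normal(size=(10, 3)) + np.arange(10)[:, None]
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 3),
            "rater": np.tile(np.arange(3), 10),
            "score": ratings.ravel(),
        })
        table = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                         ratings="score")
        types = table.set_index("Type")["ICC"]
        key = "ICC(A,k)" if "ICC(A,k)" in types.index else "ICC2k"
        ref = float(types.loc[key])
        assert icc_average_random_raters(ratings) == pytest.approx(ref, abs=1e-9)

    def test_incomplete_matrix_errors(self):
        ratings = np.ones((4, 2))
        ratings[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            icc_average_random_raters(ratings)


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.04, "*"), (0.0005, "***"), (0.05, ""), (0.009, "**"),
        (0.001, "**"), (0.01, "*"), (0.5, ""),
    ])
    def test_bands(self, p, expected):
        assert significance_stars(p) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestStructureFunctionTable:
    def make_scores(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        score = rng.integers(0, 4, size=n).astype(float)
        volume = 10.0 - 2.0 * score + rng.normal(0, 0.5, size=n)
        finding = (score > 1).astype(float)
        return pd.DataFrame({"vol": volume, "sq": score, "bin": finding,
                             "const": np.ones(n)})

    def test_effect_recovery(self):
        scores = self.make_scores(seed=21)
        table = structure_function_table(
            scores, [("vol", "sq", "spearman")], n_boot=500, seed=1)
        row = table.iloc[0]
        assert row["flag"] == ""
        assert row["estimate"] < -0.5  # strong negative monotone effect
        assert row["stars"] != ""

    def test_binary_uses_mann_whitney(self):
        scores = self.make_scores(seed=22)
        table = structure_function_table(
            scores, [("vol", "bin", "mann_whitney")], n_boot=200, seed=2)
        assert table.iloc[0]["test"] == "mann_whitney"
        assert np.isfinite(table.iloc[0]["estimate"])

    def test_constant_score_flagged(self):
        scores = self.make_scores()
        table = structure_function_table(
            scores, [("vol", "const", "spearman")], n_boot=100, seed=3)
        assert table.iloc[0]["flag"].startswith("undefined")

    def test_insufficient_rows_flagged(self):
        scores = self.make_scores().iloc[:2]
        table = structure_function_table(
            scores, [("vol", "sq", "spearman")], n_boot=100, seed=4)
        assert table.iloc[0]["flag"] == "insufficient"

    def test_one_row_per_spec_entry(self):
        scores = self.make_scores()
        spec = [("vol", "sq", "spearman"), ("vol", "bin", "mann_whitney")]
        table = structure_function_table(scores, spec, n_boot=100, seed=5)
        assert len(table) == len(spec)

    def test_missing_column_errors(self):
        with pytest.raises(KeyError):
            structure_function_table(self.make_scores(),
                                     [("nope", "sq", "spearman")])
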