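import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from stainslice import (
    bootstrap_validate,
    fold_auc,
    optimal_cutoff,
    roc,
    roc_sample_size,
    range_summary,
    spearman_matrix,
    stepwise_logistic,
)
from stainslice.prognostics import auc_mann_whitney, hanley_mcneil_variance

from reference_auc_inputs import WORKED_IMPROVEMENT_CELLS


def pair_counting_auc(scores, outcomes):
    """Exhaustive positive x negative pair enumeration oracle."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc([3, 4, 1, 2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_symmetric_ties(self):
        r = roc([1, 2, 1, 2], [1, 1, 0, 0])
        assert r.auc == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, 10).astype(float)  # heavy ties
        outcomes = rng.integers(0, 2, 10)
        if outcomes.min() == outcomes.max():
            outcomes[0] = 1 - outcomes[0]
        assert roc(scores, outcomes).auc == pytest.approx(
            pair_counting_auc(scores, outcomes), abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [1, 1, 1])

    def test_missing_scores_dropped_pairwise(self):
        r = roc([np.nan, 3, 4, 1, 2], [0, 1, 1, 0, 0])
        assert r.auc == 1.0 and r.n_pos == 2 and r.n_neg == 2

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=60) + np.r_[np.ones(20), np.zeros(40)]
        y = np.r_[np.ones(20, int), np.zeros(40, int)]
        r = roc(s, y)
        assert 0 <= r.ci_lo <= r.auc <= r.ci_hi <= 1
        assert 0 <= r.p <= 1


class TestFoldAuc:
    @pytest.mark.parametrize("a,expected", [(0.34, 0.66), (0.5, 0.5), (0.77, 0.77)])
    def test_examples(self, a, expected):
        assert fold_auc(a) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0))
    def test_reflection_involution(self, a):
        assert fold_auc(a) == fold_auc(1.0 - a)
        assert fold_auc(a) >= 0.5


class TestBootstrap:
    def test_perfectly_separable(self):
        s = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        b = bootstrap_validate(s, y, n_resamples=200, seed=0)
        assert b.corrected >= 0.95

    def test_permuted_null(self):
        rng = np.random.default_rng(42)
        s = rng.normal(size=100)
        y = np.r_[np.ones(20, int), np.zeros(80, int)]
        rng.shuffle(y)
        b = bootstrap_validate(s, y, n_resamples=1000, seed=0)
        assert b.corrected == pytest.approx(0.5, abs=0.06)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        s, y = rng.normal(size=40), rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = bootstrap_validate(s, y, n_resamples=100, seed=9)
        b = bootstrap_validate(s, y, n_resamples=100, seed=9)
        assert a == b


class TestOptimalCutoff:
    def test_hand_computed_chi2(self):
        r = optimal_cutoff([1, 1, 1, 9, 9, 9, 1, 9], [0, 0, 0, 1, 1, 1, 0, 1])
        assert r.cutoff == 5.0
        assert r.chi2 == pytest.approx(8.0)  # 2x2 of 4/4 perfect split at n=8
        assert r.high_risk == "above"

    def test_spec_six_point_example_chi2(self):
        """{1,1,1,9,9,9} with matching outcomes: midpoint 5, chi2 = n = 6."""
        s = np.array([1, 1, 1, 9, 9, 9, 1, 9], float)
        # the documented 6-point arithmetic, checked through the internal formula
        from stainslice.prognostics import _chi2_2x2

        assert _chi2_2x2(3, 0, 0, 3) == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        r = optimal_cutoff(s, y)
        # brute force over every midpoint in the window
        uniq = np.unique(s)
        mids = (uniq[:-1] + uniq[1:]) / 2
        lo, hi = np.percentile(s, [10, 90])
        best = -1.0
        for cut in mids[(mids >= lo) & (mids <= hi)]:
            high = s > cut
            a = ((high) & (y == 1)).sum()
            b = ((high) & (y == 0)).sum()
            c = ((~high) & (y == 1)).sum()
            d = ((~high) & (y == 0)).sum()
            n = a + b + c + d
            denom = (a + b) * (c + d) * (a + c) * (b + d)
            if denom:
                best = max(best, n * (a * d - b * c) ** 2 / denom)
        assert r.chi2 == pytest.approx(best, abs=1e-9)

    def test_reversed_direction_flips_flag(self):
        s = np.array([1, 1, 1, 9, 9, 9, 1, 9], float)
        y = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        fwd = optimal_cutoff(s, y)
        rev = optimal_cutoff(-s, y)
        assert fwd.chi2 == pytest.approx(rev.chi2)
        assert fwd.high_risk == "above" and rev.high_risk == "below"

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="identical"):
            optimal_cutoff(np.ones(10), np.r_[np.ones(5, int), np.zeros(5, int)])
        with pytest.raises(ValueError, match="8 patients"):
            optimal_cutoff([1, 2, 3], [0, 1, 0])


class TestSpearman:
    def test_identical_and_complementary(self):
        df = pd.DataFrame({"a": [0, 1, 0, 1], "b": [0, 1, 0, 1], "c": [1, 0, 1, 0]})
        rho, p = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)
        assert (np.diag(rho) == 1.0).all()

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["x", "y"])
        rho, _ = spearman_matrix(df)
        expect = stats.spearmanr(df["x"], df["y"]).statistic
        assert rho.loc["x", "y"] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"a": [0, 0, 0, 0], "b": [0, 1, 0, 1]})
        rho, _ = spearman_matrix(df)
        assert math.isnan(rho.loc["a", "b"])


class TestStepwise:
    @staticmethod
    def _simulated(n=200, seed=0, k_noise=5):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        logits = 2.0 * x - 1.5
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logits))).astype(int)
        data = {"outcome": y, "strong": x}
        for i in range(k_noise):
            data[f"noise{i}"] = rng.normal(size=n)
        return pd.DataFrame(data)

    def test_strong_predictor_only_retained(self):
        df = self._simulated()
        model = stepwise_logistic(df, ["strong"] + [f"noise{i}" for i in range(5)])
        assert model.terms == ["strong"]
        row = model.table.loc["strong"]
        assert row["p"] <= 0.05 and row["hr"] == pytest.approx(math.exp(row["coef"]))

    def test_all_noise_gives_empty_model(self):
        df = self._simulated(seed=1)
        model = stepwise_logistic(df, [f"noise{i}" for i in range(5)])
        assert model.terms == []

    def test_collinear_duplicate_keeps_one(self):
        df = self._simulated(seed=2)
        df["strong_copy"] = df["strong"]
        model = stepwise_logistic(df, ["strong", "strong_copy"])
        assert len(set(model.terms) & {"strong", "strong_copy"}) == 1


class TestRangeSummary:
    @pytest.mark.parametrize(
        "family,rng_label,auc_tab,p_tab,expected",
        WORKED_IMPROVEMENT_CELLS,
        ids=[c[0] + "/" + c[1] for c in WORKED_IMPROVEMENT_CELLS],
    )
    def test_worked_improvement_cells(self, family, rng_label, auc_tab, p_tab, expected):
        families = dict.fromkeys(auc_tab.index, family)
        out = range_summary(auc_tab, p_tab, families)
        assert out.loc[rng_label, f"improvement_{family}"] == pytest.approx(expected, abs=1e-9)
        assert out.loc[rng_label, "improvement_total"] == pytest.approx(expected, abs=1e-9)

    def test_worse_features_clip_to_zero(self):
        auc = pd.DataFrame({"0-255": [0.80], "x": [0.60]}, index=["f"])
        p = pd.DataFrame({"0-255": [0.01], "x": [0.01]}, index=["f"])
        out = range_summary(auc, p, {"f": "glcm"})
        assert out.loc["x", "improvement_glcm"] == 0.0

    def test_single_feature_direct_evaluation(self):
        auc = pd.DataFrame({"0-255": [0.60], "x": [0.70]}, index=["f"])
        p = pd.DataFrame({"0-255": [0.50], "x": [0.01]}, index=["f"])
        out = range_summary(auc, p, {"f": "fractal"})
        assert out.loc["x", "improvement_fractal"] == pytest.approx(0.10)

    def test_mean_folded_auc(self):
        auc = pd.DataFrame({"0-255": [0.34, 0.70]}, index=["a", "b"])
        p = pd.DataFrame({"0-255": [0.01, 0.01]}, index=["a", "b"])
        out = range_summary(auc, p, {})
        assert out.loc["0-255", "mean_folded_auc"] == pytest.approx((0.66 + 0.70) / 2)


class TestSampleSize:
    def test_default_design(self):
        r = roc_sample_size()
        assert (r.n_pos, r.n_neg, r.n_total) == (40, 40, 80)

    def test_monotone_in_effect_size(self):
        sizes = [roc_sample_size(auc).n_pos for auc in (0.6, 0.7, 0.8, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_direct_power_curve_search(self):
        """Independent oracle: scan n and evaluate the normal-approx power."""
        auc, alpha, power = 0.75, 0.05, 0.8
        za, zb = stats.norm.ppf(1 - alpha / 2), stats.norm.ppf(power)
        n = 2
        while True:
            v = hanley_mcneil_variance(auc, n, n)
            achieved = stats.norm.cdf((auc - 0.5 - za * math.sqrt(v)) / math.sqrt(v))
            if achieved >= power:
                break
            n += 1
        assert roc_sample_size(auc_alt=auc).n_pos == n

    def test_ratio_and_variance_variants(self):
        assert roc_sample_size(neg_pos_ratio=4.0).n_total == 145
        assert roc_sample_size(variance_at="null").n_total == 88

    def test_undetectable_effect_raises(self):
        with pytest.raises(ValueError):
            roc_sample_size(auc_alt=0.5)


class TestAucOracleHelpers:
    def test_mann_whitney_half_credit(self):
        assert auc_mann_whitney([1, 1], [1, 0]) == 0.5
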