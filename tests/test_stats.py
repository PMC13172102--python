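import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tddmri.stats import (
    ContingencyTable2x2,
    delong_test,
    group_compare_table,
    icc_agreement,
    logistic_backward_stepwise,
    logistic_univariable,
    mann_whitney,
    roc_analysis,
)
from tddmri.synthetic import table1_fixture


def emvi_cohort() -> pd.DataFrame:
    exposure, outcome = table1_fixture().expand()
    return pd.DataFrame({"emvi": exposure, "lvi": outcome})


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

def enumerate_exact_p(a, b) -> float:
    """Brute-force exact two-sided p: enumerate all group assignments of the
    pooled sample, compute U for each, and double the smaller tail."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    idx = range(len(pooled))

    def u_stat(first):
        x = pooled[list(first)]
        y = pooled[[i for i in idx if i not in set(first)]]
        gt = np.sum(x[:, None] > y[None, :])
        eq = np.sum(x[:, None] == y[None, :])
        return gt + 0.5 * eq

    u_obs = u_stat(range(n_a))
    us = np.array([u_stat(c) for c in itertools.combinations(idx, n_a)])
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestMannWhitney:
    def test_identical_sets(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # n_a * n_b / 2
        assert p > 0.9

    def test_fully_separated_exact(self):
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1, abs=1e-9)  # 2 / C(6,3)

    def test_exact_p_matches_enumeration(self):
        # random small-sample datasets with ties
        rng = np.random.default_rng(2024)
        for _ in range(100):
            a = rng.integers(0, 6, size=4).astype(float)
            b = rng.integers(0, 6, size=4).astype(float)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(enumerate_exact_p(a, b), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------

class TestLogisticUnivariable:
    def test_published_emvi_counts(self):
        # the 21/9 vs 13/41 exposure table
        fit = logistic_univariable(emvi_cohort(), "emvi")
        term = fit["emvi"]
        assert term.odds_ratio == pytest.approx(7.359, abs=1e-3)
        lo, hi = term.ci
        assert lo == pytest.approx(2.709, abs=1e-3)
        assert hi == pytest.approx(19.993, abs=0.02)
        assert term.p < 0.001

    def test_balanced_null_table(self):
        tab = ContingencyTable2x2(a=10, b=10, c=10, d=10)
        e, o = tab.expand()
        fit = logistic_univariable(pd.DataFrame({"x": e, "lvi": o}), "x")
        assert fit["x"].odds_ratio == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("counts", [(5, 7, 3, 11), (12, 4, 9, 20), (8, 8, 2, 14)])
    def test_binary_or_equals_cross_product(self, counts):
        tab = ContingencyTable2x2(*counts)
        e, o = tab.expand()
        fit = logistic_univariable(pd.DataFrame({"x": e, "lvi": o}), "x")
        assert fit["x"].odds_ratio == pytest.approx(tab.odds_ratio(), rel=1e-5)

    def test_complete_separation_flagged(self):
        df = pd.DataFrame({"x": [0.0] * 10 + [1.0] * 10, "lvi": [0] * 10 + [1] * 10})
        fit = logistic_univariable(df, "x")
        assert fit.separable

    def test_constant_feature_rejected(self):
        df = pd.DataFrame({"x": np.ones(20), "lvi": [0, 1] * 10})
        with pytest.raises(ValueError):
            logistic_univariable(df, "x")


def _stepwise_cohort(seed, beta, n=200) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 3))
    logit = -0.5 + X @ np.asarray(beta)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    return pd.DataFrame({"A": X[:, 0], "B": X[:, 1], "C": X[:, 2], "lvi": y})


class TestBackwardStepwise:
    def test_signal_features_retained(self):
        # A and B carry generator-known effects, C is pure noise
        hits = 0
        for seed in range(100):
            df = _stepwise_cohort(seed, beta=(1.2, 1.2, 0.0))
            fit, _ = logistic_backward_stepwise(df, ["A", "B", "C"])
            if {"A", "B"} <= set(fit.retained):
                hits += 1
        assert hits >= 90

    def test_null_cohort_retention_rate(self):
        # under the null each candidate should be retained about
        # removal_alpha of the time; assert <= 2 * alpha per candidate
        kept = {"A": 0, "B": 0, "C": 0}
        for seed in range(100):
            df = _stepwise_cohort(seed + 10_000, beta=(0.0, 0.0, 0.0))
            fit, _ = logistic_backward_stepwise(df, ["A", "B", "C"])
            for f in fit.retained:
                kept[f] += 1
        for f, k in kept.items():
            assert k / 100 <= 0.10

    def test_single_strong_candidate_matches_univariable(self):
        df = _stepwise_cohort(5, beta=(1.5, 0.0, 0.0))
        fit, full = logistic_backward_stepwise(df, ["A"])
        uni = logistic_univariable(df, "A")
        assert fit.retained == ("A",)
        assert fit["A"].odds_ratio == pytest.approx(uni["A"].odds_ratio, rel=1e-9)


# --------------------------------------------------------------------------
# ROC / DeLong
# --------------------------------------------------------------------------

class TestRocAnalysis:
    def test_published_emvi_operating_point(self):
        e, o = table1_fixture().expand()
        r = roc_analysis(e, o)
        assert r.auc == pytest.approx(0.730, abs=5e-4)
        assert r.sensitivity == pytest.approx(0.700, abs=1e-9)
        assert r.specificity == pytest.approx(0.759, abs=5e-4)
        # binary-predictor identity
        assert r.auc == pytest.approx((r.sensitivity + r.specificity) / 2.0, rel=1e-12)

    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = scores.copy()
        r = roc_analysis(scores, labels)
        assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0

    def test_null_auc(self):
        rng = np.random.default_rng(99)
        scores = rng.normal(0, 1, 2000)
        labels = rng.permutation(np.r_[np.ones(1000), np.zeros(1000)])
        r = roc_analysis(scores, labels)
        assert abs(r.auc - 0.5) < 0.03

    def test_auc_equals_mann_whitney_statistic(self):
        # tie-adjusted identity, to machine precision, with heavy ties
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        scores = rng.integers(0, 5, 60).astype(float)
        labels = rng.integers(0, 2, 60).astype(float)
        labels[:2] = [0, 1]  # both classes present
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        auc = roc_analysis(scores, labels).auc
        assert abs(auc - u / (np.sum(labels == 1) * np.sum(labels == 0))) < 1e-12

    def test_youden_cutoff_is_exhaustive_maximum(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9, 0.2, 0.75])
        labels = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        r = roc_analysis(scores, labels)
        # every possible threshold, brute force
        best = -1.0
        for c in np.r_[-np.inf, np.sort(np.unique(scores)) - 1e-9, np.inf]:
            sens = np.mean(scores[labels == 1] >= c)
            spec = np.mean(scores[labels == 0] < c)
            best = max(best, sens + spec - 1.0)
        assert r.youden == pytest.approx(best, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_scores_degenerate(self):
        y = np.r_[np.ones(20), np.zeros(30)]
        s = np.random.default_rng(0).normal(0, 1, 50)
        diff, p = delong_test(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_auc_difference_matches_roc(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(30), np.zeros(54)]
        s1 = y + rng.normal(0, 1, 84)
        s2 = y + rng.normal(0, 2, 84)
        diff, p = delong_test(s1, s2, y)
        assert diff == pytest.approx(
            roc_analysis(s1, y).auc - roc_analysis(s2, y).auc, abs=1e-15
        )
        assert 0.0 <= p <= 1.0


# --------------------------------------------------------------------------
# agreement
# --------------------------------------------------------------------------

def anova_icc2(x, y) -> float:
    """Independent oracle: ICC(2,1) from two-way ANOVA mean squares."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ms_r = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


class TestAgreement:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_agreement(x, x)
        assert res.icc == pytest.approx(1.0, abs=1e-9)
        assert res.bias == 0.0 and res.loa == (0.0, 0.0)
        assert res.grade() == "excellent"

    def test_half_shared_variance_construction(self):
        # both readers = shared signal + independent noise of equal
        # variance -> ICC ~ 0.5
        rng = np.random.default_rng(5)
        s = rng.normal(0, 1, 500)
        res = icc_agreement(s + rng.normal(0, 1, 500), s + rng.normal(0, 1, 500))
        assert res.icc == pytest.approx(0.5, abs=0.08)

    def test_matches_anova_mean_squares_oracle(self):
        x = np.array([10.0, 12.0, 15.0, 11.0, 14.0, 13.0])
        y = np.array([11.0, 11.5, 14.0, 12.0, 15.5, 12.5])
        res = icc_agreement(x, y)
        assert res.icc == pytest.approx(anova_icc2(x, y), abs=1e-10)

    def test_bland_altman_limits(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, 200)
        y = x + rng.normal(0.3, 0.5, 200)
        res = icc_agreement(x, y)
        d = x - y
        assert res.bias == pytest.approx(d.mean(), rel=1e-12)
        assert res.loa[0] == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), rel=1e-9)
        # limits are symmetric about the bias
        assert res.loa[0] + res.loa[1] == pytest.approx(2 * res.bias, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_agreement([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


# --------------------------------------------------------------------------
# cohort summary table
# --------------------------------------------------------------------------

class TestGroupCompareTable:
    def test_published_emvi_chi_square(self):
        df = emvi_cohort()
        table = group_compare_table(df, [], categorical=["emvi"])
        assert table.iloc[0]["p"] < 0.001

    def test_identical_groups(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 40)
        df = pd.DataFrame({"f": np.r_[vals, vals], "lvi": np.r_[np.ones(40), np.zeros(40)]})
        table = group_compare_table(df, ["f"])
        assert table.iloc[0]["p"] > 0.99

    def test_synthetic_cohort_power(self):
        # the two strongest published group differences should be detected
        # in essentially every replicate at the published effect sizes
        from tddmri.synthetic import generate_cohort

        hits = 0
        for seed in range(100):
            coh = generate_cohort(seed=seed)
            t = group_compare_table(coh, ["icvf", "cellularity"]).set_index("feature")
            if t.loc["icvf", "p"] < 0.05 and t.loc["cellularity", "p"] < 0.05:
                hits += 1
        assert hits >= 95
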