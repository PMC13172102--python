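"""Predictive statistics for a binary histology endpoint.

Group screening (Mann–Whitney / t-test / chi-square), univariable and
backward-stepwise multivariable logistic regression with Wald odds-ratio
intervals, empirical ROC analysis with Youden-index cutoffs and DeLong
confidence intervals / paired AUC comparison, and interobserver agreement
(two-way random absolute-agreement single-rater ICC plus Bland–Altman).

ROC and DeLong are authored here on placement values — the AUC equals the
tie-adjusted Mann–Whitney statistic algebraically, and the DeLong variance
comes from the empirical covariance of the per-subject placements.
Ordinary model fits go through statsmodels; ICC goes through pingouin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

Z_95 = sps.norm.ppf(0.975)


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------

def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann–Whitney U with two-sided p.

    Exact (permutation enumeration) when both groups have n <= 8;
    otherwise the tie-corrected, continuity-corrected normal
    approximation.  Returns (U of the first group, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) <= 8 and len(b) <= 8:
        # full enumeration: C(16, 8) = 12870 < n_resamples -> exact
        method = sps.PermutationMethod(n_resamples=20_000)
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts: a, b = exposed/unexposed among cases;
    c, d = exposed/unexposed among controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def odds_ratio(self) -> float:
        return (self.a * self.d) / (self.b * self.c)

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject (exposure, outcome) vectors reconstructed from counts."""
        exposure = np.concatenate(
            [np.ones(self.a), np.zeros(self.b), np.ones(self.c), np.zeros(self.d)]
        )
        outcome = np.concatenate([np.ones(self.n_cases), np.zeros(self.n_controls)])
        return exposure, outcome


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticTerm:
    name: str
    coef: float
    se: float
    p: float

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.coef)

    @property
    def ci(self) -> tuple[float, float]:
        return (math.exp(self.coef - Z_95 * self.se), math.exp(self.coef + Z_95 * self.se))


@dataclass(frozen=True)
class LogisticFit:
    terms: dict[str, LogisticTerm]
    llf: float
    retained: tuple[str, ...]
    converged: bool = True
    separable: bool = False

    def __getitem__(self, name: str) -> LogisticTerm:
        return self.terms[name]


def _fit_logit(df: pd.DataFrame, features: list[str], outcome: str) -> LogisticFit:
    y = df[outcome].astype(float)
    X = sm.add_constant(df[list(features)].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return LogisticFit({}, np.nan, tuple(features), converged=False, separable=True)
    separable = bool(np.any(np.abs(res.params) > 15) or not res.mle_retvals.get("converged", True))
    terms = {
        name: LogisticTerm(name=name, coef=float(res.params[name]), se=float(res.bse[name]),
                           p=float(res.pvalues[name]))
        for name in X.columns
    }
    return LogisticFit(
        terms=terms,
        llf=float(res.llf),
        retained=tuple(features),
        converged=bool(res.mle_retvals.get("converged", True)),
        separable=separable,
    )


def logistic_univariable(cohort: pd.DataFrame, feature: str, outcome: str = "lvi") -> LogisticFit:
    """Maximum-likelihood logistic fit of the outcome on one feature.

    Wald CI: exp(coef +/- 1.96*SE).  For a binary feature the fitted OR
    equals the 2x2 cross-product ratio.  Complete separation is flagged
    via ``separable`` rather than returning a spurious finite estimate.
    """
    if cohort[feature].nunique() < 2:
        raise ValueError(f"feature {feature!r} does not vary")
    if cohort[outcome].nunique() < 2:
        raise ValueError("outcome must contain both classes")
    return _fit_logit(cohort, [feature], outcome)


def logistic_backward_stepwise(
    cohort: pd.DataFrame,
    candidates: list[str],
    outcome: str = "lvi",
    removal_alpha: float = 0.05,
) -> tuple[LogisticFit, LogisticFit]:
    """Backward stepwise elimination on Wald p-values.

    Starts from the full model over ``candidates`` and repeatedly removes
    the least significant term while its p >= ``removal_alpha``, refitting
    after each removal.  Deterministic given the data.  Returns
    ``(final_fit, full_model_fit)``.
    """
    full = _fit_logit(cohort, list(candidates), outcome)
    current = list(candidates)
    fit = full
    while current:
        pvals = {f: fit.terms[f].p for f in current if f in fit.terms}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < removal_alpha:
            break
        current.remove(worst)
        fit = _fit_logit(cohort, current, outcome)
    if not current:
        fit = _fit_logit(cohort, [], outcome)  # intercept-only
    return fit, full


# --------------------------------------------------------------------------
# ROC / DeLong
# --------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per case) and V01 (per control)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    thresholds: np.ndarray = field(repr=False)
    sens_curve: np.ndarray = field(repr=False)
    spec_curve: np.ndarray = field(repr=False)

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC with Youden-optimal cutoff and DeLong 95% CI.

    Higher scores are assumed to indicate the positive class.  Candidate
    cutoffs are the midpoints between consecutive distinct scores (plus
    the two infinite extremes); predicted-positive means score >= cutoff.
    Youden ties are broken toward the higher-specificity operating point.
    The trapezoid AUC is computed from placement values, which makes it
    identically the tie-adjusted Mann–Whitney statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = Z_95 * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    distinct = np.unique(s)
    cuts = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    sens = np.array([np.mean(s[y == 1] >= c) for c in cuts])
    spec = np.array([np.mean(s[y == 0] < c) for c in cuts])
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    best = best[np.argmax(spec[best])]  # tie-break toward higher specificity
    return ROCResult(
        auc=auc,
        ci=ci,
        cutoff=float(cuts[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        thresholds=cuts,
        sens_curve=sens,
        spec_curve=spec,
    )


def delong_test(scores_1, scores_2, labels) -> tuple[float, float]:
    """Paired DeLong comparison of two AUCs on the same subjects.

    Returns (AUC_1 - AUC_2, two-sided p).  Identical score vectors give a
    zero difference with p = 1 (degenerate variance).
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s1.shape != s2.shape or s1.shape != y.shape:
        raise ValueError("scores must be paired on identical subjects")
    v10_1, v01_1 = _placements(s1, y)
    v10_2, v01_2 = _placements(s2, y)
    diff = float(v10_1.mean() - v10_2.mean())
    var = delong_difference_variance(s1, s2, y)
    if var <= 0:
        return diff, 1.0
    z = diff / math.sqrt(var)
    return diff, float(2.0 * sps.norm.sf(abs(z)))


def delong_difference_variance(scores_1, scores_2, labels) -> float:
    """DeLong sampling variance of the paired AUC difference."""
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    y = np.asarray(labels, dtype=float)
    v10_1, v01_1 = _placements(s1, y)
    v10_2, v01_2 = _placements(s2, y)
    m, n = len(v10_1), len(v01_1)
    d10 = v10_1 - v10_2
    d01 = v01_1 - v01_2
    return float(
        (np.var(d10, ddof=1) / m if m > 1 else 0.0)
        + (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    )


def delong_variance(scores, labels) -> float:
    """DeLong sampling variance of a single empirical AUC."""
    v10, v01 = _placements(np.asarray(scores, float), np.asarray(labels, float))
    m, n = len(v10), len(v01)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


# --------------------------------------------------------------------------
# agreement
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    icc: float
    icc_ci: tuple[float, float]
    bias: float            # Bland–Altman mean difference (reader1 - reader2)
    loa: tuple[float, float]  # limits of agreement, bias +/- 1.96 * SD(diff)

    def grade(self) -> str:
        """Conventional qualitative ICC interpretation."""
        if self.icc < 0.5:
            return "poor"
        if self.icc < 0.75:
            return "moderate"
        if self.icc < 0.9:
            return "good"
        return "excellent"


def icc_agreement(reader1, reader2) -> AgreementResult:
    """Interobserver agreement between two readers.

    ICC is the two-way random-effects, absolute-agreement, single-rater
    form (ICC(2,1)) with its F-based 95% CI; Bland–Altman reports the mean
    difference and the +/- 1.96 SD limits of agreement.
    """
    import pingouin as pg

    x = np.asarray(reader1, dtype=float)
    y = np.asarray(reader2, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need >= 3 paired measurements")
    if np.var(np.concatenate([x, y])) == 0:
        raise ValueError("zero total variance")
    n = len(x)
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["r1", "r2"], n),
            "value": np.concatenate([x, y]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="value"
        ).set_index("Type")
    # pingouin labels the two-way random absolute-agreement single-rater
    # form ICC2 or ICC(A,1) depending on version
    label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    diff = x - y
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(
        icc=float(row["ICC"]),
        icc_ci=(float(row[ci_col][0]), float(row[ci_col][1])),
        bias=bias,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
    )


# --------------------------------------------------------------------------
# cohort summary table
# --------------------------------------------------------------------------

def group_compare_table(
    cohort: pd.DataFrame,
    continuous: list[str],
    categorical: list[str] | None = None,
    group: str = "lvi",
    shapiro_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature group summaries with the appropriate two-group test.

    Continuous features are routed by Shapiro–Wilk normality (within both
    groups) to either mean +/- SD with a t-test or median (IQR) with a
    Mann–Whitney test; categorical features use the chi-square test.
    """
    categorical = categorical or []
    pos = cohort[cohort[group] == 1]
    neg = cohort[cohort[group] == 0]
    rows = []
    for feat in continuous:
        a, b = pos[feat].to_numpy(float), neg[feat].to_numpy(float)
        normal = (
            sps.shapiro(a).pvalue > shapiro_alpha and sps.shapiro(b).pvalue > shapiro_alpha
        )
        if normal:
            p = float(sps.ttest_ind(a, b).pvalue)
            fmt = lambda v: f"{np.mean(v):.3f} ± {np.std(v, ddof=1):.3f}"
            test = "t"
        else:
            _, p = mann_whitney(a, b)
            fmt = lambda v: (
                f"{np.median(v):.3f} "
                f"({np.percentile(v, 25):.3f}–{np.percentile(v, 75):.3f})"
            )
            test = "mann-whitney"
        rows.append({"feature": feat, "positive": fmt(a), "negative": fmt(b),
                     "test": test, "p": p})
    for feat in categorical:
        tab = pd.crosstab(cohort[feat], cohort[group])
        chi2 = sps.chi2_contingency(tab.to_numpy())
        rows.append(
            {
                "feature": feat,
                "positive": "/".join(str(c) for c in tab[1].to_numpy()),
                "negative": "/".join(str(c) for c in tab[0].to_numpy()),
                "test": "chi-square",
                "p": float(chi2.pvalue),
            }
        )
    return pd.DataFrame(rows)
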