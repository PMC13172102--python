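"""Synthetic signal phantoms and patient cohorts with known ground truth.

Two generators make every pipeline stage testable without patient data:

* :func:`generate_phantom` builds 2-D parameter grids with labelled
  regions, evaluates the two-compartment forward model per voxel and
  corrupts the magnitude signal with Rician noise of a stated SNR;
* :func:`generate_cohort` draws per-patient feature vectors whose
  per-group marginals reproduce published summary statistics exactly —
  features reported as mean +/- SD use zero-truncated normals, features
  reported as median (IQR) use shifted log-normals solved so that the
  analytic median and quartiles equal the printed values (reflected when
  the printed quartiles are left-skewed) — coupled through a Gaussian
  copula with a configurable correlation matrix.

The binary endpoint is group membership itself (ground truth), not a
logistic draw, so downstream predictive statistics can be checked against
a known signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gpa import DEFAULT_D_IN, TwoCompartmentParams, impulsed_forward
from .scheme import AcquisitionScheme
from .stats import ContingencyTable2x2

_Z75 = sps.norm.ppf(0.75)

FEATURE_COLUMNS = (
    "adc_pgse",
    "adc_25hz",
    "adc_40hz",
    "relative_adc_25hz",
    "relative_adc_40hz",
    "ratio_25_40",
    "ratio_25_pgse",
    "ratio_40_pgse",
    "icvf",
    "d_ex",
    "cell_diameter",
    "cellularity",
    "tumor_length",
)


# --------------------------------------------------------------------------
# marginal distributions matched to printed summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchedMarginal:
    """A marginal distribution solved to match a printed summary exactly.

    ``kind`` is "normal" (zero-truncated, parametrized by the printed mean
    and SD of the parent) or "lognormal" (three-parameter shifted
    log-normal; ``sign`` = -1 denotes the reflected form used when the
    printed quartiles are left-skewed).
    """

    kind: str
    mean: float = 0.0
    sd: float = 1.0
    loc: float = 0.0
    mu: float = 0.0
    sigma: float = 0.0
    sign: int = 1
    truncate: bool = True  # zero-truncation for mean/SD-specified normals

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.kind == "normal":
            if self.sd == 0:  # degenerate (zero-variance) spec
                return np.full_like(u, self.mean)
            if not self.truncate:
                return sps.norm.ppf(u, loc=self.mean, scale=self.sd)
            a = (0.0 - self.mean) / self.sd  # truncate at physical zero
            return sps.truncnorm.ppf(u, a=a, b=np.inf, loc=self.mean, scale=self.sd)
        if self.sign > 0:
            return self.loc + np.exp(self.mu + self.sigma * sps.norm.ppf(u))
        return self.loc - np.exp(self.mu + self.sigma * sps.norm.ppf(1.0 - u))

    def median_iqr(self) -> tuple[float, float, float]:
        """Analytic (q1, median, q3) — used to verify the match."""
        return tuple(float(self.ppf(p)) for p in (0.25, 0.5, 0.75))


def marginal_from_summary(record: dict) -> MatchedMarginal:
    """Build a matched marginal from a summary record.

    ``{"kind": "normal", "mean": m, "sd": s}`` or
    ``{"kind": "lognormal_iqr", "median": m, "q1": q1, "q3": q3}``.
    """
    if record["kind"] == "normal":
        return MatchedMarginal(kind="normal", mean=record["mean"], sd=record["sd"])
    if record["kind"] != "lognormal_iqr":
        raise ValueError(f"unknown marginal kind {record['kind']!r}")
    q1, med, q3 = record["q1"], record["median"], record["q3"]
    if not q1 < med < q3:
        raise ValueError("need q1 < median < q3")
    skew = (q3 - med) - (med - q1)
    if abs(skew) < 1e-12 * (q3 - q1):
        # symmetric quartiles: the shifted log-normal degenerates to a
        # normal; left untruncated so the quantile match stays exact
        return MatchedMarginal(
            kind="normal", mean=med, sd=(q3 - q1) / (2.0 * _Z75), truncate=False
        )
    if skew > 0:
        loc = (med**2 - q1 * q3) / (2.0 * med - q1 - q3)
        mu = np.log(med - loc)
        sigma = np.log((q3 - loc) / (med - loc)) / _Z75
        return MatchedMarginal(kind="lognormal", loc=loc, mu=mu, sigma=sigma, sign=1)
    loc = (q1 * q3 - med**2) / (q1 + q3 - 2.0 * med)
    mu = np.log(loc - med)
    sigma = np.log((loc - q1) / (loc - med)) / _Z75
    return MatchedMarginal(kind="lognormal", loc=loc, mu=mu, sigma=sigma, sign=-1)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Per-group feature marginals, EMVI prevalences and group sizes."""

    features: dict[str, dict[str, MatchedMarginal]]  # feature -> group -> marginal
    emvi_prevalence: dict[str, float]
    group_sizes: dict[str, int]
    correlation: np.ndarray | None = None  # over feature order, shared by groups
    feature_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.feature_order:
            self.feature_order = tuple(self.features)
        for g, p in self.emvi_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalence must lie in [0, 1]")
        if self.correlation is not None:
            w = np.linalg.eigvalsh(self.correlation)
            if w.min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")

    @classmethod
    def default(cls) -> "CohortSpec":
        """The bundled two-group rectal-cancer cohort description."""
        ref = resources.files("tddmri.data").joinpath("table12_defaults.json")
        return cls.from_dict(json.loads(ref.read_text()))

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortSpec":
        features = {
            feat: {g: marginal_from_summary(rec) for g, rec in groups.items()}
            for feat, groups in raw["features"].items()
        }
        order = tuple(features)
        corr = np.eye(len(order))
        for name_a, name_b, rho in raw.get("correlations", []):
            i, j = order.index(name_a), order.index(name_b)
            corr[i, j] = corr[j, i] = rho
        return cls(
            features=features,
            emvi_prevalence=raw["emvi_prevalence"],
            group_sizes=raw["group_sizes"],
            correlation=corr,
            feature_order=order,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def generate_cohort(
    spec: CohortSpec | None = None,
    seed: int = 0,
    size_scale: float = 1.0,
) -> pd.DataFrame:
    """Draw a cohort whose group marginals match the spec's summaries.

    Returns one row per patient with the feature columns, ``emvi`` (0/1)
    and the ground-truth ``lvi`` label (1 for the positive group).
    ``size_scale`` multiplies both group sizes (for calibration checks at
    large n).
    """
    spec = spec or CohortSpec.default()
    rng = np.random.default_rng(seed)
    order = spec.feature_order
    k = len(order)
    corr = spec.correlation if spec.correlation is not None else np.eye(k)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    frames = []
    for group, label in (("lvi_pos", 1), ("lvi_neg", 0)):
        n = int(round(spec.group_sizes[group] * size_scale))
        z = rng.standard_normal((n, k)) @ chol.T
        u = sps.norm.cdf(z)
        data = {
            feat: spec.features[feat][group].ppf(u[:, j])
            for j, feat in enumerate(order)
        }
        df = pd.DataFrame(data)
        df["emvi"] = (rng.random(n) < spec.emvi_prevalence[group]).astype(int)
        df["lvi"] = label
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "patient_id", [f"P{i:04d}" for i in range(len(out))])
    return out


def table1_fixture() -> ContingencyTable2x2:
    """The published EMVI x LVI counts: 21/9 exposed/unexposed among the 30
    LVI-positive patients, 13/41 among the 54 LVI-negative."""
    return ContingencyTable2x2(a=21, b=9, c=13, d=41)


# --------------------------------------------------------------------------
# signal phantoms
# --------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """2-D ground-truth parameter grids with labelled regions."""

    icvf: np.ndarray
    d: np.ndarray
    d_ex: np.ndarray
    mask: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    d_in: float = DEFAULT_D_IN

    @classmethod
    def two_region_default(cls, shape: tuple[int, int] = (24, 24)) -> "PhantomTruth":
        """A disk 'tumor' over a 'background' rim, at the two groups' median
        microstructure (tumor: icvf 0.334, d 12.808 um, D_ex 2.341;
        background: icvf 0.212, d 11.812 um, D_ex 2.425)."""
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        c = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
        r = np.hypot(yy - c[0], xx - c[1])
        tumor = r <= min(shape) / 4.0
        background = (~tumor) & (r <= min(shape) / 2.2)
        mask = tumor | background
        icvf = np.where(tumor, 0.334, 0.212)
        d = np.where(tumor, 12.808, 11.812)
        d_ex = np.where(tumor, 2.341, 2.425)
        return cls(
            icvf=icvf, d=d, d_ex=d_ex, mask=mask,
            regions={"tumor": tumor, "background": background},
        )


def rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-image noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma^2)."""
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return s.copy()
    e1 = rng.normal(0.0, sigma, s.shape)
    e2 = rng.normal(0.0, sigma, s.shape)
    return np.sqrt((s + e1) ** 2 + e2**2)


def generate_phantom(
    truth: PhantomTruth,
    scheme: AcquisitionScheme,
    snr: float = 50.0,
    seed: int = 0,
) -> np.ndarray:
    """Noisy signal volumes (grid + measurement axis) from known truth.

    Per-voxel signals come from the two-compartment forward model; Rician
    noise uses sigma = S(b=0)/SNR = 1/SNR (signals are normalized).  An
    infinite SNR returns the forward model exactly.  Unique parameter
    triples are evaluated once and broadcast, so piecewise-constant
    phantoms cost a handful of forward evaluations.
    """
    rng = np.random.default_rng(seed)
    grid_shape = truth.mask.shape
    signals = np.zeros(grid_shape + (len(scheme),))
    stacked = np.stack(
        [truth.icvf, truth.d, truth.d_ex], axis=-1
    ).reshape(-1, 3)
    flat_mask = truth.mask.ravel()
    uniq, inverse = np.unique(stacked, axis=0, return_inverse=True)
    table = np.zeros((len(uniq), len(scheme)))
    for i, (icvf, d, d_ex) in enumerate(uniq):
        if not flat_mask[inverse == i].any():
            continue
        params = TwoCompartmentParams(icvf=icvf, d=d, d_ex=d_ex, d_in=truth.d_in)
        table[i] = impulsed_forward(params, scheme)
    signals = table[inverse].reshape(grid_shape + (len(scheme),))
    signals[~truth.mask] = 0.0
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("SNR must be positive or infinite")
        noisy = rician_noise(signals, 1.0 / snr, rng)
        noisy[~truth.mask] = 0.0
        return noisy
    return signals
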