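"""Voxel-wise estimation: ADC per diffusion time, two-compartment fitting,
parametric-map assembly and ROI summarization.

The fit minimizes the sum of squared differences between the normalized
observed signals and the two-compartment forward model over
(icvf, d, D_ex) with D_in fixed, using bounded nonlinear least squares
started from the best cells of a coarse parameter grid.  Signals are
normalized per diffusion-time group by that group's b = 0 measurement,
which makes the fit robust to group-wise T2/TE scale differences.

For speed, the intracellular (sphere) signal of each measurement is
pre-tabulated on a fine diameter grid and interpolated with a cubic
spline: the restricted signal is a smooth function of diameter, and a
0.1 um grid keeps the interpolation error orders of magnitude below the
solver tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .gpa import DEFAULT_D_IN, DEFAULT_K_MAX, TwoCompartmentParams, intracellular_attenuation
from .scheme import AcquisitionScheme

MISSING = np.nan

MAP_NAMES = (
    "icvf",
    "d",
    "d_ex",
    "cellularity",
    "residual",
    "converged",
)

ADC_NAMES = (
    "adc_pgse",
    "adc_25hz",
    "adc_40hz",
    "relative_adc_25hz",
    "relative_adc_40hz",
    "ratio_25_40",
    "ratio_25_pgse",
    "ratio_40_pgse",
)


@dataclass(frozen=True)
class ADCSet:
    """ADCs per diffusion time (um^2/ms) and the derived relative metrics.

    ``relative_x = adc_x/adc_pgse - 1`` and the three pairwise ratios,
    exactly as conventionally defined for OGSE/PGSE comparisons.
    """

    adc_pgse: float
    adc_25hz: float
    adc_40hz: float

    @property
    def relative_adc_25hz(self) -> float:
        return (self.adc_25hz - self.adc_pgse) / self.adc_pgse

    @property
    def relative_adc_40hz(self) -> float:
        return (self.adc_40hz - self.adc_pgse) / self.adc_pgse

    @property
    def ratio_25_40(self) -> float:
        return self.adc_25hz / self.adc_40hz

    @property
    def ratio_25_pgse(self) -> float:
        return self.adc_25hz / self.adc_pgse

    @property
    def ratio_40_pgse(self) -> float:
        return self.adc_40hz / self.adc_pgse

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ADC_NAMES}


def compute_adc(
    b_values: np.ndarray, signals: np.ndarray, mode: str = "regression"
) -> float:
    """ADC (um^2/ms) from the signals of one diffusion-time group.

    ``regression`` (default) is the negated slope of the log-linear
    least-squares fit of ln S on b over all b-values; ``two_point`` uses
    only the smallest and largest b.  Requires >= 2 b-values including
    b = 0 and strictly positive signals.
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    if len(b) < 2 or 0.0 not in b:
        raise ValueError("need >= 2 b-values including b = 0")
    if np.any(s <= 0):
        raise ValueError("signals must be positive for a log-linear ADC fit")
    if mode == "two_point":
        i0, i1 = np.argmin(b), np.argmax(b)
        return float(np.log(s[i0] / s[i1]) / (b[i1] - b[i0]))
    if mode != "regression":
        raise ValueError(f"unknown ADC mode {mode!r}")
    slope = np.polyfit(b, np.log(s), 1)[0]
    return float(-slope)


def relative_adc_metrics(adc_pgse: float, adc_25hz: float, adc_40hz: float) -> ADCSet:
    """Bundle the three ADCs and validate the ratio denominators."""
    if adc_pgse <= 0 or adc_40hz <= 0:
        raise ValueError("adc_pgse and adc_40hz must be > 0 (ratio denominators)")
    return ADCSet(adc_pgse=adc_pgse, adc_25hz=adc_25hz, adc_40hz=adc_40hz)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the voxel-wise two-compartment fit."""

    d_in: float = DEFAULT_D_IN
    icvf_bounds: tuple[float, float] = (0.0, 1.0)
    d_bounds: tuple[float, float] = (2.0, 30.0)  # um
    d_ex_bounds: tuple[float, float] = (0.1, 3.5)  # um^2/ms
    grid_shape: tuple[int, int, int] = (4, 4, 4)
    n_starts: int = 4  # best grid cells polished by the optimizer
    objective_tol: float = 1e-10
    adc_mode: str = "regression"
    max_normalized_signal: float = 1.2  # noise-floor flagging threshold
    d_grid_step: float = 0.1  # um, spline tabulation step
    k_max: int = DEFAULT_K_MAX
    joint_s0: bool = False  # fit one S0 across groups instead of per-group b0

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.icvf_bounds[0], self.d_bounds[0], self.d_ex_bounds[0]])
        hi = np.array([self.icvf_bounds[1], self.d_bounds[1], self.d_ex_bounds[1]])
        return lo, hi


class ImpulsedModelCache:
    """Spline-tabulated intracellular signals for fast repeated fitting.

    Tabulates S_in(d) for every nonzero-b measurement of ``scheme`` on a
    uniform diameter grid spanning the fitting bounds, then evaluates the
    full two-compartment model by interpolation.
    """

    def __init__(self, scheme: AcquisitionScheme, config: FitConfig | None = None):
        self.scheme = scheme
        self.config = config or FitConfig()
        cfg = self.config
        d_lo, d_hi = cfg.d_bounds
        margin = 2 * cfg.d_grid_step
        self._d_grid = np.arange(max(d_lo - margin, 0.5), d_hi + margin, cfg.d_grid_step)
        self._b = scheme.b_values
        self._splines = []
        for m in scheme:
            if m.b == 0:
                self._splines.append(None)
                continue
            s_in = np.array(
                [
                    intracellular_attenuation(d, cfg.d_in, m, k_max=cfg.k_max)
                    for d in self._d_grid
                ]
            )
            self._splines.append(CubicSpline(self._d_grid, s_in))

    def signals(self, icvf, d, d_ex) -> np.ndarray:
        """Model S/S0 vector; broadcasts over array-valued parameters."""
        icvf = np.asarray(icvf, dtype=float)
        d = np.asarray(d, dtype=float)
        d_ex = np.asarray(d_ex, dtype=float)
        out = np.empty(np.broadcast_shapes(icvf.shape, d.shape, d_ex.shape) + (len(self._b),))
        for i, (b, spl) in enumerate(zip(self._b, self._splines)):
            if spl is None:
                out[..., i] = 1.0
            else:
                out[..., i] = icvf * spl(d) + (1.0 - icvf) * np.exp(-b * d_ex)
        return out


@dataclass(frozen=True)
class FitResult:
    params: TwoCompartmentParams | None
    residual: float
    converged: bool
    flag: str = ""


def _start_grid(config: FitConfig) -> np.ndarray:
    """Coarse multi-start grid over the midspans of the bounding box."""
    lo, hi = config.bounds
    axes = [
        lo[j] + (hi[j] - lo[j]) * (np.arange(n) + 0.5) / n
        for j, n in enumerate(config.grid_shape)
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)


def normalize_signals(
    signals: np.ndarray, scheme: AcquisitionScheme, config: FitConfig | None = None
) -> np.ndarray:
    """Divide each measurement by its diffusion-time group's b = 0 signal."""
    cfg = config or FitConfig()
    s = np.asarray(signals, dtype=float)
    out = np.empty_like(s)
    for label, idx in scheme.groups.items():
        s0 = s[..., scheme.group_b0_index(label)]
        for i in idx:
            out[..., i] = s[..., i] / s0
    return out


def fit_voxel(
    norm_signals: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
    cache: ImpulsedModelCache | None = None,
) -> FitResult:
    """Fit (icvf, d, D_ex) of one voxel from group-normalized signals.

    Deterministic bounded least squares: the objective is evaluated on the
    coarse start grid, the best ``n_starts`` cells are polished with a
    trust-region reflective solver, and the best local optimum is
    returned.  Voxels whose normalized signals exceed the noise-floor
    threshold or are non-positive are flagged, not clipped.
    """
    cfg = config or FitConfig()
    if cache is None:
        cache = ImpulsedModelCache(scheme, cfg)
    s = np.asarray(norm_signals, dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        return FitResult(None, np.nan, False, "non-positive signal")
    if np.any(s > cfg.max_normalized_signal):
        return FitResult(None, np.nan, False, "normalized signal above noise floor")

    def residuals(theta: np.ndarray) -> np.ndarray:
        return cache.signals(theta[0], theta[1], theta[2]) - s

    starts = _start_grid(cfg)
    sse = np.sum((cache.signals(starts[:, 0], starts[:, 1], starts[:, 2]) - s) ** 2, axis=-1)
    order = np.argsort(sse)[: cfg.n_starts]
    lo, hi = cfg.bounds
    best = None
    for j in order:
        try:
            sol = least_squares(
                residuals,
                starts[j],
                bounds=(lo, hi),
                method="trf",
                xtol=1e-12,
                ftol=cfg.objective_tol,
                gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(None, np.nan, False, "no start converged")
    icvf, d, d_ex = best.x
    params = TwoCompartmentParams(icvf=float(icvf), d=float(d), d_ex=float(d_ex), d_in=cfg.d_in)
    return FitResult(params, float(np.sqrt(2.0 * best.cost)), True)


@dataclass
class ParametricMaps:
    """Per-voxel fitted maps sharing one mask and grid geometry.

    ``maps`` holds one array per parameter (microstructure, ADC metrics
    and fit diagnostics); unanalyzed voxels carry NaN.  ``affine`` is the
    NIfTI affine carried through from the input volumes, if any.
    """

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    affine: np.ndarray | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def save_nifti(self, out_dir) -> list:
        """Write one NIfTI per parameter; returns the paths written."""
        import nibabel as nib
        from pathlib import Path

        out = []
        affine = self.affine if self.affine is not None else np.eye(4)
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, arr in self.maps.items():
            a = np.asarray(arr, dtype=np.float64)
            if a.ndim < 3:
                a = a.reshape(a.shape + (1,) * (3 - a.ndim))
            path = out_dir / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(a, affine), path)
            out.append(path)
        return out


def fit_volume(
    signals: np.ndarray,
    mask: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
    affine: np.ndarray | None = None,
    cache: ImpulsedModelCache | None = None,
) -> ParametricMaps:
    """Apply the voxel fit and ADC estimation across a masked volume.

    ``signals`` has shape ``grid + (n_measurements,)`` in scheme order and
    arbitrary scale (normalization is per diffusion-time group, inside).
    Voxels outside the mask, and flagged voxels, carry NaN in every map.
    """
    cfg = config or FitConfig()
    s = np.asarray(signals, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if s.shape[:-1] != mask.shape:
        raise ValueError("signal grid and mask shapes differ")
    if s.shape[-1] != len(scheme):
        raise ValueError("signal count does not match the scheme")
    if not mask.any():
        warnings.warn("empty mask: returning empty maps")
    if cache is None:
        cache = ImpulsedModelCache(scheme, cfg)
    maps = {name: np.full(mask.shape, MISSING) for name in MAP_NAMES + ADC_NAMES}
    maps["converged"] = np.zeros(mask.shape)

    groups = scheme.groups
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        raw = s[idx]
        if np.any(~np.isfinite(raw)) or np.any(raw[[scheme.group_b0_index(g) for g in groups]] <= 0):
            continue
        norm = normalize_signals(raw, scheme, cfg)
        fit = fit_voxel(norm, scheme, cfg, cache)
        if fit.converged and fit.params is not None:
            maps["icvf"][idx] = fit.params.icvf
            maps["d"][idx] = fit.params.d
            maps["d_ex"][idx] = fit.params.d_ex
            maps["cellularity"][idx] = fit.params.cellularity
            maps["residual"][idx] = fit.residual
            maps["converged"][idx] = 1.0
        adcs = {}
        try:
            for label, gi in groups.items():
                adcs[label] = compute_adc(
                    [scheme.measurements[i].b for i in gi], raw[gi], cfg.adc_mode
                )
            adc_set = relative_adc_metrics(adcs["PGSE"], adcs["25HZ"], adcs["40HZ"])
            for name, value in adc_set.as_dict().items():
                maps[name][idx] = value
        except (ValueError, KeyError):
            pass
    return ParametricMaps(maps=maps, mask=mask, affine=affine)


@dataclass(frozen=True)
class ROISummary:
    """Per-parameter means over the ROI voxels of a single slice."""

    values: dict[str, float]
    patient_id: str = ""
    reader_id: str = ""
    n_voxels: int = 0

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def summarize_roi(
    maps: ParametricMaps,
    roi_mask: np.ndarray,
    patient_id: str = "",
    reader_id: str = "",
) -> ROISummary:
    """Mean of every parametric map over the analyzed voxels of the ROI."""
    roi = np.asarray(roi_mask, dtype=bool) & maps.mask
    values: dict[str, float] = {}
    n = 0
    for name, arr in maps.maps.items():
        sel = arr[roi]
        sel = sel[np.isfinite(sel)]
        if len(sel) == 0:
            raise ValueError("ROI contains no analyzed voxel")
        n = max(n, len(sel))
        values[name] = float(np.mean(sel))
    return ROISummary(values=values, patient_id=patient_id, reader_id=reader_id, n_voxels=n)


def average_readers(a: ROISummary, b: ROISummary) -> ROISummary:
    """Arithmetic mean of two readers' ROI summaries, parameter by parameter."""
    if set(a.values) != set(b.values):
        raise ValueError("summaries cover different parameters")
    values = {k: 0.5 * (a.values[k] + b.values[k]) for k in a.values}
    return ROISummary(
        values=values,
        patient_id=a.patient_id or b.patient_id,
        reader_id="mean",
        n_voxels=max(a.n_voxels, b.n_voxels),
    )
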