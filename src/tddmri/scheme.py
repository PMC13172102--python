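"""Diffusion acquisition schemes: PGSE and cosine-OGSE measurements.

Unit conventions used throughout the package:

* lengths in micrometres (um), times in milliseconds (ms)
* diffusivities in um^2/ms
* b-values in ms/um^2 (1000 s/mm^2 == 1 ms/um^2)
* gradient amplitudes always carry the gyromagnetic ratio, i.e. the
  "gradient scale" G is gamma*g in rad / (um * ms).  Because G is always
  derived from b, gamma cancels out of every observable quantity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

PGSE = "pgse"
COS_OGSE = "cos_ogse"

_S_MM2_PER_MS_UM2 = 1000.0  # 1 ms/um^2 expressed in s/mm^2


@dataclass(frozen=True)
class DiffusionMeasurement:
    """One diffusion-weighted measurement.

    Parameters
    ----------
    waveform : {"pgse", "cos_ogse"}
        Gradient waveform family.  PGSE is two rectangular lobes of
        duration ``delta`` whose leading edges are ``Delta`` apart;
        cos-OGSE is two cosine-modulated lobes with an integer number of
        cycles per lobe.
    b : float
        Diffusion weighting in ms/um^2.
    delta : float
        Lobe duration in ms.
    Delta : float
        Lobe separation, leading edge to leading edge, in ms.
    frequency : float
        Oscillation frequency in Hz (0 for PGSE).
    n_cycles : int
        Integer cycles per lobe (0 for PGSE).
    group : str
        Diffusion-time group label, e.g. ``"PGSE"``, ``"25HZ"``, ``"40HZ"``.
    effective_diffusion_time : float or None
        Vendor-reported effective diffusion time in ms.  Metadata only;
        never used in any computation.
    """

    waveform: str
    b: float
    delta: float
    Delta: float
    frequency: float = 0.0
    n_cycles: int = 0
    group: str = ""
    effective_diffusion_time: float | None = None

    def __post_init__(self) -> None:
        if self.waveform not in (PGSE, COS_OGSE):
            raise ValueError(f"unknown waveform kind {self.waveform!r}")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.waveform == PGSE:
            if self.Delta < self.delta:
                raise ValueError("PGSE requires Delta >= delta")
        else:
            if self.n_cycles < 1:
                raise ValueError("cos-OGSE requires an integer n_cycles >= 1")
            # frequency (Hz) must equal n_cycles / delta with delta in ms
            f_implied = 1000.0 * self.n_cycles / self.delta
            if abs(self.frequency - f_implied) > 1e-6 * f_implied:
                raise ValueError(
                    f"frequency {self.frequency} Hz inconsistent with "
                    f"{self.n_cycles} cycles over {self.delta} ms"
                )

    @property
    def omega(self) -> float:
        """Angular frequency in rad/ms (0 for PGSE)."""
        return 2.0 * math.pi * self.frequency / 1000.0

    @property
    def duration(self) -> float:
        """Total waveform duration Delta + delta in ms."""
        return self.Delta + self.delta

    def with_b(self, b: float) -> "DiffusionMeasurement":
        return replace(self, b=b)


def gradient_from_b(measurement: DiffusionMeasurement) -> float:
    """Gradient scale G = gamma*g (rad/um/ms) realizing the measurement's b.

    Closed forms: for PGSE ``b = G^2 delta^2 (Delta - delta/3)``; for
    integer-cycle cosine OGSE with two lobes ``b = G^2 delta / omega^2``.
    Raises for b = 0, where no gradient is needed.
    """
    m = measurement
    if m.b <= 0:
        raise ValueError("b must be > 0 to derive a gradient amplitude")
    if m.waveform == PGSE:
        return math.sqrt(m.b / (m.delta**2 * (m.Delta - m.delta / 3.0)))
    return math.sqrt(m.b * m.omega**2 / m.delta)


def b_from_gradient(measurement: DiffusionMeasurement, g: float) -> float:
    """Closed-form b (ms/um^2) for gradient scale ``g`` (inverse of above)."""
    m = measurement
    if m.waveform == PGSE:
        return g**2 * m.delta**2 * (m.Delta - m.delta / 3.0)
    return g**2 * m.delta / m.omega**2


def gradient_waveform(
    measurement: DiffusionMeasurement, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the unit-amplitude effective gradient time course.

    Returns ``(t, s)`` where ``t`` are sample midpoints on a uniform grid of
    step ``dt`` covering ``[0, Delta + delta]`` and ``s`` the dimensionless
    waveform shape (second lobe sign-inverted, as seen by the spins after
    refocusing).  Multiply by the gradient scale G for physical units.
    """
    m = measurement
    n = int(round(m.duration / dt))
    t = (np.arange(n) + 0.5) * dt
    s = np.zeros(n)
    lobe1 = t < m.delta
    lobe2 = (t >= m.Delta) & (t < m.Delta + m.delta)
    if m.waveform == PGSE:
        s[lobe1] = 1.0
        s[lobe2] = -1.0
    else:
        s[lobe1] = np.cos(m.omega * t[lobe1])
        s[lobe2] = -np.cos(m.omega * (t[lobe2] - m.Delta))
    return t, s


def numerical_b(measurement: DiffusionMeasurement, g: float, dt: float = 1e-3) -> float:
    """b computed as the integral of q(t)^2 on a fine grid (round-trip check)."""
    _, s = gradient_waveform(measurement, dt)
    q = np.cumsum(s) * dt * g
    return float(np.sum(q**2) * dt)


@dataclass
class AcquisitionScheme:
    """An ordered set of diffusion measurements with diffusion-time groups.

    Invariants: each group contains exactly one b = 0 measurement and
    b-values within a group are strictly increasing.
    """

    measurements: list[DiffusionMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, idx in self.groups.items():
            bs = [self.measurements[i].b for i in idx]
            if sum(b == 0 for b in bs) != 1:
                raise ValueError(f"group {label!r} must contain exactly one b = 0")
            if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
                raise ValueError(f"b-values in group {label!r} must be strictly increasing")

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def groups(self) -> dict[str, list[int]]:
        """Map from group label to measurement indices, in scheme order."""
        out: dict[str, list[int]] = {}
        for i, m in enumerate(self.measurements):
            out.setdefault(m.group, []).append(i)
        return out

    @property
    def b_values(self) -> np.ndarray:
        return np.array([m.b for m in self.measurements])

    def group_b0_index(self, label: str) -> int:
        for i in self.groups[label]:
            if self.measurements[i].b == 0:
                return i
        raise KeyError(label)

    # ---- JSON round trip ------------------------------------------------
    @staticmethod
    def _from_record(rec: dict) -> DiffusionMeasurement:
        return DiffusionMeasurement(
            waveform=PGSE if rec["kind"].lower() == "pgse" else COS_OGSE,
            b=rec["b_s_mm2"] / _S_MM2_PER_MS_UM2,
            delta=rec["delta_ms"],
            Delta=rec["Delta_ms"],
            frequency=rec.get("frequency_hz", 0.0),
            n_cycles=rec.get("n_cycles", 0),
            group=rec.get("group", ""),
            effective_diffusion_time=rec.get("effective_diffusion_time_ms"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionScheme":
        records = json.loads(Path(path).read_text())
        return cls([cls._from_record(r) for r in records])

    def to_json(self, path: str | Path) -> None:
        records = []
        for m in self.measurements:
            records.append(
                {
                    "kind": "PGSE" if m.waveform == PGSE else "COS_OGSE",
                    "frequency_hz": m.frequency,
                    "n_cycles": m.n_cycles,
                    "delta_ms": m.delta,
                    "Delta_ms": m.Delta,
                    "b_s_mm2": m.b * _S_MM2_PER_MS_UM2,
                    "group": m.group,
                    "effective_diffusion_time_ms": m.effective_diffusion_time,
                }
            )
        Path(path).write_text(json.dumps(records, indent=2))

    @classmethod
    def paper_protocol(cls) -> "AcquisitionScheme":
        """The bundled rectal-cancer td-dMRI protocol.

        25 Hz one-cycle OGSE at b = 0/350/710 s/mm^2, 40 Hz two-cycle OGSE
        at b = 0/150/315 s/mm^2, and PGSE with delta/Delta = 54.3/59.3 ms at
        b = 0/350/710 s/mm^2.
        """
        ref = resources.files("tddmri.data").joinpath("paper_protocol.json")
        records = json.loads(ref.read_text())
        return cls([cls._from_record(r) for r in records])
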