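"""Pathology-side microstructure from nucleus-level segmentation output.

Whole-slide nuclear segmentation yields per-nucleus areas and the total
delineated tissue area.  From these the module computes the MRI-comparable
morphometric quantities:

* volume-weighted nuclear diameter  d_nuclei = sum(d^4) / sum(d^3),
  emphasizing volume-dominant cells to match diffusion MRI's sensitivity;
* cell diameter = 1.8 * d_nuclei (fixed nucleus-to-cell scaling);
* intracellular fraction = (sum(A_nuclei) / A_tissue)^(3/2), lifting the
  2-D area ratio to a 3-D volume fraction;
* pathologic cellularity = 100 * intracellular fraction / cell diameter.

All inputs are in um / um^2 — the caller applies the slide's
microns-per-pixel factor upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

NUCLEUS_TO_CELL_SCALE = 1.8
DEFAULT_MIN_CELLS = 20_000


@dataclass(frozen=True)
class NucleusTable:
    """Per-nucleus morphometry plus the tissue context of one slide ROI."""

    areas: np.ndarray          # um^2, one entry per nucleus
    tissue_area: float         # um^2
    diameters: np.ndarray | None = None  # um, optional direct measurements

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if len(areas) < 1:
            raise ValueError("need at least one nucleus")
        if np.any(areas <= 0) or self.tissue_area <= 0:
            raise ValueError("areas must be positive")
        if areas.sum() > self.tissue_area:
            raise ValueError("total nuclear area exceeds tissue area")
        object.__setattr__(self, "areas", areas)

    @property
    def n_cells(self) -> int:
        return len(self.areas)

    @classmethod
    def from_csv(cls, path: str | Path, tissue_area: float) -> "NucleusTable":
        """Read a per-nucleus CSV with columns nucleus_id, area_um2[, diameter_um]."""
        df = pd.read_csv(path)
        diam = df["diameter_um"].to_numpy() if "diameter_um" in df else None
        return cls(areas=df["area_um2"].to_numpy(), tissue_area=tissue_area, diameters=diam)


@dataclass(frozen=True)
class PathologyMicrostructure:
    """Slide-level morphometric parameters, MRI-comparable by construction."""

    d_nuclei: float              # volume-weighted nuclear diameter, um
    cell_diameter: float         # 1.8 * d_nuclei, um
    intracellular_fraction: float
    cellularity: float           # 100 * fraction / cell diameter
    n_cells: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def volume_weighted_diameter(diameters: np.ndarray) -> float:
    """sum(d^4)/sum(d^3) over nuclei; always >= the arithmetic mean."""
    d = np.asarray(diameters, dtype=float)
    if len(d) == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    return float(np.sum(d**4) / np.sum(d**3))


def diameters_from_areas(areas: np.ndarray) -> np.ndarray:
    """Equivalent-circle diameters d = 2*sqrt(A/pi) from 2-D nuclear areas."""
    a = np.asarray(areas, dtype=float)
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    return 2.0 * np.sqrt(a / np.pi)


def intracellular_fraction(total_nuclear_area: float, tissue_area: float) -> float:
    """(area ratio)^(3/2), lifting the 2-D fill factor to a volume fraction."""
    if total_nuclear_area <= 0 or tissue_area <= 0:
        raise ValueError("areas must be positive")
    ratio = total_nuclear_area / tissue_area
    if ratio > 1:
        raise ValueError("nuclear area exceeds tissue area")
    return float(ratio**1.5)


def pathologic_cellularity(fraction: float, cell_diameter: float) -> float:
    """100 * intracellular fraction / cell diameter (um^-1 convention)."""
    if cell_diameter <= 0:
        raise ValueError("cell diameter must be positive")
    return 100.0 * fraction / cell_diameter


def validate_cell_count(n: int, threshold: int = DEFAULT_MIN_CELLS) -> bool:
    """True when the ROI contains at least ``threshold`` segmented cells."""
    if n < 0:
        raise ValueError("cell count must be >= 0")
    return n >= threshold


def pathology_microstructure(
    table: NucleusTable, scale: float = NUCLEUS_TO_CELL_SCALE
) -> PathologyMicrostructure:
    """Full slide-level chain from a nucleus table to MRI-comparable values."""
    diam = table.diameters if table.diameters is not None else diameters_from_areas(table.areas)
    d_nuc = volume_weighted_diameter(diam)
    cell_d = scale * d_nuc
    frac = intracellular_fraction(float(np.sum(table.areas)), table.tissue_area)
    return PathologyMicrostructure(
        d_nuclei=d_nuc,
        cell_diameter=cell_d,
        intracellular_fraction=frac,
        cellularity=pathologic_cellularity(frac, cell_d),
        n_cells=table.n_cells,
    )


def mri_pathology_correlation(mri_values, pathology_values) -> tuple[float, float]:
    """Pearson r and two-sided t-based p between paired MRI and slide values."""
    x = np.asarray(mri_values, dtype=float)
    y = np.asarray(pathology_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
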