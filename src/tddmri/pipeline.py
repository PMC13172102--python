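"""High-level runs tying the pipeline together.

These functions are the package's operational entry points — each one
loads or generates its inputs, executes one stage end to end, and writes
its artifacts (JSON reports, CSV tables, NIfTI maps) together with the
resolved configuration and seed so every artifact is reproducible.
The ``examples/`` scripts are thin narrative wrappers around them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gpa import DEFAULT_D_IN, intracellular_attenuation
from .histomorphometry import NucleusTable, pathology_microstructure, validate_cell_count
from .mapping import FitConfig, fit_volume, summarize_roi
from .montecarlo import simulate_sphere_signal
from .scheme import AcquisitionScheme
from .stats import (
    group_compare_table,
    logistic_backward_stepwise,
    logistic_univariable,
    roc_analysis,
)
from .synthetic import CohortSpec, PhantomTruth, generate_cohort, generate_phantom, table1_fixture


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    Emitted alongside every run's outputs; combined with the seed it makes
    each artifact reproducible.
    """

    scheme_path: str | None = None  # None -> bundled protocol
    d_in: float = DEFAULT_D_IN
    fit: FitConfig = field(default_factory=FitConfig)
    snr: float = 50.0
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.d_in <= 0:
            raise ValueError("d_in must be positive")

    def scheme(self) -> AcquisitionScheme:
        if self.scheme_path is None:
            return AcquisitionScheme.paper_protocol()
        return AcquisitionScheme.from_json(self.scheme_path)

    def dump(self, out_dir: Path) -> None:
        payload = dataclasses.asdict(self)
        payload["version"] = __version__
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "run_config.json").write_text(json.dumps(payload, indent=2))


def run_model_validation(
    config: RunConfig | None = None,
    diameters=(8.0, 12.0, 20.0),
    n_walkers: int = 200_000,
    step_time: float = 0.01,
    write: bool = True,
) -> dict:
    """Analytic-model validation against the Monte-Carlo oracle.

    For each diameter and each protocol waveform, simulates the restricted
    sphere signal and reports the relative discrepancy of ln S against the
    Gaussian-phase evaluation at every nonzero b.  Returns (and optionally
    writes) a JSON-able report; the headline field ``max_rel_discrepancy``
    summarizes the whole grid.
    """
    cfg = config or RunConfig()
    scheme = cfg.scheme()
    records = []
    # one simulation per (diameter, waveform): phase integrals are shared by
    # all b-values of a diffusion-time group
    for d in diameters:
        for label, idx in scheme.groups.items():
            meas = [scheme.measurements[i] for i in idx]
            bvals = [m.b for m in meas if m.b > 0]
            res = simulate_sphere_signal(
                d,
                cfg.d_in,
                meas[-1],
                n_walkers=n_walkers,
                step_time=step_time,
                seed=cfg.seed,
                b_values=bvals,
            )
            for b, s_mc, se in zip(res.b_values, res.signal, res.stderr):
                ln_mc = float(np.log(s_mc))
                ln_gpa = float(
                    np.log(intracellular_attenuation(d, cfg.d_in, meas[-1].with_b(b)))
                )
                records.append(
                    {
                        "diameter_um": d,
                        "group": label,
                        "b_ms_um2": float(b),
                        "ln_s_mc": ln_mc,
                        "ln_s_mc_stderr": float(se / s_mc),
                        "ln_s_gpa": ln_gpa,
                        "rel_discrepancy": abs(ln_gpa - ln_mc) / abs(ln_mc),
                    }
                )
    report = {
        "seed": cfg.seed,
        "n_walkers": n_walkers,
        "step_time_ms": step_time,
        "records": records,
        "max_rel_discrepancy": max(r["rel_discrepancy"] for r in records),
    }
    if write:
        out = Path(cfg.out_dir)
        cfg.dump(out)
        (out / "model_validation.json").write_text(json.dumps(report, indent=2))
    return report


def run_phantom_fit(config: RunConfig | None = None, write: bool = True):
    """Simulate the default two-region phantom and fit it back.

    Returns ``(maps, truth, roi_summaries)``; optionally writes the
    parametric maps as NIfTI and the region ROI summaries as CSV.
    """
    cfg = config or RunConfig()
    scheme = cfg.scheme()
    truth = PhantomTruth.two_region_default()
    signals = generate_phantom(truth, scheme, snr=cfg.snr, seed=cfg.seed)
    maps = fit_volume(signals, truth.mask, scheme, cfg.fit)
    rows = []
    summaries = {}
    for region, region_mask in truth.regions.items():
        summary = summarize_roi(maps, region_mask, patient_id="phantom", reader_id=region)
        summaries[region] = summary
        for name, value in summary.values.items():
            rows.append(
                {"patient_id": "phantom", "reader_id": region, "parameter": name, "value": value}
            )
    if write:
        out = Path(cfg.out_dir)
        cfg.dump(out)
        maps.save_nifti(out / "maps")
        pd.DataFrame(rows).to_csv(out / "roi_summaries.csv", index=False)
    return maps, truth, summaries


def run_cohort_stats(
    cohort: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    features: tuple[str, ...] = ("icvf", "cellularity", "adc_pgse", "relative_adc_25hz"),
    write: bool = True,
) -> dict:
    """The predictive-statistics stage on a cohort table.

    With no cohort given, generates the default synthetic one.  Produces
    the group-comparison table, univariable odds ratios, the backward-
    stepwise multivariable model, per-feature ROC analyses, and the
    published-count EMVI fixture analysis (2x2 odds ratio and binary ROC).
    """
    cfg = config or RunConfig()
    if cohort is None:
        cohort = generate_cohort(seed=cfg.seed)
    report: dict = {"seed": cfg.seed, "n": int(len(cohort))}

    table = group_compare_table(cohort, list(features), categorical=["emvi"])
    report["group_table"] = table.to_dict(orient="records")

    uni = {}
    for feat in features + ("emvi",):
        fit = logistic_univariable(cohort, feat)
        term = fit[feat]
        uni[feat] = {
            "odds_ratio": term.odds_ratio,
            "ci": list(term.ci),
            "p": term.p,
        }
    report["univariable"] = uni

    candidates = [f for f in features + ("emvi",) if uni[f]["p"] < 0.05]
    if candidates:
        final, full = logistic_backward_stepwise(cohort, candidates)
        report["stepwise"] = {
            "candidates": candidates,
            "retained": [t for t in final.retained],
            "final_terms": {
                name: {"odds_ratio": t.odds_ratio, "ci": list(t.ci), "p": t.p}
                for name, t in final.terms.items()
            },
            "full_terms": {
                name: {"odds_ratio": t.odds_ratio, "ci": list(t.ci), "p": t.p}
                for name, t in full.terms.items()
            },
        }

    rocs = {}
    for feat in features:
        r = roc_analysis(cohort[feat], cohort["lvi"])
        rocs[feat] = {
            "auc": r.auc,
            "ci": list(r.ci),
            "cutoff": r.cutoff,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
        }
    report["roc"] = rocs

    # published-count EMVI fixture: exactly recomputable
    fixture = table1_fixture()
    exposure, outcome = fixture.expand()
    emvi_df = pd.DataFrame({"emvi": exposure, "lvi": outcome})
    fit = logistic_univariable(emvi_df, "emvi")
    r = roc_analysis(exposure, outcome)
    report["emvi_fixture"] = {
        "odds_ratio": fit["emvi"].odds_ratio,
        "ci": list(fit["emvi"].ci),
        "auc": r.auc,
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
    }

    if write:
        out = Path(cfg.out_dir)
        cfg.dump(out)
        (out / "cohort_stats.json").write_text(json.dumps(report, indent=2))
        table.to_csv(out / "group_table.csv", index=False)
    return report


def run_histomorphometry(
    table: NucleusTable,
    config: RunConfig | None = None,
    min_cells: int | None = None,
    write: bool = True,
) -> dict:
    """Slide-level morphometry from a nucleus table, with the cell-count gate."""
    cfg = config or RunConfig()
    result = pathology_microstructure(table)
    record = dataclasses.asdict(result)
    record["cell_count_ok"] = validate_cell_count(
        table.n_cells, min_cells if min_cells is not None else 20_000
    )
    if write:
        out = Path(cfg.out_dir)
        cfg.dump(out)
        (out / "histomorphometry.json").write_text(json.dumps(record, indent=2))
    return record
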