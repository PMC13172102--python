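"""Simulate a noisy two-region phantom and recover its microstructure.

The phantom's 'tumor' disk and 'background' rim carry the two cohort
groups' median microstructure; signals are Rician-corrupted at SNR 50,
fitted voxel by voxel, and summarized per region.
"""

from tddmri.mapping import FitConfig
from tddmri.pipeline import RunConfig, run_phantom_fit

cfg = RunConfig(
    seed=11,
    snr=50.0,
    out_dir="results/example_phantom",
    fit=FitConfig(d_grid_step=0.5),  # coarser signal table, faster demo
)
maps, truth, summaries = run_phantom_fit(cfg)

truth_vals = {"tumor": (0.334, 12.808, 2.341), "background": (0.212, 11.812, 2.425)}
print(f"{'region':>10} {'icvf':>14} {'d (um)':>16} {'D_ex':>14}")
for region, s in summaries.items():
    tv = truth_vals[region]
    print(f"{region:>10} {s['icvf']:>7.3f} ({tv[0]:.3f}) {s['d']:>8.2f} ({tv[1]:.2f}) "
          f"{s['d_ex']:>7.3f} ({tv[2]:.3f})")
print("\n(truth in parentheses) Region means recover the simulated contrast: "
      "the denser 'tumor' shows higher icvf and cellularity, the separation the "
      "cohort statistics exploit.  Maps were written as NIfTI under "
      f"{cfg.out_dir}/maps/.")
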