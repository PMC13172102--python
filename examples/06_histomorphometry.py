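"""Slide-level nuclear morphometry and its MRI-comparable outputs.

Builds a synthetic nucleus table (areas in um^2 plus the delineated
tissue area), applies the volume-weighted diameter, nucleus-to-cell
scaling, intracellular-fraction and cellularity formulas, and correlates
paired synthetic MRI/pathology values.
"""

import numpy as np

from tddmri.histomorphometry import (
    NucleusTable,
    mri_pathology_correlation,
    pathology_microstructure,
    validate_cell_count,
)

rng = np.random.default_rng(0)
# log-normal nuclear areas around ~40 um^2, 20% tissue fill
areas = rng.lognormal(np.log(40.0), 0.4, 25_000)
table = NucleusTable(areas=areas, tissue_area=areas.sum() / 0.20)
out = pathology_microstructure(table)

print(f"nuclei: {table.n_cells} (count gate >= 20000: "
      f"{validate_cell_count(table.n_cells)})")
print(f"volume-weighted nuclear diameter: {out.d_nuclei:.3f} um")
print(f"cell diameter (x1.8 scaling):     {out.cell_diameter:.3f} um")
print(f"intracellular fraction:           {out.intracellular_fraction:.4f}")
print(f"pathologic cellularity:           {out.cellularity:.4f}")

# paired synthetic MRI/pathology values sharing a common latent factor
latent = rng.normal(0, 1, 20)
mri_icvf = 0.27 + 0.05 * latent + rng.normal(0, 0.03, 20)
path_frac = 0.09 + 0.02 * latent + rng.normal(0, 0.012, 20)
r, p = mri_pathology_correlation(mri_icvf, path_frac)
print(f"\nPearson r between MRI icvf and pathologic fraction: {r:.3f} (p={p:.4f})")
print("The volume-weighted diameter emphasizes volume-dominant cells, matching "
      "what diffusion MRI is sensitive to; the correlation quantifies the "
      "MRI-pathology agreement on paired cases.")
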