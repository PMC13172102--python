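"""Evaluate the two-compartment forward model on the bundled protocol.

Builds the 9-measurement OGSE/PGSE scheme, evaluates the normalized signal
of a voxel at the published median tumor microstructure, and shows the
diffusion-time dependence that makes cell size measurable.
"""

from tddmri import AcquisitionScheme, TwoCompartmentParams, impulsed_forward

scheme = AcquisitionScheme.paper_protocol()
params = TwoCompartmentParams(icvf=0.334, d=12.808, d_ex=2.341)

signals = impulsed_forward(params, scheme)
print(f"voxel: icvf={params.icvf}, d={params.d} um, D_ex={params.d_ex} um^2/ms, "
      f"D_in={params.d_in} um^2/ms (fixed); cellularity={params.cellularity:.3f}")
print(f"{'group':>6} {'b (ms/um^2)':>12} {'S/S0':>8}")
for m, s in zip(scheme, signals):
    print(f"{m.group:>6} {m.b:>12.3f} {s:>8.4f}")

s_pgse = {m.b: s for m, s in zip(scheme, signals) if m.group == "PGSE" and m.b > 0}
s_25 = {m.b: s for m, s in zip(scheme, signals) if m.group == "25HZ" and m.b > 0}
print("\nAt equal b the PGSE signal exceeds the 25 Hz OGSE signal "
      f"(e.g. b=0.71: {s_pgse[0.71]:.4f} vs {s_25[0.71]:.4f}): restricted water "
      "looks slower at long diffusion times, so ADC rises with oscillation "
      "frequency — the signature the voxel fit inverts to estimate cell size.")
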