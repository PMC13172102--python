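"""Diffusion-time-resolved ADCs and the derived relative metrics.

Computes per-group ADCs from one voxel's signals on the bundled protocol
and derives the relative/ratio metrics used as cohort features.
"""

from tddmri import AcquisitionScheme, TwoCompartmentParams, impulsed_forward
from tddmri.mapping import compute_adc, relative_adc_metrics

scheme = AcquisitionScheme.paper_protocol()
params = TwoCompartmentParams(icvf=0.334, d=12.808, d_ex=2.341)
signals = impulsed_forward(params, scheme)

adcs = {}
for label, idx in scheme.groups.items():
    b = [scheme.measurements[i].b for i in idx]
    adcs[label] = compute_adc(b, signals[idx])
    print(f"ADC_{label:<5} = {adcs[label]:.4f} um^2/ms")

m = relative_adc_metrics(adcs["PGSE"], adcs["25HZ"], adcs["40HZ"])
print(f"relative ADC_25HZ  = {m.relative_adc_25hz:.4f}")
print(f"relative ADC_40HZ  = {m.relative_adc_40hz:.4f}")
print(f"ADC_25HZ/ADC_40HZ  = {m.ratio_25_40:.4f}")
print(f"ADC_25HZ/ADC_PGSE  = {m.ratio_25_pgse:.4f}")
print(f"ADC_40HZ/ADC_PGSE  = {m.ratio_40_pgse:.4f}")
print("\nOGSE ADCs exceed the PGSE ADC in restricted tissue; the relative "
      "metrics quantify that diffusion-time dependence per voxel and rise "
      "with cell density.")
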