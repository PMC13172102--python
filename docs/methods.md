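# Methods

## Signal model

A voxel is modelled as two non-exchanging water pools. The intracellular
pool is water restricted inside impermeable spheres of diameter d with
intrinsic diffusivity D_in; the extracellular pool is hindered Gaussian
diffusion with diffusivity D_ex. The normalized signal is

    S/S0 = f_in · S_sphere(b, waveform; d, D_in) + (1 − f_in) · exp(−b · D_ex)

with f_in the intracellular volume (signal) fraction, reported as ICVF.
Cellularity is defined as 100 · ICVF / d (units 1/μm in the ×100
convention). Units throughout: μm, ms, μm²/ms, b in ms/μm²
(1000 s/mm² = 1 ms/μm²). Gradient amplitudes always carry the
gyromagnetic ratio and are derived from b, so γ cancels from every
observable.

`S_sphere` is evaluated under the Gaussian phase approximation (GPA) with
the reflecting-sphere eigenmode basis: μ_k are the positive roots of
j₁′(μ) = 0 (μ₁ ≈ 2.0815760), mode rates a_k = μ_k² D_in/R², weights
B_k = 2(R/μ_k)²/(μ_k² − 2), R = d/2. Two equivalent evaluations are
implemented and cross-checked:

* **PGSE closed form** (Murday–Cotts) for two rectangular lobes of
  duration δ separated by Δ;
* **spectral form** for arbitrary waveforms, used for cosine OGSE:
  ln S = −(1/2π)∫|F(ω)|² ReD(ω) dω, where F is the Fourier transform of
  the phase weighting q(t) = ∫γg dt and
  ReD(ω) = Σ_k B_k a_k ω²/(a_k² + ω²) is the sphere's dispersive
  diffusivity. With a constant spectrum this reduces exactly (Parseval)
  to ln S = −bD, which is used as a quadrature self-test.

Assumptions: ideal rectangular/cosine waveforms (no ramps — vendor ramp
times are unpublished), no exchange, no relaxation differences between
compartments beyond what per-group normalization removes, monodisperse
spheres per voxel.

### Monte-Carlo oracle

An independent random-walk simulator provides ground truth: walkers start
uniformly in the sphere, take fixed-length isotropic steps
ℓ = √(6 D_in Δt) (Marsaglia direction sampling), reflect off the boundary
by mirroring the radial overshoot about the surface (re-reflected until
inside), and accumulate phase as the trapezoid of the gradient-weighted
z-coordinate. The magnitude signal is ⟨cos φ⟩ with standard error from
the sample variance. Because phase is linear in gradient amplitude, one
walker ensemble serves every b-value of a waveform shape. The inner loop
uses an inline xorshift128+ generator (splitmix64-seeded): random draws
dominate the per-step cost and the inline generator is ~4× faster than
the library RNG while remaining exactly reproducible for a fixed seed.
Fixed-length (rather than Gaussian) steps are a standard variance-free
choice validated by the free-diffusion limit. Defaults: 2×10⁵ walkers,
Δt = 0.005 ms; the precondition ℓ ≤ R/10 guards boundary resolution.

Agreement between the GPA and the oracle is ≤ 2% of |ln S| over the
bundled protocol at d ∈ {8, 12, 20} μm; the residual discrepancy (~1% at
d = 20 μm, 25 Hz) is the expected GPA truncation error at stronger
dephasing, not Monte-Carlo noise.

## Acquisition protocol

The bundled scheme has three diffusion-time groups: 25 Hz one-cycle
cosine OGSE (b = 0/350/710 s/mm²), 40 Hz two-cycle cosine OGSE
(b = 0/150/315 s/mm²), and PGSE with δ/Δ = 54.3/59.3 ms
(b = 0/350/710 s/mm²) — nine measurements in total. OGSE lobe durations
are not published; they default to n_cycles/frequency (40 ms at 25 Hz,
50 ms at 40 Hz) and the lobes are placed back-to-back (Δ = δ): for
integer-cycle cosine lobes q(t) returns to zero at each lobe end, so the
inter-lobe gap does not affect b and has only a phase-factor effect on
the spectrum. Vendor-reported effective diffusion times (7.3/4.7/41.1 ms)
do not match 1/(4f) for a pure cosine (the vendor waveform is likely
apodised); they are stored as metadata and never used in computation.

D_in is fixed at 1.56 μm²/ms (configurable), the common in-vivo choice
for this model family; it is not identifiable from two frequencies at
these b-values and fixing it is standard practice.

## Voxel fitting

Signals are normalized per diffusion-time group by that group's b = 0
measurement — robust to group-wise T2/TE scale differences. Bounded
nonlinear least squares (trust-region reflective) minimizes
Σ(S_model − S_obs)² over (ICVF, d, D_ex), with bounds ICVF ∈ [0, 1],
d ∈ [2, 30] μm, D_ex ∈ [0.1, 3.5] μm²/ms. The objective is first
evaluated on a 4×4×4 grid over the box midspans and the best four cells
are polished; the best local optimum wins. The fit is fully deterministic
given the configuration. Voxels with any normalized signal ≤ 0 or > 1.2
(noise floor) are flagged rather than clipped. For speed the sphere
signal of each measurement is pre-tabulated over a 0.1 μm diameter grid
and interpolated with a cubic spline (interpolation error orders of
magnitude below solver tolerance). ADCs are log-linear regressions over
all b in a group by default (two-point form available); relative metrics
follow the printed definitions, e.g. relative ADC_25HZ =
(ADC_25HZ − ADC_PGSE)/ADC_PGSE.

Recovery precision at SNR 50 under this protocol (500 voxels uniform in
ICVF ∈ [0.1, 0.5], d ∈ [8, 20] μm, D_ex ∈ [1.5, 3.0] μm²/ms): median
absolute errors ≈ 0.03–0.04 for ICVF and ≈ 0.2 μm²/ms for D_ex. Cell
diameter is the weakest-determined parameter — median absolute error
≈ 2.2–2.9 μm depending on whether the b = 0 reference is itself noisy —
because the maximum b of 0.71 ms/μm² and the 25/40 Hz frequency range
carry limited size information at low ICVF and large d (about 9% of fits
run to the upper diameter bound). This is a noise-information limit, not
an optimizer artifact: multiplying start points does not reduce it. At
the published median tumor microstructure the median recovered diameter
is unbiased well within 2 μm.

ROI summaries are single-slice means over analyzed voxels (the analysis
convention is the tumor's largest cross-section); reader averaging is the
arithmetic mean of two readers' summaries. Cellularity is computed
per-voxel and then averaged.

## Histomorphometry

Volume-weighted nuclear diameter Σd⁴/Σd³ (≥ the arithmetic mean, equality
iff constant); equivalent-circle diameters d = 2√(A/π) when only areas
are available; cell diameter = 1.8 × nuclear diameter; intracellular
fraction = (ΣA_nuclei/A_tissue)^{3/2}, lifting the 2-D fill factor to a
volume fraction; pathologic cellularity = 100 × fraction / diameter. All
inputs are in μm/μm² (the caller applies the slide's microns-per-pixel
factor); a count gate (default ≥ 20000 cells) guards against unstable
small-ROI estimates. Nuclear segmentation itself is upstream of this
package — it consumes the tabular export.

## Statistics

* Mann–Whitney U: exact permutation enumeration when both n ≤ 8,
  otherwise the tie-corrected continuity-corrected normal approximation.
* Logistic regression: maximum likelihood (statsmodels), Wald intervals
  exp(β ± 1.96·SE) — the convention that reproduces the published EMVI
  interval from the 2×2 counts. For a binary predictor the fitted OR
  equals the cross-product ratio exactly. Complete separation is flagged
  rather than reported as a finite estimate.
* Backward stepwise selection removes the largest Wald p ≥ 0.05 (the
  removal α is configurable; 0.10 is the common package default) and
  refits until all retained terms are significant; both the full and the
  final model are reported, since published tables often show statistics
  for eliminated terms from the pre-elimination model.
* ROC: empirical, with candidate cutoffs at midpoints between distinct
  scores; the AUC is computed from placement values and is therefore
  identically the tie-adjusted Mann–Whitney statistic; Youden-optimal
  cutoff with ties broken toward higher specificity; AUC confidence
  intervals and paired AUC comparison by DeLong's placement-value
  covariance.
* Agreement: ICC(2,1) — two-way random effects, absolute agreement,
  single rater (the form chosen where the convention is unstated) with
  F-based CI via pingouin, plus Bland–Altman bias ± 1.96 SD.
* Group tables route continuous features by Shapiro–Wilk (α = 0.05 in
  both groups) to t-test/mean ± SD or Mann–Whitney/median (IQR);
  categorical features use χ².

## Synthetic data

The phantom generator evaluates the forward model per voxel on labelled
2-D parameter regions (defaults: a "tumor" disk at the LVI-positive
group's median microstructure — ICVF 0.334, d 12.808 μm, D_ex 2.341 —
over a "background" rim at the LVI-negative medians) and corrupts
magnitudes with Rician noise, S_noisy = √((S + ε₁)² + ε₂²),
σ = S(b=0)/SNR, default SNR 50.

The cohort generator draws 30 + 54 patients whose per-group marginals
match the published summaries exactly: mean ± SD features use
zero-truncated normals; median (IQR) features use shifted three-parameter
log-normals solved in closed form from the three quantiles (reflected
when the printed quartiles are left-skewed — a plain two-parameter
log-normal cannot match both IQR endpoints and is right-skewed only).
Features are coupled by a Gaussian copula; the default correlations
(ICVF–cellularity 0.8, ICVF–ADC_PGSE −0.5, others 0) are conventions —
the true inter-feature correlations are unpublished — chosen because
cellularity is functionally tied to ICVF and ADC falls with cell density.
EMVI is Bernoulli at the published per-group prevalences (21/30, 13/54),
and the outcome label is group membership itself, so downstream
predictive statistics have known truth.

What a green test on this synthetic world does establish: correctness of
the formulas, fit machinery, selection behavior and operating-point
logic under the published effect sizes. What it does not: cohort-level
AUCs/cutoffs for continuous parameters (these depend on the real joint
feature distribution, and the patient data are unavailable), scanner
artifacts, partial-volume and anatomy effects.

## Numerical choices

* Eigenmode truncation k_max = 40; the last term must contribute < 1e-6
  of the sum or the evaluation raises. The partial sums of 1/(μ_k² − 2)
  increase monotonically to 1/2 with remainder ≈ 1/(π²k) — 2.0e-3 at 50
  modes — which the tests assert as the exact tail law.
* Spectral quadrature: uniform 0.01 ms step, FFT zero-padded to ≥ 8× the
  waveform duration (next power of two); halving the step changes ln S by
  < 0.1%; free-diffusion exactness holds to 1e-4 relative.
* Tie handling in ROC cutoffs: thresholds at midpoints between distinct
  scores plus ±∞ sentinels.
* All stochastic procedures take explicit integer seeds; identical seeds
  give bit-identical outputs (the Monte-Carlo kernel uses its own inline
  PRNG precisely so that reproducibility does not depend on library RNG
  internals).

## Known limitations

* Trapezoidal/apodised gradient ramps, compartment exchange, IVIM
  perfusion, non-spherical geometries and higher-order (kurtosis) terms
  are out of scope.
* Cell diameter at SNR 50 under this protocol is determined to ~±2–3 μm
  per voxel (see above); region medians are much tighter.
* The GPA itself biases |ln S| by up to ~1–1.5% at the largest diameters
  and frequencies tested, within the stated 2% oracle band.
* Cohort-level diagnostic metrics for continuous parameters are not
  reproducible without the original patient data; the package reproduces
  exactly the analyses that are functions of published counts.
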