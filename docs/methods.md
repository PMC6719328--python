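# Methods

## Tissue model

The signal model is the abbreviated clinical VERDICT variant for brain
tumours: two compartments, fitted independently per voxel.

* **Restricted sphere (intracellular).** PGSE signal for spins inside an
  impermeable sphere of radius R, via the Gaussian-phase-distribution
  (GPD, Murday–Cotts) series over the Neumann sphere roots α_m (roots of
  d/dx j₁(x) = 0, computed by bracketed root-finding). The series is
  truncated at M = 20 roots; evaluation enforces a tail bound (last term
  < 1e-6 of the leading term) and raises rather than silently returning
  an under-converged value. M = 20 satisfies the bound for all shells of
  the five-shell protocol and R ∈ [1, 15] μm.
* **Ball (combined extracellular/vascular).** exp(−b·d). The two spaces
  are merged deliberately: at clinical gradient amplitudes (~45–80 mT/m)
  a separately fitted vascular fraction is unstable, so the pipeline
  never fits one. An astrosticks forward model is provided for
  completeness only.
* Fractions are non-negative and **not constrained to sum to one**; the
  fitted sum is itself a soft consistency diagnostic (observed ~0.93–1.01
  on synthetic data).

Fixed scalars: intracellular diffusivity d_ic = 2.0e-9 m²/s (a canonical
value for tumour cytometry models; it is not identifiable from a 5-shell
clinical acquisition and is exposed in the model config). The gyromagnetic
ratio defaults to the proton value 2.6752218744e8 rad s⁻¹ T⁻¹,
configurable.

## Acquisition protocol

The built-in five-shell protocol (nominal b = 90, 500, 1500, 2000,
3000 s/mm², each with its own paired b=0 at the same TE, 8 averages,
2 mm isotropic) stores the printed pulse parameters (Δ, δ, |G|, TE).
All computation uses the Stejskal–Tanner b recomputed from those
parameters, b = γ²G²δ²(Δ − δ/3), because the restricted compartment
depends on Δ and δ separately and the forward model must be
self-consistent with the weighting. Two printed rows are not consistent
with their nominal b (b=90 computes to ≈85, and b=2000 to ≈2978 s/mm²);
`validate_protocol` flags them (default tolerance 5%, separating printed
rounding of <1% from genuine inconsistency) and the pipeline proceeds by
trusting timings + |G|. A consequence worth knowing: the "2000" and
"3000" shells have nearly equal b at different (Δ, δ), which is exactly
the timing contrast that makes the radius identifiable — and also why the
signal is not monotone in b across all five shells.

Scheme files are Camino-style `VERSION: STEJSKALTANNER` tables (SI units,
one row per diffusion-weighted shell) with a comment header carrying the
nominal b, averages and paired-b0 structure; arbitrary shell counts are
supported (e.g. 40-measurement extended protocols).

## Dictionary fit

Sphere atoms on a 1–15 μm radius grid in 0.5 μm steps (covers the
reported 3.1–11 μm glioma range with margin); ball atoms on a
0.5–3.0 μm²/ms diffusivity grid in 0.25 μm²/ms steps. The ball grid
replaces a single fixed extracellular diffusivity because tumour d_ees is
unknown a priori; with a coarser grid (0.5 steps) the unrepresentable
part of an intermediate exponential leaks into the sphere atoms and
biases f_ic by about −0.01, which the 0.25 step removes (noiseless bias
≤ 0.002).

Per voxel: min_{w≥0} ‖Dw − s‖² + λ‖w‖², solved exactly by NNLS on the
Tikhonov-augmented system. λ defaults to 1e-4 — the smallest weight that
conditions the augmented system; at 1e-3 the shrinkage bias on noiseless
data (f_ic −0.03, R̂ +1 μm) already exceeds the fit's own recovery
tolerances, so stronger ridge is left as a config choice rather than a
default. R̂ is the plain weight-averaged radius over sphere atoms
(volume-weighting would be an alternative convention; the choice is
documented and switchable by post-processing the weights). Voxels with
zero sphere weight get R̂ = NaN; voxels whose dominant sphere atom sits on
the grid edge are flagged, not censored.

The dictionary rows include each shell's paired b=0 row (atoms = 1,
normalised data = 1). These are genuine measurements; keeping them lets
the data softly inform f_ic + f_ec ≈ 1 without imposing any constraint.

### Magnitude-noise handling

Each shell is normalised by its own b=0 volume (the shells are acquired
at different TEs, so their T2 weightings differ; the per-shell b0 removes
this). Before normalisation the pipeline subtracts the Rician noise
floor: E[M²] = S² + 2σ² exactly, so ŝ = sqrt(max(M² − 2σ², 0)) with σ
estimated per volume from signal-free background voxels (Rayleigh mean
σ√(π/2)). Without this step the floor at the strongly attenuated high-b
shells masquerades as an unattenuated small-radius restricted component
and biases the whole-lesion radius median by about −1 μm at SNR 50.

## Monte-Carlo oracle

`verdict_mri.montecarlo` implements an independent random walk in an
impermeable sphere (radial reflection at the wall, trapezoidal phase
integration, numba-compiled, fully seeded): the numerical truth against
which the closed-form GPD signal is tested. An unbounded-walk mode
reproduces exp(−bD) and validates the walker core in isolation.

Known and deliberately exposed limitation: the GPD approximation
overestimates the signal once the phase distribution stops being
Gaussian, roughly qR ≳ 2. For the five-shell protocol this happens for
R = 8–11 μm on the strongest shells (deviations of ~3–15%, confirmed
dt-converged in the walker); for R ≤ 5 μm and for the published tumour
radii (~6.7 μm) on every shell, agreement is within 2%. The fitted
radius maps inherit this model error at the large-radius end of the grid
— a property of the GPD-based VERDICT family generally, not of this
implementation.

## Synthetic cohort

The generator emulates what the clinical study measured, with ground
truth known:

* **Group presets** are truncated normals for f_ic, f_ec, R, cellularity
  and demographics, truncated at the published ranges. The location
  parameter is solved so that the *median* of the truncated distribution
  equals the published group value (published group statistics are
  medians; with asymmetric truncation a naive location = median choice
  would shift the generated median, e.g. HGG f_ic to ~0.149 instead of
  0.13).
* **Phantoms** are 32×32×16 voxel, 2 mm isotropic: a brain ellipsoid, an
  ellipsoidal tumour (jittered centre/axes) and an oedema rim; the
  whole-lesion ROI is tumour + oedema. Lesion parameter fields are
  spatially smooth (Gaussian-filtered white noise, correlation scale
  1.5 voxels — a free fixture choice; no within-tumour spatial statistics
  are published) but keep the preset marginals exactly via a Gaussian
  copula (standardised smooth field mapped through the truncated-normal
  quantile function). Normal brain gets fixed nominal values (f_ic 0.35,
  f_ec 0.62, R 5 μm, d_ees 0.9 μm²/ms).
* **Extracellular diffusivity** per grade is solved from the published
  two-point ADC at the group-median tissue parameters (LGG 1.22e-3 →
  d_ees ≈ 1.42e-9 m²/s; HGG 0.98e-3 → ≈ 1.21e-9 m²/s), tying the
  generator to the one diffusivity observable the study reports.
* **Signal simulation**: noiseless two-compartment forward signal per
  measurement, scaled by a shell-specific S0 = exp(−TE/T2) with T2 =
  100 ms (this is what makes per-shell b0 normalisation necessary), plus
  Rician noise of per-channel σ = S0_shell/SNR; default SNR 50. A
  separate clinical b=0/1000 pair (Δ=35 ms, δ=25 ms, |G| solved for
  b=1000 exactly) feeds the conventional ADC map.
* **Observer masks**: observer 1 is the true lesion; observer 2 comes
  from re-thresholding the signed boundary distance plus a smooth random
  field. The default perturbation (2.8 mm) is calibrated so the
  cohort-mean inter-observer Dice is ~0.89, the published overlap
  (calibration curve in `cohort.py`); this is a fixture calibration, not
  a validation claim.
* **Histology**: per-field cell counts from the cellularity preset
  (truncated at the published range — for LGG the published SD exceeds
  the mean, so an untruncated normal would be ill-posed); 20 cells per
  field with fresh-tissue radii scattered (15%) around the subject's
  ground-truth radius, shrunk by the red-blood-cell fixation factor
  5.5/7.6 ≈ 0.72, and converted to short/long axes with uniform
  eccentricity so that (short+long)/4 recovers the generating radius
  identically. Fresh-tissue truth is retained for shrinkage-correction
  tests.
* **Determinism**: one master seed; per-subject seeds spawned via
  `SeedSequence`. Identical config ⇒ byte-identical cohort, maps and
  report files (volumes are written as uncompressed `.nii` for exactly
  this reason).

What the generator does *not* emulate: realistic anatomy, partial
volume/CSF, motion or eddy artefacts, between-subject biological
variance (all subjects of a grade draw voxelwise from the same group
distribution, so between-subject spread reflects sampling only — group
medians are faithful; between-subject SDs and grade-contrast p-values
are optimistic relative to a real cohort). Passing recovery tests
therefore demonstrates that the forward model + fit are unbiased at the
published operating points, not that the pipeline is robust to
real-world confounds.

## Statistics

* Per-subject ROI value = median over the whole-lesion ROI; group tables
  report median with the SD of per-subject values ("median ± SD", the
  clinical reporting convention) and the mean alongside.
* Wilcoxon rank-sum: exact two-sided p by full enumeration of rank
  partitions (mid-ranks for ties) for pooled n ≤ 20 — the cohort's 7 vs 7
  comparisons are always exact; normal approximation with tie correction
  above.
* Kolmogorov–Smirnov normality: one-sample test against a normal with
  moments estimated from the data (the tabulated p is conservative under
  estimated moments, matching common clinical usage).
* Dice = 2|A∩B|/(|A|+|B|); two empty masks are an error, not 0.
* Histology cell radius = (short + long)/4 per cell (mean of semi-axes;
  the axis→radius convention is not standardised, so it is stated and
  used consistently on both the generator and analysis sides), averaged
  over the 20 cells of each 184 × 138 μm field.
* Fixation shrinkage = mean(fixed)/mean(fresh) red-blood-cell size, with
  a Wilcoxon p for the difference.

## Problem sizes and tolerances

Defaults are desk-scale: 32×32×16 phantoms (~2,500–3,000 lesion voxels),
7+7 subjects, SNR 50; a full simulate→fit→report cycle runs in seconds
per subject, and the recovery experiments reproduce the preset group
medians within ±0.02 (fractions), ±0.7 μm (radius) and ±0.05×10⁻³ mm²/s
(ADC). The Monte-Carlo oracle uses 1e5 spins and a time step capped at
min(δ/20, Δ/50, step length R/8), keeping discretisation bias a few
tenths of a percent.

## Known limitations

* GPD validity at large R × strong gradients (above); radius estimates
  near the top of the grid are flagged by the boundary indicator.
* d_ic is fixed, not fitted; mis-specification maps into correlated
  radius error.
* The per-voxel radius at SNR 50 is very noisy (the subject-level median
  is the reliable quantity); single-voxel R̂ should not be interpreted.
* The exact Wilcoxon enumerates C(n, n_a) partitions — fine to pooled
  n = 20, combinatorial beyond.
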