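# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind petquant, in the spirit of a package methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Time-activity curves and conventions

Frames are half-open intervals `[start, end)` in seconds, strictly
increasing and non-overlapping; gaps are legal (split acquisitions). All
numerics evaluate a curve at the frame midpoint. User-facing protocol
descriptions are in minutes. The F-18 half-life is fixed at 109.771 min.

Brain TACs are decay-corrected to injection time (kBq/mL); whole-body
dosimetry TACs are physical (not decay-corrected) and expressed as fraction
of injected activity, because cumulated activities integrate physical
radioactivity. `decay_correct` converts between the two and is an exact
involution; attempting to correct twice is a state error.

Cumulative TAC integrals use the trapezoid rule through `(0, 0)` and the
frame midpoints — a bolus injected at t = 0 implies no pre-injection
activity — and hold the last value constant beyond the last midpoint. Two
consequences worth knowing: an idealised curve that is constant from t = 0
loses half a first-frame of area to the anchor ramp, and a multi-segment
(coffee-break) schedule is bridged linearly between the midpoints flanking
the gap, which is the minimal assumption and is what the window-stability
tests exercise.

## Arterial input function

The input model is the convention for manually sampled bolus data: zero
before injection, linear rise to the peak sample, tri-exponential decay
after it, continuous at the peak (the peak value is the amplitude sum). The
ascending limb is not fitted — with samples every ~10 s it carries one or
two points — and the tri-exponential applies to post-peak samples only.
Fitting seeds a rate-grid search with non-negative linear amplitude solves
(NNLS) and polishes with bounded least squares in log-rate space; on exact
data this recovers generating parameters to ~1e-10 relative.

The parent fraction is `exp(-k_m t)`, anchored at 1 at injection (no
metabolites can exist at t = 0), fitted by bounded least squares; a
metabolite-free dataset yields exactly k_m = 0. The parent-plasma input is
`plasma(t) * exp(-k_m t)`, so parent ≤ total plasma pointwise with equality
iff k_m = 0.

Because every input segment is a ramp or exponential times an exponential,
both the running integral of the input and its convolution with
`exp(-alpha t)` have closed forms. These are evaluated exactly (anchored so
every exponent is non-positive, with series fallbacks near removable
singularities); the tests pin them against adaptive quadrature at 1e-8
relative. No discretisation grid is involved anywhere in the forward model.

The PET-vs-blood delay is estimated once per scan by a grid search over
±30 s in 0.5-s steps, minimising the duration-weighted residual of a
one-tissue fit to the first 5 min of the composite cortical TAC, and then
held fixed for all regions. The recovered delay is accurate to the grid
step (a half-step systematic offset can appear because the one-tissue
objective is deliberately misspecified against two-tissue data). A
contrast-free composite TAC cannot inform the delay; it warns and returns 0.
The plasma free fraction is carried as metadata only and never rescales VT.

## Compartment models

The measured concentration is
`(1 - vB) * C_tissue + vB * C_wholeblood` with vB fixed (default 0.05).
`C_tissue` is the convolution of the parent-plasma input with the 1TCM or
2TCM impulse response, computed analytically via the input's closed-form
convolution, so the forward model is exact on the non-uniform 31-frame grid
and a noiseless round trip recovers micro-parameters to optimizer precision
(the tests assert 0.5% on parameters and 0.1% on VT across random draws;
observed errors are ~1e-10).

Fits are bounded (K1 in (0, 2] mL/cm3/min, k2..k4 in (0, 1] /min),
multi-start (three dispersed starts, seed-jittered beyond the built-in
list), with uniform residual weights by default and optional frame-duration
or explicit (e.g. inverse-variance) weights. vB multiplies the fitted
whole-blood curve, the standard convention. AIC is the uncorrected
least-squares form `n ln(RSS/n) + 2k` with k = 2 (1TCM) or 4 (2TCM); vB and
the delay are fixed and not counted. Ties in model selection resolve to the
more parsimonious 1TCM. Irreversible models (k4 = 0 with k3 > 0) are out of
scope and rejected at validation.

## Logan graphical analysis

The transform uses the trapezoid tissue integral and the closed-form input
integral, both divided by the tissue value at the frame midpoint; the OLS
slope over midpoints at/after t* (default 40 min, applied to midpoints: the
first included point is the first midpoint ≥ t*) is reported as VT, the
intercept kept as a diagnostic. Points with non-positive tissue values are
dropped and counted. There is no blood-volume term in the graphical model
(standard formulation). Two systematic effects follow, and both are
documented rather than corrected:

* on noiseless reversible data the slope approaches VT from below as t*
  grows (for the bundled reference kinetics the residual bias at t* = 40 is
  under 2%, shrinking monotonically with t*);
* when the measured TAC contains a blood-volume fraction, the slope
  estimates approximately `(1 - vB) * VT`: with vB = 0.05 that is a ~5%
  underestimate. Accuracy checks against ground truth therefore use
  blood-free tissue curves, while test-retest, reliability and
  window-comparison analyses — ratios in which the near-constant `(1 - vB)`
  factor cancels — keep the 5% blood signal.

Acquisition windows keep the frames wholly inside their segments; on the
31-frame schedule the 0–60/90–120-min coffee-break window retains 28 frames
(25 + 3). The voxel-wise route vectorises the same transform; voxels with
non-positive activity at any included midpoint map to NaN and the NaN
fraction is reported. Regional means of the voxel map agree with
regional-TAC fits to within 1% on homogeneous noiseless phantoms (an
internal consistency oracle, since the two routes share no fitting code).

## Reproducibility statistics

TRV, aTRV, ICC, %COV and Bland-Altman follow the printed definitions
exactly; all sample statistics use the n−1 denominator (the cohorts are
small: 4 and 12). The ICC is the one-way random-effects form, BSMSS over
n − 1 degrees of freedom and WSMSS over n(k − 1) with k = 2; its range is
[−1, 1] and degenerate zero-variance input is an error rather than a NaN.
Bland-Altman limits are bias ± 1.96 SD of the paired differences.

## Dosimetry

The three organ-curve forms are parameterised by half-times with
exponential constant c, default ln 2 = 0.693147 (configurable to the
rounded 0.69 for literal replication of half-time tables). Fits use a
coarse half-time grid with NNLS amplitudes, then bounded least squares;
organs without a satisfactory parametric fit (gallbladder, testes, urinary
bladder in the emulated study) use the trapezoid NCA, whose tail beyond the
last sample assumes physical decay only — conservative, and exact when the
terminal half-time equals the physical one. The uptake-plateau form has a
divergent closed-form integral whenever its plateau amplitude is positive
(it cannot decay the plateau), so the analytic route refuses it and the
trapezoid route applies.

The ICRP-30 GI chain takes the fraction entering the small intestine as
input (the stomach compartment is bypassed for an intravenously injected,
biliary-excreted tracer), with biological transfer coefficients 6, 1.8 and
1 per day and physical decay added to every compartment; the three NCAs are
closed-form and linear in the input fraction, so cohort statistics of the
NCAs are exact transforms of the fraction statistics. Every NCA respects the
total-decay bound T½/ln 2 = 2.6395 h per unit injected.

Phantom S-value libraries are deliberately not bundled: organ doses are a
matrix contraction of NCAs with a user-supplied delimited-text S-matrix,
and the effective dose applies the bundled ICRP-60 weights (which sum to
1), with missing weighted tissues falling back to a supplied remainder
dose. Consequently an absolute effective-dose figure is only reproducible
with an external phantom library.

## Synthetic data

The generators emulate the study conditions end to end and every one is
reproducible from its seed.

* **Input**: plasma peak at 60 s, amplitudes (300, 80, 20) kBq/mL with
  decay rates (0.01, 0.002, 0.0002) /s, whole blood at 0.85 of plasma,
  parent-fraction rate 0.01/min (parent fraction ~0.55 at 60 min); samples
  every 10 s early thinning to 100 min, matching dense-early manual
  sampling.
* **Brain kinetics**: the 31-frame, 120-min schedule. The cohort profile
  pins regional VT to the published range (hippocampus 50.4 highest,
  brainstem 26.9 lowest) by adjusting k3 around a base parameter set
  (K1 = 0.5, k2 = 0.06, k3 = 0.35, k4 = 0.10; VT 37.5). The base was chosen
  so equilibration is fast enough that the graphical and compartmental
  estimates agree to ~1% at t* = 40 min, as they do in the emulated study;
  a slow-k4 alternative with the same VT was rejected because it produces a
  double-digit graphical underestimate that no published comparison shows.
  A separate, strongly biphasic reference set (K1 = 0.3, k2 = 0.15,
  k3 = 0.05, k4 = 0.02; VT 7) drives estimator-validation tests, where the
  one-tissue misfit must be visible above noise.
* **Noise**: Gaussian on frame values with variance proportional to
  `C(t) e^{lambda_phys t} / frame_duration` (count statistics of
  decay-corrected reconstructions), scaled so `noise_level` is the COV of
  the last frame (default 5%). Gaussian, not Poisson, is the standard
  approximation for reconstructed-frame TACs.
* **Cohorts**: a per-subject log-normal factor with 13% between-subject COV
  (unit mean), males scaled by 1.15; day-apart retest perturbs K1 (which
  carries into VT) and the input amplitudes (which does not) by 5%
  log-normal, modelling physiological plus procedural variability rather
  than pure measurement noise.
* **Whole body**: 13 scan times (11 to 90 min, then 150 and 270 min) as
  1-min frames; organ curves drawn from the three dosimetry forms with
  physical decay embedded, amplitudes set so analytic NCAs sit near the
  published organ values; the total body decays physically and the
  remainder follows by conservation, validated non-negative.
* **Phantom**: block-structured slabs, one homogeneous kinetic parameter
  set per slab, optional per-voxel noise; labels tile the volume exactly.

What passing tests on these data do **not** show: robustness to
reconstruction artefacts, motion, dispersion/delay structure beyond a pure
shift, violated noise models, atlas or segmentation error, or
inter-subject kinetic heterogeneity beyond a VT-level scaling — the
generators are deliberately well-specified for the models fitted to them.

## Problem sizes in the test suite

The statistical suites use sizes chosen to keep the full run in tens of
seconds while leaving the sampling error far from the asserted bounds:
20 noiseless draws for parameter recovery, 50 noisy replicates for the
graphical-vs-compartmental comparison, 200 for the AIC selection rate,
500 generator-level replicates for the ICC band, and a rendered 4-subject
test-retest study for pipeline-level aTRV and window stability.
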