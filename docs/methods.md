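# Methods

This note documents the models, algorithms and defaults implemented in
`raman_pcad`, the design choices that were genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## The problem setting

Dried-droplet Raman spectroscopy of CSF produces, per patient, a
handful of replicate spectra taken at the ring of the dried droplet.
The classification target is binary: healthy (H) versus preclinical
Alzheimer's disease (PC), i.e. biomarker-positive but cognitively
normal.  Two complications shape the whole workflow: the
class-discriminative signal is small relative to baseline drift,
multiplicative scatter and noise; and data acquired on different
cohorts in different years carry batch structure that can dominate the
class structure.

## Synthetic-study generator

`synthgen` emulates exactly the design features downstream stages
depend on, with known ground truth:

- **Design**: cohort 1 = 20 H + 20 PC, cohort 2 = 20 H + 15 PC
  (75 patients), 15 replicate spectra per patient.  These counts are
  the generator's invariant defaults.
- **Grid**: 600–1800 cm⁻¹ at 1 cm⁻¹.  The fingerprint region covers
  every marker band of interest; real instrument grids vary, and this
  choice is a stated default, not a measurement fact.
- **Peaks**: pseudo-Voigt profiles (50/50 Gaussian–Lorentzian, the
  conventional Raman band approximation; the pipeline's contracts do
  not depend on the exact shape), FWHM 8–20 cm⁻¹.  Four
  class-discriminative bands are planted at 727, 956, 1045 and
  1065 cm⁻¹ with `class_effect = 0.3` (PC amplitude ×1.3); three bands
  carry cohort batch effects (±20–30%); the rest are neutral filler,
  including bands at 998, 1009, 1039 and 1051 cm⁻¹.
- **Nuisance structure**, applied in order: a per-patient
  multiplicative amplitude effect (`patient_sd = 0.1`, shared by all
  replicates of a patient, giving ≈10% within-class CV — this is what
  makes replicate averaging statistically meaningful); a random smooth
  polynomial baseline (degree 3, scale 0.5); a per-spectrum lognormal
  scatter factor (`scatter_sd = 0.1`); additive Gaussian noise
  (`noise_sd = 0.02`); clipping at zero.  Scatter is multiplicative
  and noise additive *after* it, so SNV and smoothing each have a
  distinct nuisance to remove.

What the generator does **not** emulate: coffee-ring spatial
gradients, cosmic-ray spikes, wavelength-calibration drift, realistic
absolute intensities or SNR, or any real biochemical difference
between the classes.  Consequently, passing tests demonstrate that the
*pipeline machinery* is correct and that planted effects of the stated
size are recovered; they say nothing about the detectability of
preclinical Alzheimer's in real CSF.  Under the default effect sizes
the classes are in fact linearly separable after preprocessing, so
cross-validated figures of merit saturate at 1.0; the informative
outputs on synthetic data are the recovery and calibration properties,
not the headline accuracy.

## Preprocessing

Order is fixed: Savitzky–Golay smoothing → baseline subtraction → SNV,
per replicate spectrum, then per-patient averaging.

- **Savitzky–Golay**: window 11, polyorder 3 (defaults).  At 1 cm⁻¹
  sampling an 11-point cubic window denoises without flattening
  ~10 cm⁻¹ bands.  Edges use interior-fit polynomial extrapolation
  (`scipy` mode `interp`).
- **Whittaker baseline**: the named "Whittaker method" is implemented
  as asymmetric least squares on a Whittaker smoother (Eilers-style):
  iteratively reweighted solution of `(W + λ D₂ᵀD₂) z = W x`, weights
  `p` above / `1−p` below the baseline, second-order differences.
  Defaults λ = 1e5, p = 0.01, maxiter 20.  The normal equations are
  pentadiagonal and solved with a banded Cholesky solver; iteration
  stops when the weight pattern is stationary.  Constants and straight
  lines are in the penalty null space and reproduced exactly.  The
  baseline is *subtracted*, never divided; corrected intensities may
  be negative and are not clipped.
- **SNV**: per-spectrum centering and scaling to unit sd, sample sd
  (ddof 1) by default, configurable since conventions differ.  A
  spectrum whose corrected variance falls below 1e-8 of its scale is
  rejected as zero-variance rather than letting SNV amplify solver
  residue (for λ = 1e5 the banded solve leaves ~1e-10 relative residue
  on signals it fits exactly).
- **Averaging**: arithmetic mean of a patient's preprocessed
  replicates; row order is first appearance; conflicting label or
  cohort metadata within a patient is an integrity error.

## PLS-DA

Single-response NIPALS PLS with X-deflation on mean-centered data;
classes coded H = 0, PC = 1.  For one response each weight vector is
closed-form (w ∝ Xᵀy), so fits are deterministic.  X is mean-centered
but not autoscaled — the spectra are already SNV-scaled, and
autoscaling would inflate noise-only wavenumbers; this is configurable
in spirit by scaling the input.  The factor model is collapsed to a
regression vector b = W(PᵀW)⁻¹q; predictions by b and by factor-wise
accumulation agree to 1e-10 (tested), and full-rank PLS equals least
squares (tested against a normal-equations oracle and scikit-learn's
PLS).

**Classification**: ŷ > threshold ⇒ PC, default threshold 0.5; a
prediction exactly at the threshold goes to H (fixed tie rule).  A
Bayes-style alternative threshold (intersection of class-conditional
Gaussians fitted to cross-validated ŷ) is provided as
`plsda.bayes_threshold` for toolbox parity but is not the default.

**Cross-validation**: random subsets — stratified random partition of
the patients into 15 folds, each fold predicted from a model fitted on
its complement, the whole partition redrawn 5 times; RMSECV pools
squared errors over samples and iterations.  A partition whose
training complement misses a class is redrawn (logged, capped).  The
reported metrics are computed from the pooled cross-validated
predictions, with per-iteration metrics kept alongside (the two
conventions differ and both are available).  LV count = argmin RMSECV
over 1..max_lv, ties to fewer LVs; inside CV the predictions at every
truncation depth come from a single NIPALS pass per training split.
Training splits of deficient rank freeze predictions at their last
extractable component instead of erroring, which is what makes the
tie-break contract observable.

**Metrics**: AUC by the Mann–Whitney rank statistic with midrank tie
correction (equals trapezoidal ROC integration; tested to 1e-10);
accuracy/sensitivity/specificity from the thresholded confusion
matrix, positive class PC.

**Permutation test**: the full cross-validation is re-run on each of
`n_perm` label permutations; p = (1 + #{null ≥ observed})/(n_perm+1),
so p is bounded below by 1/(n_perm+1) and exact under the null.

## Variable selection

- **VIP** (Chong–Jun form): VIPⱼ = √( p Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ ),
  SSYₐ = qₐ² tₐᵀtₐ; mean(VIP²) = 1 by construction (asserted on every
  fit in tests).
- **Selectivity ratio** (target projection, Rajalahti form): project X
  onto v = b/‖b‖; SRⱼ = ‖x̂ⱼ‖²/‖xⱼ − x̂ⱼ‖².  A zero-residual column
  (rank-one data) is capped at 1e12 and flagged.
- **Integration rule**: the two scores are combined as the sum of
  their ascending ranks — symmetric, scale-free and reproducible; the
  lowest combined ranks are dropped.  This rule is a design choice:
  published descriptions of VIP+SR hybrids rarely pin down the
  combination.
- **Backward elimination**: per step, tune LVs → fit → drop the worst
  10% of variables (at least one) → recompute RMSECV.  Stop at the
  first step whose RMSECV exceeds the running best by >1% relative, or
  at the variable floor (default 10); return the subset with the
  minimum RMSECV over the whole trajectory.  The 10% step and 1%
  tolerance are defaults chosen to make elimination fast yet gradual;
  "until the model no longer improves" needs an operational rule and
  this is ours.
- **Stability selection**: the elimination re-run `n_iter` times
  (default 100), each excluding `holdout_per_class` patients per class
  (default 5) uniformly at random, with the same 15×5 CV structure;
  per-iteration seeds derive from one master `SeedSequence`, so runs
  are reproducible and iterations independent.  The LV count is
  re-tuned inside every iteration.
- **Threshold scan**: for each frequency threshold f keep wavenumbers
  selected strictly more than f times ("exceeding" read strictly),
  re-tune and cross-validate; the accuracy-optimal threshold resolves
  ties toward the sparser model.  Default grid 0–90 by 10 plus 30.

## Pipeline

`run_full_pipeline` assembles the experiment matrix: Dataset 1,
Dataset 2, pooled, common-variables (intersection of the three
selections; an empty intersection yields a flagged NaN row), and the
frequency-threshold model, followed by a permutation test of the
threshold model.  Variable selection runs once, before the final
model's cross-validation — the usual chemometrics practice, which is
optimistically biased because the held-out patients influenced the
selection; `pipeline.nested_cv_metrics` offers the unbiased
alternative, repeating selection and tuning inside every outer fold.
All sub-seeds derive from one master seed and are recorded, with the
configuration and stage order, in a JSON manifest; reports are written
without timestamps so identical seeds give byte-identical artifacts.

## Problem sizes used in tests and the acceptance run

The test suite exercises the pipeline on a reduced design — 20/18- or
16-patient cohorts, a 6 cm⁻¹ grid (~200 wavenumbers), 25–35 jackknife
iterations — which preserves every structural property (15-fold CV
validity, planted-band recovery, threshold grids) at interactive
runtimes.  `scripts/acceptance.py` runs the full 75-patient design on
the full 1 cm⁻¹ grid with 25 jackknife iterations and 99 permutations.
These sizes are the package's reporting defaults; the library itself
has no scale limits beyond memory.

## Known limitations

- Binary PLS-DA only; no multi-class coding, kernel PLS, orthogonal
  signal correction or probability calibration.
- No cosmic-ray despiking, wavenumber alignment or EMSC; inputs are
  assumed spike-free and on a common grid.
- The default selection-then-CV metrics are optimistic (see above);
  use the nested mode when an honest generalization estimate matters.
- On the default synthetic regime the classes are separable, so
  figures of merit saturate; the generator is a correctness harness,
  not a difficulty benchmark.
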