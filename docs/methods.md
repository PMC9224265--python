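# Methods

This note documents the models, conventions and numerical choices behind
`fetpet`, in the order data flows through the package.

## Acquisition model

The dynamic protocol is a 40-min, 35-frame acquisition starting at tracer
injection: 12 × 5 s, 6 × 10 s, 6 × 30 s, 5 × 60 s, 6 × 300 s (2400 s in
total). Frames are contiguous; every curve is indexed by frame mid-times in
minutes. The static image is the duration-weighted mean of all frames
overlapping the 20–40-min window; with the default schedule exactly the
last four 300-s frames contribute, and a frame straddling a window edge
contributes its overlapping duration only.

All images are handled in SUV units. Injected dose, body weight, decay and
reconstruction are outside the model: the analysis consumes SUV images, so
phantoms are generated directly in SUV space.

## Phantom simulator

The phantom is a uniform spherical "brain" (radius 0.45 × the smallest grid
extent, background SUV 1.0 by default, zero outside) containing one
axis-aligned ellipsoidal lesion (default 20 mm diameter on a 2-mm isotropic
grid) displaced along +x into the right hemisphere. The lesion's noise-free
time course is

```
SUV(t) = A · (1 − e^{−k_in t}) · e^{−k_out t} / max(·)
```

with wash-in rate `k_in` (1/min), washout rate `k_out` (1/min) and peak
amplitude `A` (SUV over the 40-min acquisition). For `k_out > 0` the curve
peaks at `t* = ln(1 + k_in/k_out)/k_in` (closed form, used as the oracle in
time-to-peak tests); `k_out = 0` gives a monotone ascending curve. The
defaults for the three clinical curve classes are `(k_in, k_out)` =
(0.5, 0.01) descending, (0.5, 0.0012) plateau and (0.06, 0) ascending, all
with `A = 3.0` — chosen so the descending class loses roughly a quarter of
its peak activity by 40 min, the plateau class about 2.5% (mid-plateau
band), and all classes stay above the 1.6 × background contour cutoff in
the late static window, as typical recurrent-glioma lesions do.

Noise is additive zero-mean Gaussian per voxel and frame with standard
deviation `noise_sd · sqrt(5 s / frame_duration)`, i.e. `noise_sd` is the
sd of the shortest (noisiest) 5-s frame and longer frames are quieter by
counting statistics; values are clipped at zero. The simulator is fully
seeded.

What the phantom does **not** emulate: attenuation/scatter, reconstruction
point-spread and its partial-volume effects, anatomical background
heterogeneity (grey/white matter contrast), motion, or multi-focal disease.
Passing recovery tests therefore demonstrates correctness of the analysis
chain on idealised inputs, not clinical robustness.

## VOIs and static biomarkers

- **SUVmax**: global maximum of the static image (ties broken toward the
  lexicographically smallest voxel index).
- **Background crescent**: the clinical background VOI is drawn manually
  over the contralateral hemisphere; here it is parameterised to be
  deterministic — brain voxels between two concentric shells (defaults
  15–45 mm) about the brain centroid, restricted to a 90° cone about the
  lateral axis of the chosen hemisphere. The pipeline picks the hemisphere
  opposite the SUVmax voxel. Only the contract matters: contralateral,
  lesion-free, mixed tissue.
- **Auto-contour**: voxels with `SUV ≥ 1.6 × SUVmean_bg` (threshold
  comparison is ≥, "at least"), reduced to the 26-connected component
  containing the SUVmax seed. The cutoff is treated as a unitless
  lesion-to-brain ratio. An empty contour (seed below threshold) is valid
  and reported as TBRmean = 0 and zero volume. By construction every
  non-empty contour satisfies TBRmean ≥ 1.6 and TBRmax ≥ TBRmean (a 1-ulp
  rounding guard enforces the latter on constant regions).
- **Kinetic VOI**: a 10-mm-diameter sphere centred on the SUVmax voxel,
  applied to every frame. The sphere diameter is not standardised
  clinically; 10 mm is configurable.

## TTP and the TAC shape score

The peak is the *first* index attaining the global maximum of the
(optionally smoothed) curve. TTP is that frame's mid-time; curves whose
maximum sits at the final frame, or which are constant, have no
identifiable peak and get TTP = acquisition end (40 min). The score is:

- **1** — no identifiable peak, or peak at/after the 22.5-min cutoff (the
  late group includes late-peaking curves by definition);
- otherwise the terminal descent `(peak − final)/peak` decides:
  **−1** if ≥ 5% of the peak, **0** (plateau) if smaller.

A descent of exactly 5% counts as descending ("less than 5%" defines the
plateau). Scores are scale-invariant and coherent with TTP: a score of −1
or 0 implies TTP < 22.5 min. Smoothing (centred moving average with
symmetrically shrinking end windows) is **off by default** so the
definitions apply to the raw curve; a window of 3 is exposed for noisy
data and is what the noise-robustness tests use.

## Cohort statistics

- **ROC/AUC**: empirical ROC over all distinct thresholds; AUC is the
  normalised Mann-Whitney statistic with tied pairs counting ½ (equal to
  the trapezoidal area under the curve). AUC uncertainty is the DeLong
  structural-components estimator; curve comparisons use the paired DeLong
  variance of the difference (unpaired: summed variances), two-sided normal
  p-values, and p = 1 for the degenerate zero-difference/zero-variance
  case.
- **Youden cut-point**: candidate thresholds are midpoints between
  consecutive sorted unique values plus ±∞; `value ≥ threshold` predicts TP
  for "higher" orientation ("lower", used for TTP, negates values
  internally and maps thresholds back). Ties in J are broken toward higher
  sensitivity, then the lower threshold. Reports also echo the nearest
  observed value, since published thresholds are usually on the observed
  scale.
- **Threshold uncertainty**: the cut-point CI is a seeded bootstrap
  percentile interval (default 2000 resamples) stratified within outcome
  classes, so every resample retains both classes. This is the package's
  substitute for cut-off uncertainty modelling that cannot be reproduced
  exactly from published descriptions; its coverage is verified by
  simulation (≥ 90% at n = 200/class against the analytic optimum of a
  two-normal model).
- **Proportion intervals**: Wilson score intervals, chosen because they
  reproduce published sensitivity/specificity interval cells from their
  integer counts and behave well at 0 and 1.
- **MWU**: exact null distribution when the combined sample is ≤ 20 without
  ties (verified against full enumeration); otherwise the normal
  approximation with tie and continuity corrections.
- **Proportions**: uncorrected Pearson χ² by default (Fisher exact by
  flag). All tests are two-sided at α = 0.05; no multiple-testing
  correction is applied, matching common practice in small diagnostic
  cohorts.
- **Logistic combiner**: Newton maximum likelihood (tol 1e-8, ≤ 100
  iterations; statsmodels `Logit` underneath), Wald 95% CIs, odds ratios
  `exp(β)`. Complete/quasi-separation is detected (fitting error or
  |β| > 15) and flagged with `converged = False` rather than hidden; a
  rank-deficient design raises instead of silently dropping a column. The
  default predictor set is TAC score + IDH + TBRmean overall and TAC score
  + TBRmean within IDH strata. TTP enters ROC analyses with "lower
  indicates TP" orientation; the AUC is reported as computed and may fall
  below 0.5.
- **Missing data**: listwise exclusion per analysis with a logged and
  reported count.

## Synthetic and reference cohorts

`generate_cohort` samples biomarker tables per (IDH, outcome) group from
truncated normals (TBRmax, TBRmean, TTP) and a categorical TAC-score
distribution, with group means anchored to typical recurrent-glioma values
(e.g. IDHm TP: TBRmax 4.2, TBRmean 2.2, TTP 30 min; TRC groups ~2.6/1.8
and later peaks). TBRmean is 0 with a small empty-contour probability and
otherwise ≥ 1.6. TTP and TAC score are drawn independently — sampled rows
emulate marginal distributions, not the score⇔TTP coherence that computed
kinetics guarantee; use image-derived records where that matters.

`reference_cohort()` is a deterministic 44-row table with the marginal
composition of a typical recurrent-glioma FET referral series (26 IDHm with
7 TRC, 18 IDHwt with 5 TRC, 27 male/17 female). Its biomarker columns are
deterministic placeholders inside plausible group ranges, flagged
`measured = False`; they intentionally make the table useful for
count/proportion analyses only. Because the placeholders are constant per
group they render the logistic design exactly collinear, which the
analysis reports as a skipped block rather than a fit.

## Problem sizes and determinism

Tests and the acceptance script run phantoms on 32³–48³ grids (the lesion
and all VOIs fit comfortably; results are grid-independent beyond that),
200 random cohorts for oracle-equivalence checks, 500 seeded noisy curves
per class for recovery rates, and n = 5000 cohorts over 20 seeds for
logistic recovery — sizes chosen to make sampling error negligible
relative to the tested tolerances. Every stochastic routine takes an
explicit seed; cohort reports embed the resolved configuration and package
version, and identical inputs and seeds reproduce reports byte for byte.

## Known limitations

- Single-lesion analysis only; no MRI co-registration, DICOM ingestion,
  partial-volume correction or reconstruction modelling.
- The crescent VOI is a deterministic idealisation of a manually drawn
  clinical region.
- No survival analysis, covariate-adjusted ROC or cross-validation of the
  logistic model (apparent performance only).
- The curve-shape rules are an explicit algorithmicisation of criteria that
  are partly visual in clinical practice; all cutoffs (1.6, 22.5 min, 5%)
  are configurable.
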