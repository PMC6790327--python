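# Methods

## Signal model and pipeline

The analysis assumes each subject provides R = W + G regional-average BOLD
series (W white-matter, G gray-matter ROIs) sampled at interval TR and
band-limited to 0.01–0.1 Hz. Functional connectivity is instantaneous
Pearson correlation; dynamic connectivity is the sequence of Pearson
correlations over K overlapping windows of `window_length` samples advanced
by `step` samples, with windows 0-based and half-open
(`[k·step, k·step + window_length)`), so `K = floor((T − window)/step) + 1`.
Each edge's dynamic behaviour is summarized by the quadratic mean (RMS) of
its windowed correlations. Because the RMS is bounded by 1 and dominated by
the magnitude of correlation excursions, it responds to coupling
*variability* that time-averaged correlation misses.

All four matrices (static/dynamic × within-GM/WM–GM) are mapped through
Fisher's r-to-z before statistics; the transform is variance-stabilizing
for correlations, and is applied to RMS values as well so all four feature
sets enter selection on a comparable scale. |r| is clipped at 1 − 1e−7
first so numerically perfect correlations stay finite; the within-GM
diagonal never enters the feature vector.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| band | 0.01–0.1 | Hz | standard resting-state range; low cut removes drift, high cut removes physiological noise |
| filter | Butterworth order 2, forward–backward | — | zero phase, so correlations are undistorted; effective magnitude response is squared |
| window_length | 30 | samples (volumes) | ~90 s at TR 3 s; windows shorter than ~1/f_low trade correlation-estimate variance against temporal resolution |
| step | 1 | samples | maximal window overlap |
| alpha_static / alpha_dynamic | 0.001 / 0.01 | — | working selection thresholds; selection is non-strict (p ≤ α) |
| t-test variant | pooled | — | classical two-sample default with equal group sizes; Welch available (`test_variant="welch"`) |
| SVM | linear kernel, C = 1 | — | deliberately untuned; the features, not the classifier, are under study |
| fdr_q | 0.05 | — | Benjamini–Hochberg level used when reporting top edges (reporting only, never selection) |
| display threshold | 0.5 | correlation | group-mean FC masks show edges with strictly \|value\| > 0.5 |

## Synthetic cohort generator

The generator emulates a two-group resting-state cohort: per subject a
zero-mean multivariate Gaussian over the W + G ROIs, sampled white in time,
then band-pass filtered with exactly the filter the extraction stage uses.
The background covariance is exchangeable (all off-diagonal correlations
equal `base_correlation`, default 0.1). Group contrasts enter through two
channels:

- **static effects** — the patient group's stationary correlation on the
  chosen edges is shifted by `static_effect_delta`; because the filter is
  applied identically to all channels of temporally white input, the
  injected correlation survives filtering unchanged in expectation, so the
  generator is calibrated in the units the analysis measures;
- **dynamic effects** — the patient group alternates between two regimes
  whose correlations on the chosen edges are `base ± amplitude`
  (default amplitude 0.4), with geometric dwell times of mean `state_dwell`
  samples (default 20, i.e. 60 s at TR 3 s; geometric for memorylessness).
  The two regimes average back to the baseline correlation, so static FC is
  blind to these edges by construction while the windowed RMS is not.

Every regime covariance is checked for positive semidefiniteness and the
generator refuses otherwise, naming the offending edge set — no silent
projection, so injected effects are exactly as specified. The default
effect set (`default_dynamic_edges`) pairs distinct GM targets with WM
sources reused at most twice, which keeps the perturbed exchangeable
covariance comfortably positive definite at amplitude 0.4.

`noise_sd` defaults to 0: additive white measurement noise attenuates all
observed correlations by 1/(1 + noise_sd²), which would silently rescale
injected deltas; users who want noisy cohorts opt in explicitly. Subject
streams are seeded by `(seed, group_index, subject_index)`, so cohorts are
bit-reproducible and any subject can be regenerated alone.

What the generator does **not** emulate: hemodynamic-response convolution,
head motion, physiological noise structure, spatial autocorrelation of
real parcellations, or non-Gaussian BOLD marginals. Passing tests on these
cohorts therefore demonstrate correctness and calibration of the
*statistics*, not clinical performance on real fMRI.

Default cohort dimensions mirror the study design this pipeline targets:
45 subjects per group, 48 WM + 82 GM ROIs, TR 3 s. Series length defaults
to 140 volumes (7 min), a typical resting-state acquisition length chosen
here as a stand-in; it is a free parameter of `CohortSpec`.

## Numerical and procedural choices

- **Degenerate windows**: a zero-variance window makes Pearson r undefined;
  the edge's C^k is set to 0 and counted, keeping K identical across edges
  (dropping windows would desynchronize the RMS denominators).
- **Zero-variance ROIs** in static FC get all edges set to 0 with a logged
  warning rather than NaN propagation.
- **Empty selections**: by default an empty edge selection raises an error
  naming the fold and α. `min_features=k` provides an explicit fallback to
  the k smallest-p edges; the threshold sweep instead records the α as
  missing and continues.
- **Ties**: top-edge ranking breaks p ties by |t| descending, then by edge
  index, so reports are deterministic. ROC ties step simultaneously; AUC is
  the trapezoid rule over unique thresholds and equals the Mann–Whitney
  pair statistic.
- **Group-mean FC maps** average raw r / RMS values (not Fisher z); z is
  used only for statistics.
- **AUC pooling**: LOO yields one decision value per subject; the ROC/AUC
  is computed on the pooled decision values, since per-fold ROCs are
  undefined for single held-out points.
- **Metric conventions**: rates are percentages; ratios with zero
  denominators (e.g. precision with no positive predictions) are reported
  as NaN, never 0. With equal group sizes accuracy necessarily lies between
  sensitivity and specificity, which the result object asserts.

## Selection protocols and leakage

`protocol="paper"` selects edges once on the whole cohort before LOO; this
matches the procedure most published connectome-classification studies
describe, but the held-out subject contributes to its own feature
selection, which biases accuracy upward — measurably so on null data,
where whole-cohort selection is at least as optimistic as nested selection
in expectation (this is asserted in the test suite). `protocol="nested"`
re-runs selection inside each training fold and is the default. Every
output records which protocol produced it.

## Validation problem sizes

The cohort-scale checks run at the full study dimensions (45+45 subjects,
48 WM + 82 GM ROIs, T = 140): type-I calibration uses 5 null-cohort
replicates and tests the mean selected fraction at α ∈ {0.01, 0.001}
against 3 binomial SDs; the chance-level control permutes labels on one
null cohort and checks nested-LOO accuracy against the binomial 95%
interval at n = 90; effect recovery uses 5 replicates with dynamic-only
effects on 50 WM–GM edges and compares mean dWGFC vs. sGFC accuracy and
the fraction of injected edges among the 100 smallest dWGFC p-values.
Exact-arithmetic checks (windowed-correlation oracle, RMS/static
consistency, Fisher-z round trip, feature counts) use direct independent
computation.

## Known limitations

- Pearson-only coupling; no partial correlation, no tapered windows, no
  dynamic-state clustering, no graph metrics.
- No preprocessing beyond band-passing: slice timing, motion correction,
  registration and smoothing are assumed done upstream; inputs must share
  the atlas grid.
- LOO accuracy on a single cohort has high variance; single-run accuracies
  (including the chance-level control) scatter several points around their
  expectation, which is why replicate means are used wherever a comparison
  is asserted.
- The pooled t test assumes equal group variances; with equal group sizes
  it is robust, and Welch is available where that assumption is doubtful.
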