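# Methods

## Problem setting

A two-class expression study compares `n0` normal samples against `n1`
cancer samples over `G` genes, on a normalized log scale. For many
oncogenes the activation is *heterogeneous*: only a subset of cancer
samples — the cancer outliers — is shifted, and a two-sample t statistic,
which assumes common activation of all cancer samples, loses power. The
classical response is a family of robust per-gene statistics (COPA, OS,
ORT, MOST) that look only at the extreme cancer tail. This package
implements those comparators and a mixture-model alternative that shares
information across both genes and cancer samples.

## The mixture model

Each cancer observation is standardized against its gene's normal-class
statistics,

    u_gj = (y_gj - x̄_g) / s_g,x ,

with `x̄_g` the mean and `s_g,x` the sample standard deviation (divisor
`n0 - 1`) of the gene's normal values. `s_g,x` is used as a
per-observation scale, not divided by sqrt(n0): this is the reading under
which null `u_gj` are approximately N(0,1), which the mixture's null
component assumes. Genes whose normal values are constant cannot be
standardized and are excluded with a warning; no pseudo-count is added, so
no arbitrary constant leaks into the fit.

All `u_gj` pooled over genes and cancer samples are modeled as

    f(u) = pi0 N(u; 0, 1) + pi1 N(u; delta1, 1) + pi2 N(u; delta2, 1),

a three-component normal mixture whose variances are fixed at 1 and whose
null mean is fixed at 0 — only `(pi1, pi2, delta1, delta2)` are free. The
under/over component means `delta1 < delta2` are shared across genes; the
mixing proportions are *observation-level*: with gene-level nonnull
proportions `(pi_under, pi_over)` and outlier fraction `phi`, the fitted
`pi2` estimates `pi_over * phi`, not `pi_over` (verified in the tests).

### EM estimation

The E-step computes posteriors `w_gj,k ∝ pi_k N(u_gj; mu_k, 1)`; the
M-step sets `pi_k` to the mean posterior weight and `delta_k` to the
weighted mean of `u` for k = 1, 2. Numerical choices:

* **Convergence** — maximum over the four free parameters of
  `|θ_new − θ_old| / max(|θ_old|, 1e-8) < rel_tol`, default `rel_tol =
  1e-4`. The threshold is the published convergence rule for this model;
  the metric (max relative change) is our choice since only the threshold
  is stated.
* **Initialization** — `delta1/delta2` start at the 5th/95th percentiles
  of the pooled data clipped to ≤ −1 / ≥ +1, with `pi1 = pi2 = 0.05`.
  This is scale-free and lands in the basin of the intended labeling.
  A `(pi1, pi2, delta1, delta2)` tuple or callable can be supplied
  instead (used by the tests to reproduce hand-computed EM steps).
* **Label switching** — after every M-step components 1 and 2 are swapped
  (with their proportions) if `delta1 > delta2`. Only the ordering is
  enforced; the signs are data-driven.
* **Vanishing components** — proportions are floored at `1e-10` during
  iteration so the mean update never divides by zero; a component whose
  final proportion is within an order of magnitude of the floor is
  reported with a NaN mean and a warning.
* **Stability** — the E-step subtracts the row maximum before
  exponentiating and the total log-likelihood uses log-sum-exp, so the
  computation is finite for |u| up to at least 1e3.

The log-likelihood trace is recorded every iteration and checked
(in tests, on arbitrary inputs) to be non-decreasing within 1e-8.

### Gene selection statistics

From the fitted posteriors, the one-sided score

    S_g = 1 - prod_j (1 - w_gj,2)

is one minus the posterior probability that *no* cancer sample of gene g
is an overexpression outlier; `T_g = 1 - prod_j (1 - w_gj,1 - w_gj,2)` is
its two-sided analogue and dominates `S_g`. The products are accumulated
as `exp(Σ log1p(-w))`, which is exact for saturated factors and immune to
underflow. Both are pure ranking statistics; no FDR calibration is
attached to them. When many genes saturate at S_g = 1, ranking falls back
to the deterministic tie rule (input gene order); `log(1 - S_g)` is
available through the posterior output as a saturation-free secondary key.

## Comparator statistics

All use the 1.4826-scaled MAD, type-7 (linear-interpolation) quantiles
and midpoint medians; the quantile convention materially affects the
small-sample values and is fixed for bit-reproducibility. Zero scale
estimates yield NaN scores, which rank last.

* **t** — pooled-variance two-sample t.
* **COPA** — `(q_r(cancer) - med_pooled) / mad_pooled`, default r = 90
  (the original proposal lists 75/90/95 without choosing; 90 is the
  middle option), configurable.
* **OS** — sum of `(y - med_pooled)/mad_pooled` over cancer values above
  the *pooled* q75 + IQR threshold (strict `>`).
* **ORT** — same sum but centered on the normal-class median, thresholded
  on the *normal-class* q75 + IQR, and scaled by the class-centered
  pooled MAD (deviations of normals from the normal median and of cancer
  values from the cancer median, pooled before taking the median).
* **MOST** — maximum over k of the standardized cumulative sum of the k
  largest cancer values, using ORT's center/scale, normalized by the
  mean and SD of partial sums of standard-normal order statistics.

The MOST moments are estimated by Monte Carlo (default 1e5 sorted
standard-normal samples, fixed seed 20130410, cached per
`(n1, reps, seed)`), giving O(reps^-1/2) error that is negligible against
between-gene ranking differences; exact numerical integration of the
order-statistic covariances would be a drop-in alternative.

## Synthetic benchmark

`generate_dataset` emulates the two-class microarray design the methods
are evaluated on: i.i.d. base noise per entry — N(0,1), or a central t
with 20 df (used unscaled, variance 20/18) to probe misspecification —
with no gene-gene correlation; genes partitioned 0.6/0.2/0.2 into
null/under/over components; and for each nonnull gene an additive shift
of −2.0/+2.0 applied to a uniformly random subset of `round(phi * n1)`
cancer samples, `phi ∈ {0.1, 0.3, 0.5}`. The fixed outlier count (rather
than per-sample Bernoulli, available via `outlier_sampling="bernoulli"`)
makes the TPR denominator exact. Replicates are seeded as
`default_rng([master_seed, rep_index])`, so each replicate is
independently re-runnable and every result is bit-reproducible.

What the generator does *not* emulate: gene-gene correlation, probe-level
noise, array effects, or non-additive activation. Passing benchmarks here
show correctness of the statistics and the fitting machinery under the
stated model, not performance on real arrays.

Rankings are scored by FDR (fraction of selected genes outside the target
component) and TPR (fraction of target genes selected, i.e. average
power) over every top-m list; experiments average both across replicates
at fixed m. "TPR at FDR 0.1" reads the averaged curve at the list size
whose mean FDR is closest to 0.1.

### Problem sizes used in the shipped checks

The test suite exercises parameter recovery at full scale (G = 10000,
n = 200, one replicate) and the benchmark orderings at G = 2000 with 20
replicates across three master seeds; `scripts/acceptance.py` uses
G = 10000 for recovery and G = 2000 with 10 replicates for the TPR table.
At these sizes the method orderings are stable across seeds; the curves
themselves are noisier than a 200-replicate run would give.

## Known limitations

* A single nonnull component per direction; no AIC/BIC selection of the
  number of components, and no gene-level null/nonnull mixture layer —
  S_g ranks genes but carries no calibrated error rate.
* Missing values are rejected, not imputed; normalization is assumed done.
* The EM likelihood is not unimodal in general; the quantile
  initialization is a heuristic, and pathological starts can converge to
  a vanished component (reported as NaN with a warning).
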