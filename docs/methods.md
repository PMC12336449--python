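# Methods

This note records the mathematical model behind each stage and the design
decisions that are not obvious from the code.

## 1. Trajectory generator

Time is a uniform grid of 289 frames at 10-min spacing over 48 h
(`t = np.arange(289)/6` hours). Each simulated cell draws one of six
trajectory archetypes and evaluates a closed-form curve plus noise:

- **Two-pulse archetypes** (on-time cytokinesis, cytokinesis delay,
  cell-cycle delay, G1 arrest): a baseline plus one or two Gaussian bumps,
  `y(t) = b + a₁·exp(−(t−t₁)²/2w²) [+ a₂·exp(−(t−t₂)²/2w²)]`. G1 arrest has
  a single, delayed, resolved pulse; cytokinesis delay has a much smaller
  first pulse; cell-cycle delay shifts both pulses late.
- **G2 arrest**: a four-parameter logistic rise that is held at its plateau
  (FOXM1 accumulates toward mitosis but the cell never divides).
- **Cell death**: a Gaussian rise to the first peak, then exponential decay.

Per-cell heterogeneity multiplies amplitudes and jitters times via a
coefficient of variation (`cv_cell`); measurement noise is additive Gaussian
(`sigma_noise`), and intensities are clamped at zero. Cytokinesis event
times are emitted for archetypes that divide. Everything is driven by
`numpy.random.default_rng(seed)` so panels serialize byte-identically.

**Calibration.** `calibration.yaml` maps each of 16 inhibitors × a fixed
dose ladder to archetype mixture weights, organized by mechanistic class
with optional per-drug overrides (`per_drug`) for both weights and curve
modifiers. The ATR/CHK1-axis class additionally scales the second-pulse
amplitude down and shifts the second pulse and cytokinesis earlier, with a
per-drug potency gradient. That gradient is load-bearing: if all five drugs
in the class had identical calibrations, their condition-mean curves would
correlate at exactly 1 and the mutual-KNN adjacency within the group would
be decided by simulation noise; a monotone potency ordering makes
within-group adjacency signal-driven and the six-cluster partition stable
across seeds (validated over 69 seeds at the default panel size of 200
cells per condition×batch).

## 2. Normalization and pulse features

Traces are normalized to the mean of each cell's initial window (first six
frames = 1 h), making amplitudes comparable across cells with different
expression levels. Pulse detection uses `scipy.signal.find_peaks` with a
prominence floor (a fraction of the trace's range) and a minimum peak
separation in hours.

**Amplitudes are peak prominences**, not absolute peak values: the
prominence measures the pulse height above its own base, so a "two-fold
smaller mitotic pulse" means the pulse itself halves, independent of the
baseline the pulse sits on. With absolute values a halved pulse riding on
an unchanged baseline would show a fold change well above 0.5. Onset is
defined consistently: the first time the trace climbs a configurable
fraction (default 50%) of the first pulse's prominence above the pulse
base, searched from the pulse's left base. The terminal slope is the
least-squares slope over the final window (default 6 h).

Half-life comes from a log-linear fit: `ln 2 / |slope|` of
`log(intensity)` vs time over the decay window. Two-group comparisons
report the mean second-pulse amplitude fold change (B over A), median
second-peak time difference and median first-cytokinesis difference (A
minus B, positive = earlier in B), each with an unpaired two-tailed Welch
t test; a metric missing in either group is reported absent, never zero.

## 3. Batch correction

Parametric empirical-Bayes location/scale adjustment per time point:
standardize by the overall mean and pooled (ddof = 0) variance, estimate
per-batch locations and scales, shrink them toward moment-matched priors
(normal for locations, inverse-gamma for scales) by iterative conditional
estimation to 1e-6, then remove them. Using ddof = 0 for the per-batch
scale estimates matches the pooled-variance denominator, so two batches
holding identical data yield scale estimates of exactly 1 and the
adjustment is the identity — a property the tests assert. Constant time
points are passed through unadjusted with a warning.

## 4. Functional PCA

Curves on the uniform grid are treated as discretized functions with
trapezoid quadrature weights `w`. Centering the data and scaling columns by
`√w` turns the SVD of the scaled matrix into the eigendecomposition of the
quadrature-weighted covariance operator: right singular vectors divided by
`√w` are eigenfunctions orthonormal under the quadrature inner product, and
scores are quadrature integrals of centered curves against eigenfunctions.
Signs follow a fixed convention (non-negative quadrature integral, ties by
the final value) so results are reproducible. No presmoothing is applied:
at 10-min sampling the raw covariance is already stable.

**Condition-level fPCA.** The panel analysis (`pipeline.analyze_panel`)
fits fPCA on the condition×batch *mean* curves (34 curves for the default
panel) rather than on single cells. The clustering question is about
condition-level dynamics; averaging removes the within-condition archetype
mixture variance that would otherwise dominate the spectrum, which is why
the first two components explain ≈97% at the condition level versus ≈90%
at the cell level. Batch correction is applied to the cell-level matrix
before averaging.

## 5. Clustering

Drugs are represented by their mean fPC score vectors; similarity is the
Pearson correlation across score dimensions (with a scaled-Euclidean
fallback below three dimensions, where correlation is meaningless). The
mutual-KNN graph joins two drugs iff each ranks the other in its top-k
(default k = 2) most similar neighbours, ties broken by item order;
clusters are the connected components. This uses exactly two ingredients —
a neighbour count and a similarity — and is deterministic and shape-
agnostic. A k-means-with-silhouette fallback is available for sensitivity
analysis.

## 6. Endpoint gating

DAPI (DNA content, 2N vs 4N) and EdU (replication) intensities are modelled
as two-component Gaussian mixtures in log space, fitted on the pooled
population. The cutoff is the point between the component means where the
posterior responsibility is 0.5, found by root bracketing in log space
(log-space likelihoods so near-degenerate components cannot underflow).
Degenerate fits (a vanishing weight or unseparated means) raise "no
bimodality detected"; an Otsu histogram threshold is available as a
fallback. The 2×2 rule assigns G1 (low/low), early S (low DAPI, high EdU),
late S (high/high), G2-M (high DAPI, low EdU); cells exactly on a cutoff
gate low.

## 7. Fate calling

A fixed decision cascade, evaluated in order so a trace matching several
descriptions gets one reproducible label:

1. **cell death** — terminal slope below a negative threshold and a
   terminal level under half the trace maximum;
2. **G2 arrest** — terminal level at ≥ 80% of the trace maximum
   (continuous rise, held);
3. **G1 arrest** — a single *delayed* pulse that resolves (sheds ≥ 30% of
   its prominence after the peak);
4. **cell-cycle delay** — a delayed first pulse with a later second pulse;
5. **cytokinesis delay** — a first pulse under half the second's height;
6. **on-time cytokinesis** — two pulses with an on-schedule first pulse.

"Delayed" means the first pulse sits more than a margin (default 2 h) past
the *DMSO control's median* first-pulse time — an internal anchor, not an
absolute clock. A trace matching no rule is labelled `unclassified` and
tallied, never silently defaulted. On noiseless archetypes the cascade
round-trips 100%; on the default noisy panel it agrees with ground truth
for ≳90% of cells.

## 8. Determinism and provenance

Seeds are mandatory for every stochastic CLI step. Each output embeds a
provenance block — command, seed, SHA-256 hash of the canonicalized
effective config, package version, and the config itself — as a
`# provenance:` comment line on delimited files or a `provenance` key in
JSON documents. Unknown config keys are rejected. Rerunning any command
with identical inputs produces byte-identical files, and the tests assert
this at both the generator and report level.
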