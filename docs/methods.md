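# Methods

This note documents the models, conventions, defaults and design
choices behind `emgburg`, and what the synthetic experiments do and do
not establish.

## Signal conditioning

Recordings begin with an inactive stretch before the muscle engages.
Conditioning is deliberately minimal — no band-pass, notch, wavelet or
EMD denoising — consisting only of:

1. **Onset trimming.** There is no canonical onset-detection rule for
   this protocol, so the package uses a sliding-window RMS detector: keep the
   signal from the first window (default 25 samples = 50 ms at 500 Hz)
   whose RMS reaches `onset_fraction` (default 0.1) of the whole-signal
   RMS. The rule is scale-invariant, linear-time, and capped at
   removing half the signal so noise-only inputs still yield a usable
   sequence. Trimming is per channel; channels of one trial may end at
   different lengths, which is harmless because all features are
   per-channel.
2. **Mean removal.** Subtraction of the arithmetic mean over exactly N
   samples. The linear-prediction stage assumes a zero-mean process;
   `CleanSignal` enforces |mean| ≤ 1e−9 × RMS at construction.

## Time-domain features

Ten descriptors per channel, in the fixed serialization order
IEMG, MAV, SSI, VAR, RMS, WL, WAMP, SSC, ZC, MYOP. Conventions that
needed a decision:

- **VAR** keeps the zero-mean convention (SSI/(N−1), no internal
  re-centring), consistent with the conditioning stage.
- **WL** sums the N−1 adjacent absolute differences.
- **ZC** counts sign changes whose amplitude step also clears the
  threshold: x_n·x_{n+1} < −th and |x_n − x_{n+1}| ≥ th. With th = 0
  this is the plain zero-crossing count.
- **SSC** counts interior samples with (x_n − x_{n−1})(x_n − x_{n+1})
  ≥ th, strict > 0 at th = 0.
- **WAMP** counts adjacent differences |x_n − x_{n+1}| ≥ th (the
  standard Willison amplitude); **MYOP** counts samples |x_n| ≥ th.
  Both are normalised by N, so they lie in [0, 1].
- **Thresholds.** No reference values exist for this protocol. ZC and
  SSC default to 0; WAMP and MYOP default to 5% of the signal RMS
  (resolved per signal, so they track gain), all overridable via
  `ThresholdConfig` / the `features.*` config keys.

## Burg lattice estimator

`BurgAR(x, order).fit()` returns reflection coefficients K_1..K_p, AR
coefficients a_p(1..p), and per-stage error powers ε_0..ε_p.

- **Objective.** K_m minimises ε_m = Σ_n [f_m(n)² + b_m(n)²]; setting
  dε_m/dK_m = 0 gives the harmonic-mean form with stage-(m−1) errors in
  the denominator, which guarantees |K_m| ≤ 1 by the AM–GM inequality
  and ε_m = (1−K_m²)·(denominator) ≤ ε_{m−1}.
- **Summation ranges.** Stage-m sums run over the n where both
  f_{m−1}(n) and b_{m−1}(n−1) exist, i.e. n = m..N−1 (0-based). Hence
  ε_0 = 2·SSI.
- **Sign convention.** K and a are stored in the monic
  prediction-error-filter convention: A(z) = 1 + Σ a_k z^{−k} whitens
  the signal, and a_m(m) = K_m at every stage. Most AR references (and
  `yule_walker` here) write the generative form
  x[n] = Σ φ_k x[n−k] + e[n]; those coefficients are the negation,
  exposed as `arcoefs_ar`. Under this convention an alternating
  ±1 signal has K_1 = +1 and a constant signal K_1 = −1.
- **Degenerate inputs.** Zero-energy signals are rejected (the ratio is
  undefined). If a later stage's denominator vanishes (the signal is
  already perfectly predicted), the remaining coefficients are set to 0
  and the remaining error powers to 0.
- **Order.** Default p = 10 per channel (feature names K1..K10,
  Arb1..Arb10), configurable via `ar.order`.
- **Yule–Walker comparison.** `yule_walker` solves the Toeplitz normal
  equations from biased autocorrelation estimates (delegated to
  statsmodels). It exists as the classical comparison point: on long
  Gaussian AR data the two estimators agree (verified to 1% relative at
  N = 100 000), while Burg is preferred for short records.

## Dataset construction

Per channel the requested blocks are extracted in the fixed order
TD (10), Arb (10), K (10); channel blocks are concatenated in channel
order with names like `K1_ch2`. Variants: TD / Arb / K (10 per
channel), K+TD / K+Arb (20), X (30; 60 features for two channels).
Labels are the six gesture names stored as nominal strings. Instances
are ordered deterministically by (subject, class, trial), so identical
corpus + config produce byte-identical CSVs. Interchange formats are
CSV (header row, trailing `subject`, `trial`, `class` columns) and a
minimal ARFF dialect (numeric attributes, nominal class); an optional
reader ingests the public MATLAB container layout (per-class
trials × samples matrices) when such a file is available locally.

## Feature selection

- **Plus-l-take-away-r** (backward wrapper): repeatedly remove the
  feature whose removal least degrades the evaluator; if even the best
  removal drops the score below the initial reference minus the
  tolerance (default 0), the feature is reinstated and the search
  stops. Ties prefer removing the feature later in canonical column
  order.
- **Forward selection**: greedily add the best-improving feature from a
  (possibly restricted) candidate pool on top of optional seed features
  (e.g. K1 and Arb1 per channel); non-improving additions are rejected
  and terminate the search. Ties prefer the earlier feature.
- **Wrapper evaluator** defaults to 1-nearest-neighbour accuracy under
  seeded stratified 10-fold CV (folds clamped to the smallest class
  count on small data); pluggable.
- **CFS**: best-first forward search over subsets scored by
  merit = k·r̄_cf / √(k + k(k−1)·r̄_ff). The feature–class correlation
  r̄_cf is computed as the prevalence-weighted mean |Pearson r| between
  the feature and one-vs-rest class indicators (the merit formula
  requires a scalar class correlation and the class is nominal; this is
  the simplest well-defined choice). Constant features score 0. The
  search terminates after 20 consecutive non-improving expansions —
  patient enough to guarantee the exhaustive optimum on small feature
  sets, which the tests verify by enumeration.
- **PCA** standardises features to unit variance by default (the blocks
  mix amplitude units with normalised counts) and keeps components up
  to the requested variance fraction (default 0.95). With exactly
  collinear inputs and `variance_retained=1.0` the trailing null
  component is numerical noise; callers wanting strict decorrelation
  should drop duplicates or retain < 1.0.

## Classifier benchmark

Stratified k-fold CV (default 10) from a seeded shuffle; every instance
is tested exactly once; per-class fold sizes differ by at most one.
Accuracy is reported in percent as 100·trace(confusion)/total, which in
the binary case reduces to 100·(TP+TN)/P. Sensitivity, specificity and
AUC are computed one-vs-rest per class and aggregated weighted by class
prevalence; AUC uses continuous membership scores (probabilities or
margins) where the model provides them, else hard 0/1 assignments, in
which case each class's AUC reduces to (sensitivity+specificity)/2.

WEKA-style defaults are re-expressed explicitly: Gaussian naive Bayes;
pruned decision tree (min leaf 2); 100-tree random forest with √d
features per split; one hidden layer of (features+classes)/2 units
trained 500 epochs by SGD at learning rate 0.3, momentum 0.2; SVM C = 1
with linear, cubic-polynomial or RBF (γ = 1/d) kernels. Min-max
normalisation to [0,1], fitted on training folds only, is on by default
for knn/svm/mlp and off for trees and naive Bayes. The k-NN classifier
is implemented in-package because its tie-breaking is pinned: majority
vote, ties broken by the nearest neighbour among tied classes, residual
exact-distance ties by canonical class order; k = 7 (classes + 1) can
never tie six ways.

## Synthetic corpus generator

Each gesture class is a stationary AR process with its own per-channel
reflection-coefficient vector (the *class bank*), kept inside a
stability margin |K| ≤ 0.98. A trial is synthesised by stepping K up to
AR form, filtering unit-variance Gaussian innovations (500-sample
burn-in discarded), applying an attack/hold envelope (linear rise over
the first 15% of the trial, floored at 5% so the AR structure
survives), prepending a 250-sample low-activity lead-in at 2% of signal
RMS, and adding white measurement noise at 5% of signal RMS. Subject
identity perturbs the class coefficients with Gaussian jitter
(sd 0.02), drawn once per (seed, subject, class, channel) so a
subject's signature is consistent across trials. The default protocol
is 5 subjects × 6 classes × 30 trials × 2 channels at 500 Hz, 6 s.

The default bank's six classes differ in their leading two reflection
coefficients (grid-placed, pairwise Euclidean separation ≥ 0.3 per
channel) plus a small class-specific tail. Envelope and lead-in exist
to exercise the conditioning stage realistically and are disabled for
parameter-recovery experiments, separating estimator validation from
preprocessing validation. Gaussian innovations make the classical
Burg/Yule–Walker agreement property hold on the fixtures.

**What passing tests show — and don't.** The generator reproduces the
statistical structure the pipeline assumes: per-class stationary AR
signatures, activity onset, additive noise, and the corpus bookkeeping.
It does not model motor-unit action-potential trains, recruitment,
electrode cross-talk, within-trial non-stationarity, or realistic
inter-subject variability. Perfect classification on the synthetic
corpus therefore validates the pipeline's correctness and the
discriminative power of reflection coefficients for well-separated AR
classes; it does not predict accuracy on real recordings, where class
signatures overlap.

## Problem sizes and numerical choices

- Parameter-recovery experiments use the generator's own class bank
  truncated to p = 4, N = 3000 (one 6-s trial), 100+ seeded
  replicates; mean RMSE ≈ 0.015, halving roughly per 4× in N. At the
  full order p = 10 the statistical floor at N = 3000 is ≈ 0.018, so
  recovery bounds are asserted on means, not single draws.
- Oracle-equivalence tests compare the closed-form K_m with dense
  grid + parabolic-polish minimisation of the error power (the
  objective is exactly quadratic in K_m) to 1e−8 on signals of N ≤ 64.
- Unit and property tests run on a scaled-down corpus (2 subjects ×
  6 classes × 5 trials, 1.2-s trials); acceptance tests use the full
  900-trial protocol.
- All randomness flows through `numpy.random.default_rng` with
  explicit seeds; cross-validation records its seed and fold count in
  the result object.

## Known limitations

- The onset-trimming rule is a reasonable stand-in, not a validated
  activity detector; real deployments should check it against annotated
  onsets.
- ARFF support covers the numeric+nominal subset this pipeline writes,
  not the full format (no sparse data, strings, or dates).
- The MLP at WEKA-like learning rate 0.3 may report convergence
  warnings at 500 epochs on hard problems; this mirrors the fixed-epoch
  training it re-expresses.
- The "BayesNet"-style structured Bayesian classifier is not in the
  roster (its structure search is underdetermined); Gaussian naive
  Bayes is the Bayesian representative.
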