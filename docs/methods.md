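# Methods

## Problem setting

K binary classifiers each emit a per-sample probability vector over an
ordered class catalog (e.g. `Normal`, `Pneumonia`, positive class
`Pneumonia`). The task is decision fusion: combine the K probability rows
per sample into one fused probability row and prediction, and quantify
whether the fused model improves on its constituents. The package treats
learner training as external — inputs are score tables, not images or
model checkpoints.

## The metric-fused weight

For learner *i*, precision, recall, F1 and AUC are computed on a
weight-fitting split and summed through the hyperbolic tangent:
w⁽ⁱ⁾ = Σ tanh(x) over the four metrics. Design properties:

- tanh is strictly increasing on [0, 1], so the weight is monotone in
  every metric; each term is bounded by tanh(1) ≈ 0.7616 and the whole
  weight by 4·tanh(1) ≈ 3.046.
- Concavity on [0, 1] means marginal reward shrinks as a metric
  approaches 1: two mediocre metrics are worth less than their linear sum
  would suggest relative to two strong ones.
- Using four metrics rather than accuracy alone makes the weight sensitive
  to imbalance (precision/recall/F1 are class-aware) and to ranking quality
  (AUC is threshold-free).

Fusion is the weight-normalized convex combination of probability rows
followed by argmax. The combination is invariant to rescaling all weights
by a positive constant, and row normalization is conserved.

### Metric conventions

- **Predictions** are per-row argmax over catalog order; ties go to the
  lowest catalog index (deterministic).
- **Averaging mode.** Precision/recall/F1 are support-weighted across both
  classes by default; a positive-class-only mode is selectable
  (`mode="positive"`). Both are standard conventions for imbalanced binary
  reporting and the choice is recorded in the `MetricVector.mode` tag.
- **AUC** is the Mann–Whitney rank statistic on the positive-class
  probability column, ties at half credit; the trapezoidal area under the
  returned ROC curve equals it to machine precision (asserted in tests).
- **Zero denominators** (no predicted positives, no actual positives)
  yield metric 0 plus a `zero_division` flag instead of an exception, so a
  degenerate learner cannot abort a cross-validation run. AUC on
  single-class labels is an error, since no ranking question exists.

## Comparison ensembles

- *Average probability*: uniform weights.
- *Maximum probability*: per-class probability sums over learners,
  argmax. The sum is stored divided by K so the output stays a valid
  probability table; the scaling cannot change the argmax. (With this
  convention its predictions coincide with the average ensemble's;
  both are kept because both names circulate as baselines.)
- *Majority voting*: plurality over per-learner argmax votes. Vote ties
  (possible for even K) break by highest mean probability among tied
  classes, then lowest catalog index. In fold reports, the voting rule's
  score for AUC purposes is the positive-class vote share — the only
  ranking the rule itself induces; it is coarse (K+1 levels), and its AUC
  is expected to trail the probability-level methods.
- *Accuracy-only weighting*: convex combination weighted by each
  learner's plain accuracy on the fitting split — the scheme the
  tanh-fused weight is designed to improve on.

## Cross-validation protocol

Stratified k-fold (default k=5): within each class, samples are shuffled
by a seeded generator and dealt round-robin, so per-fold class counts
deviate from perfect stratification by at most one. Stratification can be
disabled. For each fold, weights are fitted on the training portion only
and evaluated on the held-out fold; flipping a held-out label provably
changes no fitted weight for that fold (leakage test in the suite). A fold
whose training portion is single-class raises an error naming the fold.

Aggregates are mean and standard deviation over folds. The std convention
is **population** (divide by k) by default, with the sample convention
selectable; the convention used is recorded in the report metadata so
reports remain comparable.

## Statistical comparisons

- **McNemar's test** on paired correctness, orientation fixed as
  b = (A wrong, B right), c = (A right, B wrong). For b + c < 25 the exact
  two-sided binomial p = min(1, 2·P(X ≤ min(b,c))), X ~ Bin(b+c, ½);
  otherwise the continuity-corrected χ² = (|b−c|−1)²/(b+c) on 1 df. The
  switch point is standard small-sample practice. Zero discordance returns
  p = 1 with a degenerate flag. Near-ties (|b−c| ≤ 1) are a known edge
  where the corrected χ² saturates at p ≈ 1 while the doubled exact p
  clips near 0.92; decisions agree there.
- **One-way ANOVA** on per-fold metric values (e.g. two groups of k
  accuracies), classical F on (g−1, N−g) df. All-identical data returns
  F = 0, p = 1 with a degenerate flag; zero within-group variance with
  group separation reports F = ∞, p = 0. Fold-level metrics are the
  replicate unit because they are the only repeated measurement the
  protocol produces.
- Decisions are reported at α = 0.05; p-values print to 4 decimals. No
  multiple-testing correction is applied.

## Score simulator

The simulator emulates K correlated binary classifiers with an
equal-variance binormal latent model: latent score of learner *i* on
sample *j* is √ρ·z_j + √(1−ρ)·e_ij (z shared, e idiosyncratic, both
standard normal), plus a positive-class mean shift d_i = √2·Φ⁻¹(AUC_i).
Under this model the theoretical AUC is exactly Φ(d/√2), so target AUCs
are hit analytically rather than by tuning. Latents map to positive-class
probability through the standard logistic with scale 1 — a strictly
increasing map, so AUC is preserved exactly; calibration is arbitrary and
not a contract. A single master seed spawns independent substreams for
labels and scores, so changing the learner list never perturbs the labels.

Defaults (chosen once): n = 2000 samples, positive prevalence 0.73
(the class imbalance typical of public pneumonia X-ray splits), three
learners with target AUCs (0.85, 0.88, 0.90), ρ = 0.3. What the simulator
does **not** emulate: miscalibration patterns of real CNNs, heteroscedastic
score distributions, structured failure modes (e.g. systematic errors on a
radiographic subtype), or inter-learner correlations that vary by class.
Passing tests therefore demonstrate correctness and internal consistency of
the fusion/evaluation machinery under a controlled generative model, not
expected performance on any real imaging dataset.

## Numerical and I/O choices

- Probability rows must sum to 1 within 1e-6; rows inside tolerance are
  renormalized exactly, rows outside raise with the offending sample id.
- Score CSVs serialize probabilities with 12 significant digits; the
  write→read round trip is the identity well below 1e-12.
- Class column order is the catalog order, never alphabetical; sample ids
  are opaque strings.
- All CLI outputs carry `# metricfuse <version>` / `# seed=<seed>` comment
  headers, and a fixed config + seed reproduces outputs byte-for-byte.

## Known limitations

- Binary tasks only; the simulator and AUC are binary, and multi-class
  generalizations are out of scope.
- Weight fitting assumes the fitting split is representative; with very
  small folds the four metrics are noisy and tanh weights approach
  uniformity in effect.
- The ANOVA on k folds has few replicates and inherits the usual caveats
  of treating fold metrics as independent observations.
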