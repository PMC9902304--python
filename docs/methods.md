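# Methods

## Problem and scope

Metric sex estimation treats the two sexes as two multivariate normal
populations over a fixed set of bone measurements and asks for a decision
rule applicable to an isolated bone. This package implements that workflow
for six linear patella measurements (maxh, maxb, maxt, haf, mafb, lafb, in
millimetres) as studied in pooled South African skeletal samples: a
generative model standing in for the unavailable collection data, the
classical linear discriminant analysis with its leave-one-out validation,
and a stacked machine-learning alternative, with identical evaluation
conventions throughout (male = positive class, balanced 130/130 design).

## Synthetic cohorts

Each sex is modelled as a multivariate normal with the published per-sex
mean vector and SDs, a shared correlation matrix, and per-variable
truncation to the published [min, max] ranges by whole-row rejection
sampling (capped at 1,000 attempts per requested row; implausibly tight
boxes raise an error rather than looping).

Two calibration details matter:

- **Moment matching.** Rejecting whole rows against a six-variable box
  shrinks marginal SDs by several percent and nudges means. Before the
  final draw, a fixed-point iteration (4 rounds on a 40,000-row calibration
  sample, driven by the same seeded generator) adjusts the pre-truncation
  means, SDs and correlations so the *output* distribution matches the
  configured values. The published summary statistics describe the observed
  (i.e. already-bounded) data, so matching output moments is the faithful
  choice.
- **Pooled vs within-sex correlation.** The published maximum pairwise
  correlation (0.81, maxb–lafb) describes the pooled 260-case sample.
  Pooling two groups whose means differ inflates every dimorphic pair's
  correlation above its within-sex value, so configuring 0.81 within sex
  would produce ≈ 0.89 pooled and wrongly trip the r > 0.85 redundancy
  filter. The default matrix (0.81 maxb–lafb; 0.65 for strongly coupled
  height/breadth pairs; 0.45 elsewhere — the full pooled matrix is not
  published) is therefore treated as the pooled target, and the shared
  within-sex generative matrix is recovered by inverting the equal-n
  mean-shift decomposition pooled-cov = mean within-cov + outer(Δμ/2),
  with a nearest-positive-definite projection as a guard.

Presets: the pooled sample (130/130) and per-population groups (SAAD 50/50,
SAED 50/50, MASA 30/30) with published per-group means/SDs; pooled ranges
are reused as bounds for the population presets. The generator is
deterministic in (spec, seed).

What the generator does *not* emulate: skewness (published medians differ
slightly from means), age/side/pathology structure, and any non-Gaussian
dependence. Passing tests on these cohorts therefore demonstrate
correctness of the statistical machinery under the Gaussian idealization,
not performance on real skeletal data — see "Known limitations".

A retest simulator perturbs a table with i.i.d. Gaussian measurement error
(default studies use ~0.3 mm), supporting reproducibility analyses with
Lin's concordance coefficient; at that error level all six coefficients
land in (0.95, 1.0), bracketing the published 0.974–0.998 band.

## Screening conventions

- Quartiles: linear interpolation between order statistics (the common
  statistical-package default).
- Rank-sum test: Wilcoxon–Mann–Whitney with the normal approximation and
  tie correction, no continuity correction (groups of 130 are far into the
  asymptotic regime; exact enumeration appears only in tests at n ≤ 10).
  Sign convention: Z = −(W_male − E[W_male])/σ, so Z is negative when males
  rank higher — the direction every patella measurement shows.
- Correlation filter: iterative greedy removal; for each pair with
  |r| > 0.85 the member with the larger mean absolute correlation to the
  remaining variables is dropped. Zero-variance columns have undefined
  correlations and are reported but never "removed".
- Z-score normalization uses 1/n SDs, is always fitted on training
  partitions only, and errors loudly on zero training SD.
- Lin's concordance coefficient uses 1/n (biased) variance/covariance
  terms, the original convention: P_c = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²).
  It is bounded by |Pearson r| with equality only on the identity line.

## Discriminant engine

Coefficients follow the "unstandardized canonical discriminant function"
convention of the major packages: w ∝ S⁻¹(μ_M − μ_F) rescaled so
wᵀSw = 1, with S the pooled within-group covariance (denominator N − 2)
and the male centroid positive; the constant −wᵀ(μ_M + μ_F)/2 puts the
equal-priors sectioning point at 0. This is the convention under which the
published coefficients are closed-form functions of the published group
moments (univariate: 1/s_pooled), verified analytically for all six
measurements. A score of exactly 0 is assigned female with an on-boundary
flag — an arbitrary but deterministic convention for a measure-zero event.
Exactly coincident group means cannot orient the axis; such fits are
flagged degenerate.

Leave-one-out validation refits means and covariance from scratch on every
held-out case (n honest refits). Average accuracy is the unweighted mean of
the sex-specific rates, which equals overall accuracy under the balanced
design. Stepwise selection minimizes Wilks' Λ greedily with partial
F-to-enter ≥ 3.84 and F-to-remove < 2.71 (the common package defaults; both
surfaced as arguments), iterated to a fixpoint. For two groups the partial
F at model size p is (n − 2 − p)(Λ_p/Λ_{p+1} − 1). Noise variables pass the
3.84 threshold about 5% of the time each — stepwise selection is a greedy
screening heuristic, not an inference procedure — so tests assert the
informative variable enters first rather than sole selection.

The registry of published equations (six univariate, one stepwise, five
direct multivariate) stores the printed coefficients verbatim; applied to
the published male and female mean vectors, every registry function scores
the correct side of 0.

## ML harness and stacking

Eight classifiers (LDA, logistic regression, k-NN, random forest,
extra-trees, AdaBoost, gradient boosting, XGBoost) run with library-default
hyperparameters and a fixed seed; hyperparameters are deliberately not
tuned. Evaluation is stratified 5-fold cross-validation with per-split
Z-score normalization; the confusion matrix accumulates over held-out folds
so each case is tested exactly once, and all metrics (with male positive)
derive from it. CI half-widths use the binomial normal approximation
1.96·√(p(1−p)/n) at the evaluated-case count — the convention that
reproduces the published ±half-widths (e.g. 90.77 → ±3.52 at n = 260)
exactly. Undefined metrics (zero denominators) are reported as missing,
never as 0. ROC/AUC uses trapezoidal integration, which equals the
normalized Mann–Whitney statistic.

Stacking: within each outer training partition, base learners train across
5 stratified inner folds and emit class-probability vectors for their
held-out inner fold; the assembled out-of-fold probability matrix (one
2-column block per base learner, rows summing to 1 per block) trains the
meta learner; outer-fold evaluation then uses base learners refit on the
full outer-train. The fold bookkeeping is retained so the no-leakage
property (no meta-feature row predicted by a model that saw it) is
assertable. An `argmax` meta rule is provided as a correctness probe: with
a single base learner it reproduces that learner's own out-of-fold
predictions exactly.

## Known limitations

- On these Gaussian cohorts a linear rule is already Bayes-optimal, so the
  stacking ensemble has no headroom over LDA-like decision surfaces. With
  the default gradient-boosting meta learner, stacking *underperforms* its
  base learners by several points here (the meta learner overfits a small
  out-of-fold probability matrix); linear or argmax meta learners are
  non-inferior. Reported gains of stacking on real skeletal data therefore
  reflect structure the Gaussian generator does not produce, and this
  package's synthetic experiments should not be read as evidence for or
  against stacking on real material.
- Synthetic LOOCV accuracies sit near the Gaussian-theory value
  Φ(d/2) for the standardized separation d implied by the published
  moments (≈ 79% for maxh), slightly below the published real-data 81.5%;
  reproduction targets on synthetic data are interval-valued, not
  point-valued.
- The published per-sex medians/quartiles (mild skewness) and the exact
  real-data classification rates are intentionally out of reach of a
  Gaussian generator.

## Problem sizes used

Tests and the acceptance checks run on the study-scale design: 130 cases
per sex, 5-fold cross-validation, 20-replicate averages for stochastic
claims, and 10,000-per-sex draws for moment-recovery checks.
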