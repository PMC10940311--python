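# Methods

## The gated stepwise model

The prediction target is the TIDE score, defined by routing: for sample *i*
with CTL indicator *c_i*, dysfunction score *d_i* and exclusion score *e_i*,

&nbsp;&nbsp;&nbsp;&nbsp;*y_i* = *d_i* if *c_i* = True, else *e_i*;&nbsp;&nbsp; responder ⇔ *y_i* < 0.

A score of exactly 0 is classed non-responder; the source convention defines
only "positive ⇒ non-responder, negative ⇒ responder", and the strict
less-than keeps the boundary deterministic.

Three sub-models share one miRNA feature space: a binary CTL classifier and
two independent regressors, each trained against its own score on **all**
training samples (the label table supplies both scores for every sample;
`subgroup_only=True` restricts each regressor to its routed subgroup, for
sensitivity analyses).  At prediction time the fitted classifier's call
routes each sample to one regressor, whose output becomes the predicted TIDE
score.  The routing invariant — every predicted TIDE value equals the routed
sub-regressor output — is asserted on every prediction batch.

The *direct baseline* is a single random-forest regressor on the TIDE score
itself.  Conditional on the CTL level the TIDE target mixes the dysfunction
and exclusion distributions, which are driven by different miRNA sets; a
single regressor must absorb that mixture, which is why the gated model wins
on held-out MSE.

Model families:

* **forest** — `RandomForestClassifier` / `RandomForestRegressor`.  Default
  hyperparameters are the tenfold-CV grid-search winners on the full
  real-data cohort: classifier `criterion="entropy"`, `max_features=None`,
  250 trees; dysfunction regressor depth 25, 700 trees; exclusion regressor
  depth 20, 300 trees.  `grid_search_cv` (exhaustive grid, tenfold shuffled
  KFold, ties broken by first grid order) is available but optional.
* **simple** — L2 logistic regression (liblinear, the reported best
  configuration) and ordinary least squares, on features z-standardized with
  training-split statistics only.  Zero-variance features are dropped with a
  warning.  This family is used after feature selection, where the feature
  count is small relative to the sample count.

The 80/20 train/test split is stratified on CTL level by default — the
source does not state stratification; it is chosen so the rare CTL-low class
stays represented in the test split.  The classifier's decision threshold is
the estimator default (0.5 posterior).

## Evaluation

Classifier: precision, recall, F1 = 2·(recall·precision)/(recall+precision)
for the positive ("True" = CTL-high) class, sensitivity, specificity,
balanced accuracy = (sensitivity+specificity)/2, and ROC-AUC, which equals
the Mann–Whitney pairwise-rank statistic with midrank tie handling (the tie
convention is a package choice).  Regressors: MSE = (1/N)·Σ(fᵢ−yᵢ)² and the
sample Pearson correlation; both regressors are scored on **all** test
samples against their own score, with routed-subset metrics additionally
emitted for transparency.  The end-to-end routed prediction is scored
against the observed TIDE score.  Degenerate inputs (single-class truth for
AUC, zero-variance vectors for PCC) raise explicit errors; MSE-only
evaluation of constant targets is available via `include_pcc=False`.

## Shapley attribution

`shap` the library is not a dependency; the attribution engine is part of
this package:

* **Tree models** — exact path-dependent tree Shapley values.  The value
  function is the cover-weighted conditional expectation of the tree output
  (splits on in-coalition features follow the sample; other splits average
  both branches by training cover).  The polynomial algorithm carries the
  permutation weights of all subset sizes along each root-to-leaf path
  (EXTEND/UNWIND bookkeeping), giving per-leaf Shapley contributions in
  O(depth²).  It is implemented as a numba-jitted explicit-stack DFS and is
  tested for exact agreement (≤1e-9) with brute-force coalition enumeration
  on small trees, including trees that reuse a feature along a path.
  Forest attributions are the mean of per-tree attributions, matching the
  forest's mean-of-trees prediction.  Classifier attributions are on the
  positive-class **probability** (per-node class proportions).
* **Simple models** — the closed-form linear attribution
  φⱼ = βⱼ·(xⱼ − E[xⱼ]) with the training set as background, computed on the
  standardized feature scale the model consumes.  Logistic attributions are
  on the log-odds **margin** (the linear scale), since the probability is
  not additive in the features.

Every route satisfies local accuracy — attributions sum to the model output
minus the expected value — and the null-player property (a feature no tree
splits on gets exactly zero).  The attributed output space
(probability/margin/raw) is recorded in the importance table's metadata,
because mean-|φ| values are only comparable within one output space.

Importance is computed on the held-out test partition by default
(configurable): attribution on unseen samples reflects generalizable
structure rather than training-set memorization.  Features are ranked by
mean absolute attribution, descending, ties broken by feature name.

## Selection and refit

A feature is informative for a sub-model when its mean |φ| is ≥ τ, with
τ = 0.01 (and a stricter 0.02) by convention; the threshold is inclusive
("0.01 or higher"), so the 0.02 selection is always nested inside the 0.01
one.  Selection is per-sub-model, not pooled.  An empty selection is legal
(it warns) but blocks the refit.  The refit swaps in the simple family on
the selected features, standardized with training statistics.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at configurable
scale:

* **Expression** — per-miRNA lognormal RPM counts (log-mean ~ N(2, 1.5²),
  log-SD ~ U(0.4, 1.2)) transformed to log₂(RPM+1), matching the scale and
  right skew of real miRNA quantifications.  Default feature count 1,881,
  the size of the real per-sample miRNA panel.
* **CTL level** — Bernoulli under a logistic model on a small planted miRNA
  set (default 5 features, standardized coefficients ±`effect_size`, default
  1.0), with the intercept calibrated by root finding so the realized mean
  CTL-high probability equals `ctl_high_fraction` (default 0.9 — the real
  class balance is not published; 0.9 is inferred from the near-perfect F1
  alongside a much lower balanced accuracy, and remains configurable).
* **Scores** — dysfunction and exclusion are linear in their own planted
  sets (disjoint from each other and from the CTL set by default; an
  overlap option exists because real informative miRNAs recur across
  sub-models) plus N(0, `noise_sd`²) noise, default SD 0.25 against a signal
  SD of ≈ √5 ≈ 2.2.  The TIDE score and responder call follow the routing
  and sign rules.
* **Truth record** — planted indices, generative coefficients, and the
  feature moments used for standardization; with `noise_sd=0` the scores are
  exactly reconstructible from the record (checked to <1e-9).
* Optional additive per-tumor-type block shifts (off by default).  A single
  RNG stream per cohort, seeded from `config.seed`, makes equal seeds give
  byte-identical cohorts.

What the generator does **not** emulate: count-level noise, miRNA–miRNA
correlation structure, batch effects, nonlinear or interaction effects, and
the dependence of the two scores on shared biology.  Passing tests therefore
demonstrate the machinery — routing, recovery, selection, exactness of the
statistics — under a known generative model, not performance on real tumors.

The synthetic target-gene resources (`generate_target_resources`) extend the
same idea downstream: a scored source with prediction scores uniform on
[50, 100], an unscored second source with 80% overlap, and a gene-set
collection whose first three sets are concentrated on targets of the planted
miRNAs, so a correct selection yields detectable enrichment.

## Target intersection and over-representation

A gene is a high-confidence target of a miRNA when it appears in the
unscored source *and* in the scored source with prediction score ≥ 80
(inclusive; the scored database's own reliability guideline).  Raising the
threshold can only shrink the sets.  The pooled target list of the selected
miRNAs is tested per gene set with the one-sided hypergeometric upper tail
P(X ≥ k) for overlap k under (M, K, n) — the standard statistic behind
web-based enrichment services — adjusted across sets by Benjamini–Hochberg
(the adjustment method is recorded in the module, since the source names
only the service).  The background universe defaults to the union of all
supplied set members and is overridable.  Significance is adjusted P < 0.05
(strict).  Exactness is tested against full enumeration of all query draws
on universes of ≤ 25 genes.

## Numerical and scale choices

* Forest sizes in the test suite, CLI desk preset and acceptance script are
  60–80 trees with bounded depth and feature subsampling — the package's
  desk-scale setting for simulated cohorts of a few hundred features; the
  library defaults remain the full-cohort grid-search winners.
* Test cohorts use 500–2,000 samples and 120–200 miRNAs; the
  stepwise-vs-direct comparison uses n = 2,000 with 200 miRNAs over five
  seeds.
* All randomness flows from explicit integer seeds; fits are
  single-threaded, so reruns are bit-identical, and the CLI's text outputs
  are byte-identical under a fixed seed.
* Attribution tolerances: local accuracy 1e-6 (observed ≈ 1e-15),
  brute-force agreement 1e-9 (observed ≈ 1e-16); metric oracle agreement
  1e-10.

## Known limitations

* The TIDE label-side logic is consumed, not recomputed: dysfunction and
  exclusion scores enter as inputs (real analyses) or are simulated (tests);
  the signature-level TIDE computation is out of scope.
* Tree-model attributions are path-dependent (cover-conditioned); they are
  not interventional Shapley values against an explicit background dataset.
* The simple-model classifier is attributed on the margin, so its mean-|φ|
  values are not numerically comparable with the forest classifier's
  probability-scale values at the same τ.
* Grid search at the full published grids is supported but slow at desk
  scale; defaults pin the published winners instead.
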