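# Methods

## The Biomarker Identifier score

`bmfilter` ranks the features of a two-group expression matrix (control vs
experiment, features in rows) by the Biomarker Identifier (BMI) score

    score(x) = λ · TP² · |Δ_diff| · CV_ctr / CV

with, per feature x:

* **TP² = TP_ctr · TP_exp** — the product of the per-group true-positive
  rates of a one-covariate logistic regression of group on x.  The feature
  is z-standardized and fitted by Newton/IRLS with an L2 ridge of 1e-4 on
  the slope (never the intercept), at most 100 iterations, tolerance 1e-8.
  The ridge makes perfectly separable and constant features well-defined
  (no diverging slope), and standardization makes the fitted probabilities
  — hence TP² — invariant to the feature's measurement scale.  Samples are
  classified as *experiment* when the fitted probability is ≥ 0.5 (the
  boundary ties to experiment, deterministically); TP rates are
  resubstitution rates on the samples used for the fit.
* **Δ_diff = (mean_exp − mean_ctr)/|mean_ctr|** — the signed relative mean
  difference; positive is read as over-expression in the experiment group,
  negative as under-expression, and the sign becomes the score table's
  `direction` column.  An alternative `all_vs_ctrl` mode uses
  (mean_all − mean_ctr)/|mean_ctr|.
* **CV_ctr / CV** — the control-to-overall coefficient-of-variation ratio
  (CV = SD/|mean|, SDs with ddof 1).  A feature whose overall behavior is
  noisier than its control behavior (CV > CV_ctr) is penalized; one that
  becomes *more* consistent when the experiment group is included is
  credited.  This is the score's heteroscedasticity term.
* **λ** — a pure scale factor, default 1.0.  It rescales every score
  equally and never changes ranks.

All four factors are invariant under multiplication of a feature by a
positive constant, so BMI does not depend on per-feature units.  Scores are
non-negative; a feature with zero overall variance, zero TP², or zero
Δ_diff scores 0.  Features whose control or overall mean is within ε =
1e-12 of zero have no defined CV: they score 0 with a warning by default
and raise in strict mode.  Because CV and Δ_diff divide by means, the score
is *not* invariant under additive shifts: it is intended for strictly
positive expression summaries (e.g. RMA-scale values) and this
scale-sensitivity is inherent to the definition.

## Comparator filters

Six standard filters are implemented for comparison, each returning the
same ranked score-table structure (descending score, ties get the average
of the tied positions so ranks always sum to n(n+1)/2):

* **Information gain** — IG(x) = H(Y) − Σ_b p(b) H(Y|X∈b) in bits, over a
  supervised discretization of x.  Default discretization is Fayyad–Irani
  recursive binary entropy partitioning with the MDL stopping rule
  (candidate cuts at midpoints between adjacent distinct values; a cut is
  accepted when the information gain exceeds (log2(N−1) + log2(3^k−2) −
  kH(S) + k₁H(S₁) + k₂H(S₂))/N).  MDL may return zero cuts, in which case
  the feature scores 0.  Equal-width binning (default 10 bins) is available
  as a label-free alternative.
* **Chi-squared** — Pearson's Σ (O−E)²/E over the bins × groups table of
  the same discretization, empty bins dropped.
* **Relief-F** — Kononenko's instance-based weights with k = 10 neighbors
  by default and all samples probed (deterministic); per-feature
  differences are min-max normalized, distances are Manhattan, neighbor
  ties break to the lowest sample index, and with two classes the
  miss-class prior weight is 1.  Constant features get weight 0.
* **Welch t** — (mean_exp − mean_ctr)/√(s²_exp/n_exp + s²_ctr/n_ctr),
  ranked by |t|.  When both group variances vanish the statistic is +∞ if
  the means differ and 0 otherwise (documented convention).
* **Moderated t** — empirical-Bayes shrinkage of the pooled gene-wise
  variances s²_g (df d_g = n_ctr + n_exp − 2) toward a scaled
  inverse-chi-square prior: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with
  (d₀, s₀²) estimated by matching the first two moments of log s²_g using
  digamma/trigamma identities (the trigamma equation is solved by Newton
  iteration).  Homogeneous variances give d₀ = ∞ and complete shrinkage;
  d₀ = 0 recovers the ordinary Student t.  The implementation was verified
  against limma's `squeezeVar` to 6+ decimals.  The pooled (Student) form
  is used; a Welch-variance variant would be a configuration extension.
* **Window t** — genes are sorted by overall mean expression and each
  gene's pooled variance is replaced by the moving average over a
  `window`-gene neighborhood at its sort position (truncated at the ends;
  even window sizes round up to odd).  Default window is 99 genes, about
  0.5 % of a 22k-feature array; window = 1 is the Student t and a full
  window ranks by |mean difference|.

The t-family ranks by the absolute statistic rather than a p-value; for
equal degrees of freedom (which hold by construction across genes within
each method) the orderings coincide.

## Evaluation protocols

**AUC** is the Mann–Whitney probability that a random experiment sample
scores above a random control sample, ties counted ½ (computed from
average ranks).

**Selection-inside-CV** (`cv_selection_eval`): samples are split into 10
stratified folds (stratification is a deliberate default — group sizes are
unequal in the emulated design — with fold membership a deterministic
function of sample IDs and the seed).  For each fold, the selection method
ranks features using only the other nine folds; the classifier is trained
there on the top-n features for n = 1..60 and scored on the reserved fold;
fold AUCs are averaged (not pooled).  Single-class test folds are skipped
with a warning and excluded from the mean.  A deliberately *leaky* mode
ranks once on all samples first; it exists purely as a negative control —
on null data it inflates the apparent maximum AUC dramatically while the
honest protocol stays at chance, which is the package's own check that the
protocol cannot leak.

**Train/validation split** (`split_eval`): features are ranked once on the
training set; the AUC-versus-n grid comes from 10-fold CV entirely within
the validation set using that fixed list.

**Median ranks** (`median_ranks`): for externally validated genes, each
fold's ranking again uses only the training portion, and the median of the
10 fold-wise ranks is reported per method and gene.

Native classifiers — Gaussian naive Bayes (posterior probability of
experiment as the score) and k-NN (k = 1, inverse-distance-weighted
experiment fraction, distance ties to the lowest training index) — keep
the evaluation harness dependency-free; `sklearn:svm`, `sklearn:rf` and
`sklearn:mlp` adapters are optional plug-ins.  Adapters must expose a
continuous score, never just a label.

**Confusion metrics**: sensitivity is the recall of the experiment class,
specificity the recall of the control class.

## Enrichment

Over-representation of a top-k symbol list in GMT gene sets uses the exact
hypergeometric upper tail P(X ≥ k) (one-sided Fisher).  The universe
defaults to the collection's own union of symbols and is configurable; raw
p-values below α = 0.05 are reported sorted ascending (ties by set name,
so output is byte-reproducible), with no multiple-testing adjustment by
default and Benjamini–Hochberg as an option.  Probe→symbol maps drop
unmapped probes with a counted warning and collapse duplicate symbols
keeping first (best-ranked) occurrence.

## Synthetic data

The generator emulates an RMA-summarized two-group cohort: 69 control and
60 experiment samples by default (the bronchoscopy smokers-with/without-
lung-cancer design), 2000 features on a log2-like scale with per-gene
values ~ Normal(8, 1).  Planted features (default 20) shift the experiment
mean by `effect` control-SD units with a random recorded sign and scale
the experiment SD by `var_ratio`; `var_ratio` ≠ 1 exercises the BMI
CV-ratio term directly (> 1 penalty, < 1 credit).  Values are clipped at
0.01 to stay strictly positive so CVs are defined.  Each feature has its
own counter-based stream keyed by (seed, feature index), making the
generator seed-deterministic and stable under array enlargement.  Features
are independent by default; an equicorrelated-block option (ρ within
consecutive blocks) is available for stress tests.

What the generator does *not* emulate — probe-level noise, batch effects,
correlated co-expression modules (by default), missingness, heavy tails —
bounds what passing benchmarks show: they demonstrate that the methods and
protocols are implemented correctly and behave as designed under the
stated model, not that any method will achieve the same recall on real
microarray cohorts.

## Numerical choices and degenerate inputs

* SDs and variances use ddof 1 throughout.
* Rank ties take the average of tied positions; neighbor/argmax ties break
  deterministically to the lowest index; logistic probability exactly 0.5
  classifies as experiment.
* The IRLS ridge (1e-4), iteration cap (100) and tolerance (1e-8) are
  fixed; the linear predictor is clipped at ±35 before the sigmoid to
  avoid overflow without affecting classifications.
* Missing values are rejected at load, never imputed; groups with fewer
  than 3 samples are rejected because every statistic needs within-group
  variances.
* Problem sizes in the test benchmarks (2000 features × 129 samples for
  recovery, 300 features × 120 samples for the null-protocol checks, 500
  genes for prior recovery) were chosen as the smallest scales at which
  the corresponding behavior is scientifically meaningful.

## Known limitations

* BMI's CV terms presuppose strictly positive, ratio-scale expression
  values; on log-ratio data with near-zero means the score degrades to
  warnings/zeros by design.
* TP rates are resubstitution rates; an inner split would lower them on
  tiny samples.
* The moderated t is the pooled-variance form only.
* Relief-F is O(n²) in samples (full distance matrix); for cohorts beyond
  a few thousand samples a subsampled `m` should be used.
* The enrichment universe choice materially changes p-values; the default
  (union of the collection) is only one defensible choice and should be
  set explicitly when a measured background is available.
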