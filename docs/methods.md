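# Methods

## The model

The scorer is a small one-dimensional convolutional network over a
per-variant annotation vector of length `input_len` (default 141). The
annotation vector is treated as a single-channel sequence:

| layer | operation | default output |
|---|---|---|
| conv1 | valid 1-D convolution, kernel 5, 32 maps, GELU | (137, 32) |
| pool1 | max over adjacent pairs, trailing element dropped | (68, 32) |
| conv2 | valid 1-D convolution over all input maps, kernel 5, 64 maps, GELU | (64, 64) |
| pool2 | max over adjacent pairs | (32, 64) |
| flatten | position-major, map-minor (k = i·maps + j) | 2048 |
| dense | fully connected, GELU | 16 |
| dropout | Bernoulli mask, p = 0.1, training only | 16 |
| output | fully connected, sigmoid | 1 |

GELU is the Gaussian-CDF form x·Φ(x) (not the tanh approximation). The
loss is mean binary cross-entropy with predicted probabilities clamped to
[1e−7, 1−1e−7]; the optimizer is Adam with learning rate 0.001
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8), mini-batches of 32, 50 epochs. The
functional-significance score of a variant is the trained network's
positive-class probability, with dropout disabled.

## Semi-supervised procedure

Labeled variants are split 80/20 (uniform shuffle, round-half-up test
size); the 20% test split never enters training. The training split is
partitioned into five stratified folds; each leave-one-fold-out model
scores the entire unlabeled pool, so each pool variant carries five
out-of-fold probabilities. Retention uses a two-sided one-sample
Student's t-test of those five values against 0.5 at p < 0.05: variants
whose predictions sit consistently away from the decision boundary
survive. Retained variants are labeled by their mean probability against
symmetric cuts 0.5 ± δ (above → pseudo-positive, below → pseudo-negative,
between → discarded), with δ ∈ {0, 0.1, 0.2, 0.3, 0.4} searchable by
held-out AUC after retraining; δ = 0.4 (the 0.9/0.1 rule) is the default.
The merged labeled + pseudo-labeled set is retrained under fivefold
cross-validation and the fold model with the highest held-out-fold AUC is
the final model. Pseudo-labeled and labeled examples are weighted
equally, and pseudo-labeling runs for a single round.

Interpretation choices where the procedure is underdetermined:

- **t-test null.** The consistency test is read as a one-sample test of
  the five fold probabilities against 0.5 — the reading under which
  retention means "confidently away from the decision boundary". A
  variance-style test across folds is a defensible alternative; it is not
  what is implemented.
- **Zero-variance rows.** Five identical probabilities leave the
  t-statistic undefined; perfect agreement is maximal consistency, so the
  variant is retained iff its common value differs from 0.5.
- **Aggregation.** Thresholds apply to the mean of the five
  probabilities.
- **Grid ties** break toward larger δ (fewer, higher-confidence labels);
  the final model is chosen per fold by held-out AUC, first fold wins
  ties.
- **Stratified folds** guarantee both classes in every training split;
  plain unstratified shuffling is used only for the 80/20 split.

## Dataset construction rules

Positives: the intersection (by (chrom, pos, ref, alt) coordinates) of
two variant sets. Negatives from association tables: P > 0.1 AND
AF > 0.3, both strict. Curated negatives around known positives: same
chromosome, distance ≤ 1000 bp (inclusive), conservation < 0.5, AF > 0.3,
never itself a positive. Random-genome negatives: chromosomes sampled by
length, positions uniform, rejected within `min_dist` of any positive,
with an attempt cap to surface infeasible settings. Multi-allelic VCF
records are split into biallelic records; symbolic/non-ACGT alleles are
rejected; positions are 1-based.

## Feature selection

A name-based predicate first restricts to a domain subset (e.g. features
named for immune cell types; the list is caller-supplied). Ranking is by
mutual information (k-nearest-neighbor estimator, 3 neighbors, seeded) or
random-forest Gini importance (500 trees, √p features per split, seeded),
followed by top-k selection (default k = 141) with ties broken toward the
earlier column, which makes nested selections monotone.

## The synthetic generator

Real annotation features are unavailable offline, so the generator draws
class-conditional spherical Gaussians: `n_informative` columns are
shifted by `effect` in positives, all other columns are N(0, noise_sd²)
in both classes. This makes the Bayes-optimal AUC analytic,
Φ(d/√2) with d = effect·√n_informative / noise_sd, which the tests use as
an oracle. The unlabeled pool draws its hidden class from
Bernoulli(prevalence); the truth is returned out-of-band so pseudo-label
precision can be audited without leaking labels into the pipeline. Mock
eQTL tables plant an exact number of rows passing the negative filter.
Defaults (500+500 labeled, 141 features, 20 informative, effect 3, pool
2000 at prevalence 0.5) define the benchmark conditions used by the
acceptance script; at these settings the classes are nearly separable, so
AUCs saturate and the informative checks are pseudo-label fidelity
against the hidden truth and the no-harm comparison with the supervised
baseline. The generator does not emulate feature correlations, linkage
disequilibrium between variants, heavy-tailed annotation distributions or
label noise — passing tests show the machinery is correct, not that the
model transfers to real annotation data.

## Numerical choices

- Weights are Glorot-uniform, biases zero, all draws from one seeded
  generator that also drives epoch shuffling and dropout masks, making
  training bit-reproducible for a fixed configuration and platform.
- Training runs in float32. Φ is evaluated by a rational erf
  approximation accurate to ~3e−7 (below float32 resolution) on the
  float32 path and by the double-precision CDF routine on the float64
  path; the Gaussian factor computed inside the approximation is cached
  and reused for the backward pdf. A thin optional Cython layer fuses
  these elementwise kernels; results match the numpy fallback to float32
  precision.
- Dropout uses the inverted convention (mask scaled by 1/(1−p)) so
  inference needs no rescaling; it is disabled at scoring time.
- Max-pooling drops a trailing odd element (137 → 68), as the printed
  shapes require; gradient routes to the argmax, earlier position on
  ties.
- The decision threshold maximizes Youden's J over midpoints between
  consecutive distinct scores (rule: score > threshold); perfectly
  separated classes get the gap midpoint, all-equal scores fall back
  to 0.5.
- Metric edge cases: AUPRC is average precision (step rule, no
  trapezoidal interpolation); zero-denominator metric cells report 0 with
  an explicit flag.

## Problem sizes

Unit tests run miniature configurations (tens of variants, reduced
architectures, few epochs). The semi-supervised recovery check and the
acceptance script use the full benchmark conditions above with the
default architecture and 50 epochs — five seeds in the test suite, one
configurable seed in the script.

## Known limitations

- The pseudo-label stage assumes the pool is drawn from the same feature
  distribution as the labeled data; covariate shift would silently bias
  the pseudo-labels.
- Probabilities are not calibrated; the 0.9/0.1 cuts act on raw sigmoid
  outputs.
- Single-round pseudo-labeling only; no iterative self-training.
- The seven-metric report fixes the metric set to AUC, AUPRC, accuracy,
  precision, recall, F1 and specificity.
- No genome-build liftover and no LD-aware reasoning about proxy/sentinel
  variants; variant identity is coordinates-plus-alleles.
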