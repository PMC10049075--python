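# Methods

`ummetab` implements a peripheral-blood untargeted-metabolomics analysis
protocol for small case–control cohorts: LC-MS feature tables measured in
two ionisation polarities across a discovery and a replication batch are
filtered, normalized against spiked internal standards, merged, and then
interrogated with a cross-validated random-forest classifier, sample
embeddings and a per-feature differential-abundance screen. This note
records the model assumptions, the parameter choices and the places where
the design was genuinely open.

## Data model

A `FeatureTable` is an `n_features x n_samples` matrix with per-feature
m/z, retention time and ion mode. Zeros in raw tables mean "below
detection"; there are no missing cells. Tables move through one-way
transform states `raw -> log1 -> z` (natural `log(1+x)`, then per-feature
standardisation with population sd), and every stage checks the state of
its input. Positive- and negative-mode tables are separate objects
analysed independently end to end, because metabolites often ionise in
only one polarity; results are reported per mode.

Technical/biological replicates are carried in metadata (`role =
replicate_of:<id>`) but never merged; the LOOCV engine accepts
fold-exclusion groups so replicates of one subject leave the training set
together.

## Feature filtering

All strictly positive `log1` values of a table are pooled across features
and samples; the 2nd percentile of the pool (linear interpolation between
order statistics) is the detection threshold, and a feature is retained
when at least 5 samples lie strictly above it. Choices worth noting:

* the percentile convention is linear interpolation — the most common
  definition — and is pinned by an order-statistics oracle test;
* "above" is read strictly; the boundary (exactly 5 samples above) is
  unit-tested;
* the pool is computed after log transformation, on the same table being
  filtered, per ion mode and per batch (the transformation is monotone,
  so only the interpolation step can differ between the two orders);
* spiked standards are exempt from removal — they must survive to anchor
  normalization;
* merged analyses keep only features detected (post-filter) in both
  batches, by feature-id intersection.

## Internal-standard PC-regression normalization

Ten internal standards are spiked into every sample at fixed
concentration, so systematic variation in their measured abundances is
technical by construction. The internal-standard rows are centered (not
scaled — the standards share a concentration scale) and decomposed by
SVD with samples as observations; the first two sample-score vectors
summarise the technical variation. Each well-detected feature (strictly
more than 75% of samples above zero) is regressed on these two score
vectors with a Bayesian ridge (data-driven regularization; at high
signal-to-noise it coincides with ordinary least squares, which is
oracle-tested), and the feature is replaced by `residual + feature mean`.
Sparser features pass through with their original log abundance.

Open points settled here:

* outlier samples (per-feature |Z| > 3, computed on the raw feature row
  before fitting) are excluded from the fit but still corrected with the
  fitted coefficients — every sample must emerge normalized;
* the regression removes only the PC-explained component and re-centers
  at the overall feature mean (no per-batch re-centering);
* the sign of each PC score vector is fixed by making its
  largest-magnitude entry positive, so results are deterministic and
  invariant to the ordering of the standards;
* a degenerate model (standards with no variance) leaves the table
  unchanged rather than re-centering it.

The merged-dataset path is per-batch PC regression, then feature
intersection, then Z-transform. Four diagnostics judge the correction:
the WTR score (mean over features of pooled within-batch variance over
total variance; 1 = no batch component), mean pairwise Pearson
correlation of QC profiles, and 5-fold cross-validated balanced
accuracies of a default random forest predicting batch labels or
QC-versus-study labels (both should drop toward 0.5 after a successful
correction). These are internal diagnostics with the definitions above,
not cross-package comparables. With a single batch or fewer than two QC
samples the corresponding metrics are reported absent, never zero.

## Classification engine

The validation engine is a leave-one-out cross-validation of a random
forest (150 trees, maximum depth 100). Inside each training fold — and
only there — every class is oversampled with replacement to 200 rows and
i.i.d. Gaussian noise with sd 0.25 is added as regularization. Applying
either step before the split would leak (noisy copies of) the held-out
sample into training and inflate every metric, so the leakage-free
ordering is the only one the pipeline uses; the fold builder is public
(`make_training_fold`) for anyone who wants to study the inflated
variant. The "N(0, 0.25)" noise convention is read as sd = 0.25; the
config field is an sd, so the variance reading is one line away.

Held-out class probabilities come from `predict_proba` (the mean of
per-tree leaf probabilities, which at depth 100 is in practice the
fraction of trees voting for the class). Argmax ties resolve to the
first class in sorted label order. For binary tasks the positive class is
the disease class (UM); the ROC is computed over held-out positive-class
probabilities, and the AUC is summarised as mean ± sd over 25 bootstrap
resamples of the (score, label) pairs, with the rank/Mann–Whitney tie
convention and resamples lacking a class redrawn. Robustness is assessed
by repeating the LOOCV ten times on random 50% per-class subsamples
drawn without replacement and re-drawn independently per repeat.

All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning (per fold, per repeat, per
bootstrap), so a run is bit-reproducible on one platform while repeats
stay independent.

## Embeddings

PCA and t-SNE explore unsupervised structure; PLS-DA (PLS2 on one-hot
labels, so four groups fit in one model) gives the supervised view.
PLS-DA separates groups very easily, which is exactly why it is
visualisation-only here — the cross-validated classifier is the
inferential criterion. t-SNE is stochastic and carries only structural
guarantees (shape, determinism under a fixed seed); perplexity defaults
to 30 and is not claimed to match any particular published figure.
Per-group 95% confidence ellipses use the sample mean and covariance
scaled by the chi-square quantile with 2 df (5.991), the standard
construction.

## Differential-abundance screen

Per feature: a Welch two-sample t-test UM versus control (the
equal-variance variant is a config switch) and a Pearson correlation with
longest tumor diameter over UM samples, both on the transformed scale;
Benjamini–Hochberg adjustment of each p-value family (Bonferroni
available); and a joint flag for features passing both adjusted tests at
alpha = 0.05. The p-value histogram diagnostic reports bin counts and a
chi-square uniformity statistic over the right-tail bins (p > 0.2): true
signals spike near zero while a calibrated null stays flat.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not chromatography. On the log scale, feature j in sample i is

    y_ij = mu_j + batch_ij + delta_j·[UM] + s_jg·[subclass g] + eps_ij

with `mu_j ~ N(8, 1.5^2)`, `eps_ij ~ N(0, 0.4^2)`, and raw abundance
`exp(y_ij)` zeroed with probability 0.05 (never for standards or QC).
Default group sizes are the study design's: discovery 46 controls + 37 /
16 / 15 UM subclasses, replication 19 / 17 / 9 with no controls. Ten
internal and seven external standards are present in both modes with
instrument noise sd 0.05. QC samples are low-noise replicates of the
pooled mean profile. A designated feature pair is generated with a
chosen correlation with tumor diameter. Batch effects are multiplicative
per-feature offsets `b_j ~ N(0, sd^2)` on the replication batch, drawn
from the same distribution for standards and features; in `share_exact`
mode both instead load on the same two sample-level latent factors, which
is the positive control for PC regression — only variation expressible in
the standards' PCs can be removed.

The share_exact stress preset (`share_exact_stress_config`) uses
batch sd 1, no group effects and no dropout: it isolates the removable
technical component so that batch-mean-difference reduction measures the
normalization itself. With the default 5% dropout the zero-vs-nonzero
sampling noise in batch means (~0.3 on the log scale) would dominate the
measurement; dropout behaviour is exercised by the filtering,
classification and calibration tests, which keep the default.

What the generator does *not* emulate — retention-time drift, peak-shape
artifacts, adducts and isotopes, annotation ambiguity, correlated
metabolite modules, age/storage confounding — bounds what passing tests
show: they validate the statistical machinery under the stated model, not
the biology of any real cohort. No effect sizes for real discriminating
metabolites are published for this setting; the simulation defaults
(2-sigma shifts on 40 of 120–200 features in the stress cohorts) are
stress-test values.

## Problem sizes and numerical choices

Simulated tables carry 120–200 features per mode rather than the
thousands of a real acquisition, and the permutation-null cohort is
smaller than the full design (45 samples); these sizes keep the test
suite and the acceptance script at desk scale while leaving every
statistical property intact. Tolerances: oracle comparisons for the
percentile, BH and bootstrap-AUC primitives are exact to 1e-12; PCA/PLS
score comparisons to 1e-8; stochastic checks use binomial or
permutation bands stated in each test. Degenerate inputs (constant
features, zero-variance standards, single batches, all-zero pools) are
handled explicitly and unit-tested rather than left to exceptions.

## Known limitations

* The normalization metrics follow the definitions above; other
  implementations of similarly named scores may scale differently.
* LOOCV with per-fold forests is O(n) forest fits; cohorts beyond a few
  hundred samples will want a coarser CV.
* The screen treats features independently; correlated features make the
  BH control conservative in the usual way.
* PLS-DA explained-variance fractions refer to the feature block of the
  deflated model, not to label variance.
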