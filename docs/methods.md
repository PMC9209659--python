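# Methods

`methsub` implements a DNA-methylation molecular-subtyping analysis for
tumor cohorts profiled with 450K-style beta-value arrays plus matched
expression: feature selection by integrating differential methylation
with negatively correlated expression, subtype discovery by resampling
consensus clustering, prognosis comparison, entropy-based calling of
subtype-specific markers, and a subtype classifier for new cohorts. A
synthetic-cohort generator with planted ground truth makes every stage
testable without access to a real cohort.

## Preprocessing

Expression matrices arrive as non-negative counts/FPKM-like values;
zeros are replaced by the matrix-wide minimum positive value and the
matrix is log2-transformed. Methylation is a probe x sample matrix of
beta-values in [0, 1]. Probes missing in *more than* 70% of samples are
removed (the boundary is retained); remaining gaps are imputed by a
probe-wise k-nearest-neighbour rule (default k = 10): the distance
between two probes is the Euclidean distance over samples where both are
observed, and a missing entry becomes the mean beta, at that sample, of
the k nearest probes observed there. This donor convention is
implemented directly (a means of neighbours is always inside the donors'
range, so imputed values stay in [0, 1]); it intentionally does not
rescale distances by missingness the way `sklearn`'s nan-Euclidean
metric does. Probes flagged as SNP-overlapping and probes on sex
chromosomes are dropped, and analysis is restricted to promoter probes:
2 kb upstream to 0.5 kb downstream of the TSS, strand-relative (for the
minus strand the window is reflected around the TSS; the upstream bound
is closed, the downstream bound half-open, all coordinates 0-based).
Each stage is idempotent on its own output.

## Differential screens

Both tumor-vs-normal screens use a Welch unequal-variance t test with
Benjamini-Hochberg adjustment across all features, plus an effect gate:
genes are called at |log2 fold change| > 1 (fold change > 2 on the
geometric-mean scale) and BH q < 0.05; CpGs at |mean beta difference| >
0.20 and BH p < 0.05. The fold-change screen's q threshold defaults to
0.05 and is configurable. A defined two-sample statistic was chosen over
moderated-variance machinery so the stage is self-contained and exactly
testable; degenerate zero-variance features receive p = 1.

## Feature integration

Promoter methylation tends to repress transcription, so classification
features are the called CpGs whose annotated gene is itself called and
whose beta correlates negatively with that gene's log2 expression:
r < 0 and p < 0.05, with

    r = 1/(n-1) * sum_i ((X_i - Xbar)/s_X) ((Y_i - Ybar)/s_Y)

(sample standard deviations) and the exact two-sided p-value from
t = r sqrt((n-2)/(1-r^2)) on n-2 df. Correlations default to all shared
samples (tumor-only is available); each probe links to one promoter
gene.

## Consensus clustering and choice of k

For each k in 2..10, 80% of tumors are drawn without replacement 100
times and each subsample is partitioned by k-means (squared Euclidean,
Lloyd iterations capped at 300, tol 1e-6, one start per repetition).
Initial centers are data points drawn by the distance-weighted
k-means++ rule: with uniformly random centers and a single start, a
non-negligible fraction of runs seeds two centers inside one tight
cluster and freezes a wrong split, so the consensus matrix cannot
converge to the true co-membership indicator even on perfectly
separated data; the resampling still provides all the averaging. The
consensus value of a sample pair is the fraction of runs containing
both in which they co-clustered; the per-k call is average-linkage
agglomerative clustering on 1 - consensus, cut to k. Feature
subsampling is available but off by default (samples are what the
resampling scheme varies).

Evidence per k: the area under the empirical CDF of off-diagonal
consensus values (trapezoid rule), its relative increase over k-1
(delta area; the first entry is the k = 2 area itself), the mean
within-cluster consensus, and the coefficient of variation of cluster
consensus (100 x sample SD / mean). The automatic choice takes the k
with maximal delta area among those ranking in the top half by mean
cluster consensus and the bottom half by CV (ties toward smaller k);
when no k passes both filters the overall delta-area maximum is
reported with `stable=False`, and any choice whose mean cluster
consensus is below 0.8 is likewise flagged. The full evidence table is
always emitted so the user can override.

## Survival

Kaplan-Meier product-limit curves per subtype and the g-group log-rank
chi-square test (df = g-1) are computed through lifelines; ties are
handled jointly via the hypergeometric mean/variance. Observations
censored at t = 0 carry no information and are dropped with a warning.

## Entropy-based subtype specificity

The candidate markers are scored on the probe x subgroup matrix of mean
beta-values. The cross-subgroup difference of probe r is the normalized
Shannon entropy of the mean vector m: with pseudocount eps = 1e-6,
p_s = (m_s + eps)/sum_t(m_t + eps) and H = -sum p log2 p / log2 n.
Because a raw entropy cannot flag a hypomethylated outlier (a small
coordinate barely perturbs the distribution), the same entropy is
computed on the reflected vector max(m) + min(m) - m and the profile
entropy is H_Q = min(direct, reflected), which is symmetric in hyper-
and hypomethylated outliers and equals 1 exactly for constant vectors.
For each subgroup S the leave-one-out entropy H_{Q/S} is computed on m
with S removed (normalized by log2(n-1) so entropies share the [0, 1]
scale), Delta-H(S) = H_{Q/S} - H_Q, and the categorical specificity is
CS(S) = Delta-H(S) x sign(m_S - median(m)) when Delta-H(S) > 0, else 0.
A probe with H_Q at or below the calling threshold is assigned to the
subgroup with maximal |CS|; CS > 0 marks subgroup-specific
hypermethylation, CS < 0 hypomethylation. Ties in the argmax (possible
by reflection symmetry) go to the lower subgroup index and are flagged.
This H_Q is a QDMR-inspired surrogate — the original tool's exact
weighting and probability-model threshold are not reproduced bit for
bit.

The default threshold is the 1st percentile of H_Q under a per-probe
label-permutation null: cluster labels are permuted across samples
(50 rounds) and the subgroup-mean profile recomputed, which destroys
subgroup structure while preserving each probe's baseline methylation.
A pooled-value null (resampling subgroup means from the pooled
distribution of all probes) was evaluated and rejected: it combines
means from probes with unrelated baselines, inflating the spread of
null vectors so grossly that its 1st percentile falls below the H_Q of
genuinely subtype-specific probes and nothing is called. With the
permutation null the false-call fraction among structureless probes is
approximately the chosen quantile (1% by default). In the full pipeline
the null is built from all cleaned promoter probes — a larger, more
representative collection than the feature CpGs that are actually
scored.

## Classifier

A soft-margin linear SVM (one-vs-rest for k > 2, C = 1) on raw beta
features, which are already bounded in [0, 1] and are not re-scaled.
Evaluation is stratified ten-fold cross-validation with pooled
predictions: accuracy, macro recall, macro precision, the k x k
confusion matrix, and a macro one-vs-rest AUC computed per class from
the decision scores (the averaging scheme is a declared choice). Fitted
linear models persist to a flat JSON file (feature list, class list,
weights, intercepts); an RBF kernel is available but not persistable.
Folds shrink with a warning when the smallest class has fewer members
than requested folds.

## Synthetic cohorts

The generator emulates the cohort structure the pipeline assumes.
Beta-values are Beta-distributed with a per-group mean and shared
concentration nu = 50 (a = mu nu, b = (1-mu) nu; sd about 0.07 at
mu = 0.5), so draws are strictly inside (0, 1). Background probes share
a per-probe baseline from U(0.15, 0.85) across all groups. Planted
differential probes shift tumors by delta_beta = 0.3 (alternating
hyper/hypo around 0.5); subtype-specific probes (a subset of the
differential set, alternating direction) separate exactly one subtype
from the rest by specific_shift = 0.4 while keeping the tumor-vs-normal
mean difference at delta_beta, and the config validator rejects
parameter combinations that push any group mean outside (0.02, 0.98).
Regulated genes follow baseline - 4 x (beta - 0.5) + N(0, 0.5) on the
log2 scale (emitted on the raw scale so normalization is exercised);
with these values a planted pair correlates at roughly r = -0.5 and the
coupled gene shifts by 1.2 log2 units, comfortably beyond both screens'
gates. Survival is exponential with per-subtype hazards (2, 2, 4, 8) x
10^-3 events/day, censored at an independent exponential time with rate
2 x 10^-3/day; 2% of beta entries are masked at random. Default layout
mirrors a TCGA-like bladder cohort at array-subsampled scale — 4
subtypes x 102 tumors, 14 normals, 2000 promoter probes (200
differential, 40 subtype-specific), 500 genes with 70% of differential
probes coupled. One root seed drives spawned substreams per stage, so a
fixed seed reproduces the cohort bit for bit.

What the generator does *not* emulate: probe-level spatial correlation,
Infinium probe-type effects, batch effects, tumor purity, copy-number
confounding, or graded (non-block) subtype structure. Passing recovery
tests therefore demonstrates correctness of the machinery under the
assumed generative model, not performance on real arrays.

## Problem sizes used in tests and the acceptance script

Recovery and error-control runs use desk-scale cohorts chosen to keep
effect sizes at the generator defaults while remaining quick to
simulate: 4 x 30 tumors with 10 normals and 2000 probes for subtype
recovery, marker calling and classification; 500-probe cohorts with
30+10 samples across 200 replicates for differential error control; 500
and 200 replicates for log-rank size and power. The numbered scripts
under `analysis/` run the same pipeline at the full default scale
(408 tumors).

## Known limitations

* Differential screens are unmoderated Welch tests; with very few
  normals per group an empirical-Bayes variance would be more powerful.
* One gene per probe; multi-gene promoters are out of scope.
* The k-selection rule codifies the usual reading of consensus evidence
  but is a heuristic; the evidence table is the primary output.
* The entropy threshold is calibrated per dataset; absolute H_Q values
  are not comparable across cohorts with different subgroup counts.
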