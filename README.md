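# methsub

DNA-methylation molecular subtyping of tumor cohorts from 450K-style
beta-value arrays with matched expression. The package is aimed at
computational epigenomics analyses of the TCGA/GEO kind: given a probe x
sample matrix of methylation fractions (beta in [0, 1]), a gene x sample
expression matrix, probe annotation and clinical metadata, it

1. cleans both matrices (zero replacement + log2 for expression;
   missingness filtering, probe-wise KNN imputation, SNP/sex-chromosome
   blacklisting and promoter windowing for methylation);
2. screens tumor-vs-normal differentially expressed genes and
   differentially methylated CpGs (Welch t + Benjamini-Hochberg, with
   fold-change and delta-beta gates);
3. selects *regulatory* CpG features — called promoter CpGs whose beta
   correlates negatively with their gene's expression
   (r < 0, p < 0.05 from the exact t transform);
4. discovers molecular subtypes by resampling consensus clustering:
   for k = 2..10, k-means over 100 random 80% subsamples of tumors, the
   consensus value of a pair being the proportion of runs co-clustering
   it; k is chosen from the delta-area of the consensus CDF, the mean
   within-cluster consensus, and its coefficient of variation
   CV = 100 x SD/mean;
5. compares subtype prognosis (Kaplan-Meier curves, g-group log-rank);
6. calls subtype-specific hyper/hypo-methylated markers with a signed
   leave-one-out Shannon-entropy specificity score
   CS_{r/S} = ΔH_{r/S} x sign(m_S - median(m)) for ΔH_{r/S} > 0, where
   ΔH_{r/S} = H_{Q/S̄} - H_Q and H_Q is the normalized min(direct,
   reflected) entropy of the subgroup-mean vector;
7. trains a linear SVM on the feature CpGs, evaluates it by stratified
   ten-fold cross-validation (accuracy, macro sensitivity/precision,
   macro one-vs-rest AUC, confusion matrix) and labels new cohorts.

A synthetic-cohort generator (`methsub.simulate`) plants all of this
structure — subtype-specific beta blocks, negative methylation-expression
coupling, subtype-dependent exponential survival, injected missingness —
with full ground truth, so every stage is verifiable end to end without
downloading a cohort.

## Worked example

The numbered scripts under `analysis/` run the whole analysis on the
default synthetic cohort (4 subtypes x 102 tumors, 14 normals, 2000
promoter CpGs, 500 genes; seed 1) and write their tables under
`results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
...
python analysis/08_classify_subtypes.py
```

Subtype discovery (script 05) prints the per-k evidence table and the
chosen k:

```
      area  delta_area  mean_cluster_consensus   cv_pct
k
2   0.4485      0.4485                  0.8409  26.7596
3   0.6877      0.5333                  0.8972  19.8513
4   0.7469      0.0861                  0.9947   0.6318
5   0.7771      0.0405                  0.9030   2.0032
...
chosen k = 4 (stable=True); cluster sizes: {1: 102, 2: 102, 3: 102, 4: 102}
```

k = 4 is the planted number of subtypes: it combines near-perfect
within-cluster consensus (0.995) with the lowest CV (0.63%), while the
large delta-areas at k = 2 and 3 come from unstable merges of true
subtypes and are filtered out by the consensus/CV ranks. Prognosis then
separates the four groups (script 06):

```
cluster 1: n=102, median survival 412 days
cluster 2: n=102, median survival 322 days
cluster 3: n=102, median survival 191 days
cluster 4: n=102, median survival 97 days
log-rank: chi2=65.68, df=3, p=3.59e-14
```

matching the planted hazard ordering (2, 2, 4, 8) x 10^-3 events/day.
Script 07 calls 37 subtype-specific markers among the 125 feature CpGs
at the permutation-calibrated entropy threshold (H_Q <= 0.9994), a mix
of hyper- and hypomethylated sites in each subtype, and script 08
reports a 10-fold CV accuracy of 1.000 (macro AUC 1.000) with all 408
held-out predictions on an independent synthetic cohort matching their
planted subtype.

The same pipeline runs as one call from a config:

```python
from methsub.pipeline import PipelineConfig, run_all
manifest = run_all(PipelineConfig(seed=1, outdir="results/pipeline"))
```

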