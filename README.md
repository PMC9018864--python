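# scnctype

Transcriptomic subtyping of metastatic small cell neuroendocrine cancers
(SCNC), re-implemented as a tested, reusable Python pipeline.

Small cell lung cancer and its extrapulmonary counterparts span a spectrum
of neuroendocrine (NE) differentiation with four consensus molecular
subtypes named for their dominant lineage transcription factor: SCNC-A
(*ASCL1*), SCNC-N (*NEUROD1*), SCNC-P (*POU2F3*) and SCNC-Y (*YAP1*).
`scnctype` provides the analysis stack that takes a bulk RNA-seq count
matrix and clinical annotations to per-tumor NE state, molecular subtype,
intratumoral cell-state fractions, pathway phenotypes (including the
chemoresistant, drug-metabolism-high "NEv2-like" state) and outcome
associations. Because the cohorts this analysis targets are typically
controlled-access, the package ships a fully labeled synthetic cohort
generator so every stage is testable end to end without any download.

## What it computes

* **Normalization** — TMM (trimmed mean of M-values) scaling factors,
  FPKM with effective library sizes, `log2(x+1)` transform.
* **NE score** — for sample *x* and the 50-gene two-centroid signature,

  ```
  NE(x) = [ corr(x, c_NE) − corr(x, c_nonNE) ] / 2  ∈ [−1, 1]
  ```

  with Pearson correlations over the signature genes; positive scores
  call NE, non-positive non-NE.
* **ssGSEA** — single-sample gene-set enrichment: per sample, the sum of
  running differences between a rank^α-weighted in-set ECDF and a uniform
  out-of-set ECDF over the descending expression ranking (α = 0.25,
  range-normalized), used for EMT/APM/immune/pathway scores.
* **Repstress score** — weighted sum of cohort z-scored expression of 17
  replication-stress genes (*SRSF1, SUV39H1, GINS1, …, RRM1*).
* **Subtyping** — agglomerative clustering of patients on z-scored
  expression of the four TFs, cluster labeling by dominant TF with a
  per-patient POU2F3/YAP1 split of the non-NE cluster, reclassification
  of patients whose subtype conflicts with the 50-gene NE call, and
  percent agreement / Cohen's kappa between classifications.
* **Deconvolution** — non-negative least squares (or ν-SVR) of each bulk
  sample against a per-state signature matrix after joint
  standardization, coefficients renormalized to the simplex; add-one
  permutation p-values (100 gene-label permutations, quantile
  normalization disabled).
* **Pathways / NEv2** — ssGSEA over a gene-set collection; Welch t +
  Benjamini–Hochberg selection of the most differentially regulated
  pathways between NE and non-NE tumors; Euclidean/complete-linkage tumor
  clustering; NEv2-like score = cohort z of the summed drug-metabolism
  pathway scores, with z > 1 (strict) defining NEv2-like tumors.
* **Outcomes** — Kaplan–Meier curves and medians, log-rank tests, Cox
  proportional-hazards regression (Efron ties), the 3-month clinical
  benefit rule (CR/PR/SD lasting ≥ 3 months), chi-square / Fisher
  association tests.
* **Ancillary** — INSM1 H-score (`1·%weak + 2·%moderate + 3·%strong`)
  and the somatic variant filter (VAF > 0.10, tumor and germline depth
  > 50, all strict).

## Worked example

Run the whole pipeline on the default synthetic cohort (100 tumors from
72 patients, 5 000 genes, 500 pathways):

```bash
scnctype run-all --seed 0 --outdir out/
```

or in Python:

```python
from scnctype import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(simulate={}, seed=0, outdir="out"))
```

The run takes about a minute on one CPU and prints (abridged):

```json
{
 "n_ne": 71,
 "n_samples": 100,
 "subtype_counts": {"SCNC-A": 30, "SCNC-Y": 22, "SCNC-N": 20},
 "tf_vs_ne_percent_agreement": 93.06,
 "tf_vs_ne_kappa": 0.8424,
 "n_nev2_like": 14,
 "recovery": {
  "ne_accuracy": 0.99,
  "subtype_accuracy": 0.986,
  "nev2_sensitivity": 1.0,
  "nev2_specificity": 1.0,
  "ne_fraction_rank_corr": 0.995
 }
}
```

Reading the numbers: 71 of 100 tumors are called NE by the 50-gene score;
TF-based subtyping assigns 30/20/22 patients to SCNC-A/N/Y and agrees
with the NE dichotomy for 93.1% of patients (κ = 0.84); 14 tumors exceed
the NEv2-like z > 1 threshold. The `recovery` block compares every call
against the generator's planted truth: 99% of NE labels, 98.6% of subtype
labels and all NEv2 flags are recovered, and the deconvolved NE fraction
rank-correlates 0.995 with the true mixing fraction. `out/` holds the
normalized matrix, per-sample scores, subtype table, fractions, pathway
scores, NEv2 calls, outcome statistics, and a manifest (parameters +
input checksums) that reproduces the run exactly.

Each stage is also exposed as a subcommand (`simulate`, `normalize`,
`score`, `subtype`, `deconvolve`, `pathways`, `outcomes`) and as plain
library functions.

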