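# Methods

This note documents the statistical procedures implemented in `scnctype`,
the parameter choices that matter, what the synthetic cohort generator
does and does not emulate, and the numerical conventions that make the
results reproducible.

## Normalization

Raw counts are normalized with TMM (trimmed mean of M-values) followed by
FPKM and `log2(x+1)`. The TMM factor of a sample against the reference is
the precision-weighted mean of per-gene log2 expression ratios
(M-values), after discarding genes with a zero count in either sample and
two-sided trimming of the M distribution (trim fraction 0.30) and the
average-abundance A distribution (0.05) — the method's canonical
defaults; weights are inverse asymptotic (delta-method) variances. The
reference sample is the column whose upper-quartile of scaled counts is
closest to the mean upper quartile. Factors are re-centered to geometric
mean 1, so the product of factors is 1 to within 1e-9 and normalization
is invariant to uniform rescaling of a library. FPKM uses the effective
library size (raw library size × TMM factor):
`fpkm = count · 1e9 / (eff_lib · length_bp)`.

Per-gene z-scores use the sample standard deviation (ddof = 1)
everywhere in the package. Constant rows (including rows whose computed
sd is a floating-point epsilon) z-score to 0 rather than NaN, so signature
sums never propagate missing values.

## Signature scores

**ssGSEA.** For one sample and one gene set, genes are ranked by
expression with average ranks for ties (deterministic and input-order
independent; the top gene has rank N). Walking the descending ranking,
the score accumulates the difference between an in-set ECDF weighted by
rank^α and a uniform out-of-set ECDF; the score is the sum of running
differences. α defaults to 0.25; with `normalize="range"` all samples'
scores from one run are divided by their max − min. At α = 0 the
statistic reduces to the unweighted Kolmogorov-style running sum. Genes
absent from the matrix are dropped with a warning; a set with zero
overlap is an error (or skipped, with a warning, inside a collection).

**NE score.** The 50-gene signature (25 genes correlating positively and
25 negatively with NE differentiation) is scored as half the difference
between a sample's Pearson correlation with the NE and the non-NE
centroid profiles over the signature genes present. The score lies in
[−1, 1] by construction and attains exactly ±1 when the sample equals one
centroid and the centroids are perfectly anti-correlated. The NE label is
strict: a score of exactly 0 is non-NE. A sample that is constant over
the signature genes has no defined correlation and raises an error. Both
a centroid-correlation scorer and the generic ssGSEA scorer are provided;
only the centroid score feeds NE labeling, because its bounded range is
the property the classification relies on.

**Weighted z-score signatures.** The 17-gene replication-stress score is
the weighted sum of cohort z-scored expression; default weights are 1 and
user-overridable. Scores are cohort-relative and therefore mean 0 across
samples by construction.

## Deconvolution

Each bulk sample is modeled as a non-negative combination of per-state
reference profiles. The sample and the signature matrix are restricted to
shared genes (signature genes absent from the mixture are dropped, not
zero-filled, which would bias fractions toward low-expression states) and
standardized with one shared mean and sd. The shared affine transform is
deliberate: it preserves convex combinations exactly (the shift is
absorbed when coefficients sum to 1), so noiseless mixtures are recovered
to numerical precision. The default solver is non-negative least squares
(deterministic); a ν-SVR mode (linear kernel, ν ∈ {0.25, 0.5, 0.75},
keep the lowest-RMSE fit, clip negatives) is provided for fidelity to the
support-vector deconvolution convention. Coefficients are renormalized to
the simplex (relative fractions, matching stacked-bar presentations).

Significance per sample uses an add-one permutation test with 100
permutations by default and quantile normalization disabled: the null
distribution permutes the mixture's gene labels and refits;
`p = (1 + #{R_null ≥ R_obs}) / (1 + n_perm)`, so p is never 0. The
permutation statistic is the correlation between the mixture and its
unconstrained least-squares projection onto the signature column space
rather than the non-negative fit's correlation: the constrained fit has a
point mass at R = 0 (all-zero coefficient vectors for anti-correlated
noise), which would make null p-values conservative instead of uniform.
The reported per-sample `fit_r` and `rmse` remain those of the
constrained fit.

## Subtyping

Patients are clustered on z-scored expression of ASCL1, NEUROD1, POU2F3
and YAP1 (Euclidean distance, tree cut at k = 3: an A cluster, an N
cluster, and a merged non-NE Y/P cluster). The default linkage is
**average**, not complete, and this is a considered choice: with only
four dimensions, a TF that is near-silent in almost all patients becomes
a unit-variance noise axis after z-scoring (a z-scored row has variance 1
regardless of its information content), and complete linkage's
max-distance criterion is fragile to such an axis — it either isolates
the rare POU2F3-high patient as a singleton (forcing A and N to merge at
k = 3) or lets worst-case noise distances contaminate the A/N split.
Average linkage integrates the noisy axis out. The linkage is a keyword
argument for users who prefer the complete-linkage convention.

Clusters are labeled by the TF with the highest mean z-score (exact ties
break by the fixed priority A > N > P > Y, with a warning). Within the
Y/P cluster, a patient is labeled SCNC-P when POU2F3 exceeds YAP1 both in
z-score **and in raw log2 expression**. The raw-expression guard exists
for the same unit-noise reason as the linkage choice: a z-only comparison
would call a tuft subtype in ~7% of YAP1-high patients whose absolute
POU2F3 expression is negligible.

Patients whose subtype implies the wrong NE category (A/N are NE, P/Y
non-NE) relative to the 50-gene call are reclassified to the subtype of
their globally strongest TF by z-score (the 50-gene signature is treated
as the more noise-robust classifier), with the same POU2F3 guard, and
flagged. Agreement between classifications is reported as percent
agreement and Cohen's kappa (`(p_o − p_e)/(1 − p_e)`, chance agreement
from marginal products); both raters constant on the same category is
treated as kappa 1 when agreement is perfect.

Subtype gene signatures are derived from the top differentially expressed
genes (one-way F across subtypes by default, Kruskal–Wallis optional;
BH-adjusted; top 2000 by adjusted p with ties broken by larger statistic)
via PCA on the gene-standardized matrix: the top 500 contributors by
absolute loading on PC1 and PC2 are pooled and each gene is assigned to
the subtype whose sample-group centroid in (PC1, PC2) space has maximal
inner product with the gene's loading vector — a rule invariant to PC
sign flips.

## Pathway analysis and the NEv2-like state

Pathway scores are ssGSEA per set over a collection; differential
pathways between NE and non-NE tumors are found on per-pathway z-scores
with an unpaired t test (Welch by default; pooled-variance optional) and
BH adjustment. Selection is either the top n (default 1000) by adjusted p
with |t| tie-break — operationally identical to stepwise restriction of
the adjusted-p threshold until n pathways remain — or all pathways below
an FDR cutoff (used at FDR < 1% for the biopsy-site confound check).
Tumor clustering on selected pathway scores uses Euclidean distance with
complete linkage (the stated convention for this step; the source
description "complete-linkage non-hierarchical" is contradictory, and
agglomerative hierarchical clustering is the implemented interpretation).

The NEv2-like score takes a named list of drug-metabolism pathways
(ordinarily ~100, identified by co-clustering; the list is an input, not
re-derived), sums their scores per tumor and z-normalizes across the
cohort. Tumors with z > 1 — strictly; a tumor at exactly 1.0 is not
flagged — are NEv2-like. A degenerate cohort (identical sums) yields no
flags, with a warning.

## Outcomes

Survival uses lifelines: Kaplan–Meier product-limit curves with the
median reported as the first time S(t) ≤ 0.5 and "not reached" encoded as
+inf; the k-group log-rank test (df = k−1); Cox proportional hazards with
Efron tie handling (better small-sample behavior than Breslow) and Wald
confidence intervals, with non-convergence surfaced as an explicit error.
Clinical benefit is CR/PR/SD maintained for at least 3 months from
treatment start; benefit-eligible records missing a duration are excluded
with a warning. Association tests default to chi-square without
continuity correction, falling back to the two-tailed Fisher exact test
for 2×2 tables with any expected cell below 5; either test can be forced.
Both OS-from-diagnosis and PFS-from-treatment clocks are supported via
the `event_type` argument.

## Ancillary measures

The INSM1 H-score is `1·%weak + 2·%moderate + 3·%strong` (range 0–300;
percentages must not sum above 100). The somatic variant filter keeps
records with VAF > 0.10 and tumor and germline depth > 50, all strict —
boundary records are excluded; a VAF column expressed in percent (values
above 1) is auto-detected and rescaled with a warning.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
100 tumor samples from 72 patients; patient subtypes assigned by quota
(largest-remainder rounding of the proportions 41.7/27.8/1.4/29.2% for
A/N/P/Y, then shuffled) because the cohort composition is a fixed study
condition, not a resampled quantity; each sample's expected expression is
`f·NE + (1−f)·non-NE` over two archetype programs with the true NE
fraction f drawn per subtype from Beta(13, 7) for A/N (median ≈ 0.65) and
Beta(5, 11) for Y/P; a `model_systems` preset uses Beta(28, 2)
(median ≈ 0.93) to mimic purer model-derived tumors. The archetypes
differ on the 50 centroid genes (contrast 12×/0.15×) and two broader
200-gene programs (6×/0.3×); replication-stress genes run 4× higher in
the NE archetype. The subtype-defining TF is set 12× baseline (0.4×
otherwise); YAP1 elevation is shared by both non-NE subtypes and the
tuft-like POU2F3 elevation is modest (1.1×), so the rare P tumor sits
inside the non-NE cluster rather than forming an extreme outlier axis. A
planted 15% of patients have all drug-metabolism block genes inflated
2-fold (the NEv2-like truth). Counts are negative-binomial (gamma–Poisson,
dispersion 0.1) around length- and library-scaled means (library size
2e6 × lognormal(0, 0.2)), with per-gene multiplicative lognormal
biological noise (sd 0.4). Centroid and deconvolution reference profiles
are emitted in log2(FPKM+1) units — the same units the pipeline scores —
and the 50 centroid genes get comparable baseline abundance and lengths,
as marker panels selected for clean contrast do; without this, random
covariance between per-gene baselines and the differential pattern
shifts the score's zero crossing away from f = 0.5.

Truth labels: a sample's NE truth is f > 0.5 (the quantity the 50-gene
score estimates); subtype truth is the planted subtype; NEv2 truth is the
planted flag. Survival times are exponential with a planted NEv2 OS
hazard ratio of 2.45 (a simulation parameter, not a reproduced
estimate), and PFS carries an NE × treatment-arm interaction (hazard
ratio 2.37 for NE patients on immunotherapy versus ATR inhibition);
responses are drawn so clinical benefit is most likely for NE patients on
ATR inhibition and least likely for NE patients on immunotherapy.

What the generator does **not** emulate: read-level sequencing artifacts,
batch effects, tumor purity variation, immune/stromal admixture beyond
the two archetypes, correlated gene–gene noise within pathways, and
non-exponential hazards. Passing recovery tests therefore demonstrates
the pipeline's correctness under the assumed generative model, not
robustness to the full messiness of real cohorts.

At the default seed, label recovery errors are confined to samples whose
true fraction lies within ~0.03 of the 0.5 boundary, where the label is
intrinsically ambiguous; the planted singleton P patient is usually
labeled SCNC-Y (one patient of 72, within the recovery tolerance).

## Numerical conventions and problem sizes

All randomness flows through `numpy.random.default_rng` seeded from a
single spec/config seed; per-sample permutation seeds are spawned via
`SeedSequence`. Pipeline runs are deterministic for a fixed seed and
write a manifest (configuration + SHA-256 checksums of file inputs)
sufficient to reproduce the run. The default end-to-end problem size —
100 samples × 5 000 genes with a 500-set pathway collection — completes
in about a minute on one CPU; simulation-based tests use reduced sizes
(tens of samples, hundreds of genes) chosen to keep the full suite fast
while leaving planted effects clearly detectable. Calibration tests use
rep-indexed seeds so their outcomes are deterministic.
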