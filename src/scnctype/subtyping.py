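"""Transcription-factor subtype assignment and subtype signatures.

Small cell neuroendocrine cancers are classified into SCNC-A, -N, -P and
-Y by the dominant lineage transcription factor (ASCL1, NEUROD1, POU2F3,
YAP1). Patients are clustered on the z-scored expression of the four TFs
(Euclidean distance, complete linkage, tree cut at k=3: an A cluster, an
N cluster, and a merged Y/P cluster that is split per patient), then
patients whose subtype NE-category conflicts with the 50-gene NE call are
re-classified to the subtype of their overall strongest TF. Agreement
between classifications is quantified by percent agreement and Cohen's
kappa. Subtype-specific gene signatures are derived from the top
differentially expressed genes via principal-component contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f_oneway, kruskal
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .expr_io import zscore_by_gene
from .signatures import GeneSet, GeneSetCollection, NeScoreResult

__all__ = [
    "CORE_TFS",
    "TF_TO_SUBTYPE",
    "SUBTYPE_NE_CATEGORY",
    "SubtypeAssignment",
    "AgreementStats",
    "cluster_tf",
    "label_clusters",
    "reclassify_discordant",
    "agreement_kappa",
    "select_top_de_genes",
    "derive_subtype_signatures",
    "assign_subtypes",
]

CORE_TFS = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")
TF_TO_SUBTYPE = {
    "ASCL1": "SCNC-A",
    "NEUROD1": "SCNC-N",
    "POU2F3": "SCNC-P",
    "YAP1": "SCNC-Y",
}
# A and N are neuroendocrine-high subtypes; P and Y are non-NE.
SUBTYPE_NE_CATEGORY = {
    "SCNC-A": "NE",
    "SCNC-N": "NE",
    "SCNC-P": "non-NE",
    "SCNC-Y": "non-NE",
}
# fixed priority for exact ties in mean z: A > N > P > Y
_TF_PRIORITY = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")


@dataclass
class SubtypeAssignment:
    """Per-patient subtype label with cluster id and reclassification flag."""

    patients: list[str]
    cluster_ids: np.ndarray
    labels: list[str]
    reclassified: np.ndarray  # bool per patient

    @property
    def ne_category_of_label(self) -> list[str]:
        return [SUBTYPE_NE_CATEGORY[l] for l in self.labels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": self.patients,
                "subtype": self.labels,
                "cluster": self.cluster_ids,
                "reclassified": self.reclassified,
            }
        ).set_index("patient")


@dataclass
class AgreementStats:
    percent_agreement: float  # 0..100
    kappa: float


def _tf_zscores(tf: pd.DataFrame) -> pd.DataFrame:
    """z-score TF rows across patients; expects TFs x patients."""
    missing = [t for t in CORE_TFS if t not in tf.index]
    if missing:
        raise ValueError(f"missing core TFs: {missing}")
    return zscore_by_gene(tf.loc[list(CORE_TFS)])


def cluster_tf(tf: pd.DataFrame, k: int = 3, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of patients on z-scored TF expression.

    ``tf`` is a TFs x patients frame containing the four core TFs.
    Returns integer cluster ids (1..k) per patient.

    Average linkage is the default: with only four dimensions, a TF that
    is near-silent in most patients becomes a unit-variance noise axis
    after z-scoring, and max-distance (complete) linkage is fragile to
    it, while average linkage integrates it out. The linkage is
    configurable.
    """
    n = tf.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds number of patients ({n})")
    z = _tf_zscores(tf)
    if np.allclose(z.to_numpy(), 0.0):
        warnings.warn("all patients identical: single effective cluster")
        return np.ones(n, dtype=int)
    lnk = linkage(z.to_numpy().T, method=method, metric="euclidean")
    return fcluster(lnk, t=k, criterion="maxclust")


def label_clusters(clusters: np.ndarray, tf: pd.DataFrame) -> SubtypeAssignment:
    """Label each cluster by its TF with the highest mean z-score.

    Within a cluster labeled SCNC-Y or SCNC-P, individual patients whose
    POU2F3 z exceeds their YAP1 z are labeled SCNC-P (and vice versa),
    since the two non-NE subtypes co-cluster. The tuft call additionally
    requires POU2F3 to exceed YAP1 in absolute (log) expression: a TF
    that is silenced cohort-wide carries a unit-variance noise axis after
    z-scoring, and a z-only comparison would call a tuft subtype in
    tumors that barely express POU2F3.
    """
    z = _tf_zscores(tf)
    patients = list(tf.columns)
    clusters = np.asarray(clusters)
    labels = [""] * len(patients)

    for cid in np.unique(clusters):
        members = np.flatnonzero(clusters == cid)
        means = z.iloc[:, members].mean(axis=1)
        top = means.max()
        tied = [t for t in _TF_PRIORITY if means[t] == top]
        if len(tied) > 1:
            warnings.warn(
                f"cluster {cid}: exact tie among {tied}; using priority "
                "A > N > P > Y"
            )
        top_tf = tied[0]
        base = TF_TO_SUBTYPE[top_tf]
        for i in members:
            lab = base
            if base in ("SCNC-Y", "SCNC-P"):
                p = patients[i]
                pou_wins = (
                    z.loc["POU2F3", p] > z.loc["YAP1", p]
                    and tf.loc["POU2F3", p] > tf.loc["YAP1", p]
                )
                lab = "SCNC-P" if pou_wins else "SCNC-Y"
            labels[i] = lab

    return SubtypeAssignment(
        patients=patients,
        cluster_ids=clusters.copy(),
        labels=labels,
        reclassified=np.zeros(len(patients), dtype=bool),
    )


def reclassify_discordant(
    assignment: SubtypeAssignment,
    ne: NeScoreResult | pd.Series,
    tf: pd.DataFrame,
) -> SubtypeAssignment:
    """Re-classify patients whose subtype conflicts with the NE call.

    When a patient's cluster-derived label implies the wrong NE category
    (A/N are NE, P/Y non-NE), the label is replaced by the subtype of the
    TF with the greatest z-score in that patient (the 50-gene signature is
    treated as the more robust classifier; the TF vote is re-taken over
    all four TFs).
    """
    ne_labels = (
        dict(zip(ne.samples, ne.labels))
        if isinstance(ne, NeScoreResult)
        else ne.to_dict()
    )
    missing = [p for p in assignment.patients if p not in ne_labels]
    if missing:
        raise ValueError(f"NE labels missing for patients: {missing[:5]}")

    z = _tf_zscores(tf)
    labels = list(assignment.labels)
    reclassified = assignment.reclassified.copy()
    for i, p in enumerate(assignment.patients):
        if SUBTYPE_NE_CATEGORY[labels[i]] != ne_labels[p]:
            zs = z[p].copy()
            # same tuft-call guard as labeling: POU2F3 cannot win on a
            # z-score alone while YAP1 dominates it in raw expression
            if tf.loc["POU2F3", p] <= tf.loc["YAP1", p]:
                zs["POU2F3"] = -np.inf
            top = zs.max()
            top_tf = next(t for t in _TF_PRIORITY if zs[t] == top)
            labels[i] = TF_TO_SUBTYPE[top_tf]
            reclassified[i] = True

    return SubtypeAssignment(
        patients=list(assignment.patients),
        cluster_ids=assignment.cluster_ids.copy(),
        labels=labels,
        reclassified=reclassified,
    )


def agreement_kappa(labels_a, labels_b) -> AgreementStats:
    """Percent agreement and Cohen's kappa between two label vectors.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    product of the marginal label frequencies.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    n = len(a)
    if n == 0:
        raise ValueError("empty label vectors")
    p_o = sum(x == y for x, y in zip(a, b)) / n
    cats = sorted(set(a) | set(b))
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if p_e == 1.0:  # both raters constant on the same category
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return AgreementStats(percent_agreement=100.0 * p_o, kappa=kappa)


def select_top_de_genes(
    expr: pd.DataFrame,
    labels,
    n_top: int = 2000,
    method: str = "f",
) -> pd.DataFrame:
    """Rank genes by differential expression across label groups.

    One-way F statistic per gene (Kruskal-Wallis with ``method='kruskal'``),
    Benjamini-Hochberg adjustment, ranking by smallest adjusted p with
    ties broken by larger statistic. Returns the top ``n_top`` rows of a
    frame with columns ``statistic, p_value, adj_p``.
    """
    labels = np.asarray(list(labels))
    if len(labels) != expr.shape[1]:
        raise ValueError("labels length must equal number of samples")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 label groups")
    group_idx = [np.flatnonzero(labels == g) for g in groups]
    for g, idx in zip(groups, group_idx):
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    mat = expr.to_numpy(float)
    test = f_oneway if method == "f" else kruskal
    stats = np.empty(mat.shape[0])
    pvals = np.empty(mat.shape[0])
    for i in range(mat.shape[0]):
        samples = [mat[i, idx] for idx in group_idx]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            stats[i], pvals[i] = 0.0, 1.0
            continue
        try:
            stats[i], pvals[i] = test(*samples)
        except ValueError:
            stats[i], pvals[i] = 0.0, 1.0
    pvals = np.nan_to_num(pvals, nan=1.0)
    stats = np.nan_to_num(stats, nan=0.0)
    adj = multipletests(pvals, method="fdr_bh")[1]

    res = pd.DataFrame(
        {"statistic": stats, "p_value": pvals, "adj_p": adj}, index=expr.index
    )
    if n_top > len(res):
        warnings.warn(
            f"n_top = {n_top} exceeds gene count ({len(res)}); returning all"
        )
        n_top = len(res)
    res = res.sort_values(
        ["adj_p", "statistic"], ascending=[True, False], kind="mergesort"
    )
    return res.head(n_top)


def derive_subtype_signatures(
    expr: pd.DataFrame,
    labels,
    n_contributors: int = 500,
) -> GeneSetCollection:
    """Subtype gene signatures from principal-component contributions.

    PCA on the gene-standardized samples x genes matrix; the top
    ``n_contributors`` genes by absolute loading on PC1 and on PC2 are
    pooled, and each is assigned to the subtype whose sample-group
    centroid in (PC1, PC2) space points in the direction of the gene's
    loading vector (maximal inner product).
    """
    labels = np.asarray(list(labels))
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    n_genes = expr.shape[0]
    if n_contributors > n_genes:
        warnings.warn(
            f"n_contributors = {n_contributors} exceeds gene count; taking all"
        )
        n_contributors = n_genes

    z = zscore_by_gene(expr)  # genes x samples
    X = z.to_numpy().T  # samples x genes
    pca = PCA(n_components=2)
    coords = pca.fit_transform(X)  # samples x 2
    loadings = pca.components_.T  # genes x 2

    top1 = np.argsort(-np.abs(loadings[:, 0]), kind="stable")[:n_contributors]
    top2 = np.argsort(-np.abs(loadings[:, 1]), kind="stable")[:n_contributors]
    pool = sorted(set(top1) | set(top2))

    groups = np.unique(labels)
    centroids = {g: coords[labels == g].mean(axis=0) for g in groups}

    members: dict = {g: [] for g in groups}
    for gi in pool:
        vec = loadings[gi]
        best = max(groups, key=lambda g: float(centroids[g] @ vec))
        members[best].append(expr.index[gi])

    sets = [
        GeneSet(f"{g}_signature", tuple(members[g]))
        for g in groups
        if members[g]
    ]
    return GeneSetCollection(sets)


def assign_subtypes(
    tf: pd.DataFrame,
    ne: NeScoreResult | pd.Series,
    k: int = 3,
) -> SubtypeAssignment:
    """Cluster, label and reclassify in one call."""
    clusters = cluster_tf(tf, k=k)
    assignment = label_clusters(clusters, tf)
    return reclassify_discordant(assignment, ne, tf)
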