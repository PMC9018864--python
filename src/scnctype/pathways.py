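"""Pathway-level scoring, differential selection, clustering and the
NEv2-like score.

Pathway activity is quantified per sample by ssGSEA over a gene-set
collection. Differentially regulated pathways between NE and non-NE
tumors are found by an unpaired t test on z-normalized pathway scores
with Benjamini-Hochberg adjustment, keeping either the top-n ranked
pathways or all below an FDR cutoff. Tumors are clustered on the selected
scores (Euclidean distance, complete linkage). The NEv2-like score sums a
named block of drug-metabolism pathway scores per tumor and z-normalizes
across the cohort; tumors with z > 1 (strict) are NEv2-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .expr_io import NormalizedExpressionMatrix, zscore_by_gene
from .signatures import GeneSetCollection, SsgseaParams, ssgsea_score

__all__ = [
    "Nev2Result",
    "score_pathway_collection",
    "differential_pathways",
    "cluster_on_pathways",
    "nev2_score_and_label",
]


@dataclass
class Nev2Result:
    """Per-tumor summed pathway score, cohort z, and the NEv2-like flag."""

    samples: list[str]
    sum_scores: np.ndarray
    z_scores: np.ndarray
    nev2_like: np.ndarray  # bool; z > 1 strictly

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "sum_score": self.sum_scores,
                "z": self.z_scores,
                "nev2_like": self.nev2_like,
            }
        ).set_index("sample")


def score_pathway_collection(
    expr: NormalizedExpressionMatrix | pd.DataFrame,
    collection: GeneSetCollection,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """ssGSEA scores for every set in a collection: pathways x samples.

    Sets with zero gene overlap are skipped with a warning; it is an
    error for every set to have zero overlap.
    """
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    df = expr.to_frame() if isinstance(expr, NormalizedExpressionMatrix) else expr
    rows = {}
    for gs in collection:
        if not any(g in df.index for g in gs.genes):
            warnings.warn(f"set {gs.name!r}: no gene present in matrix, skipped")
            continue
        rows[gs.name] = ssgsea_score(df, gs, params)
    if not rows:
        raise ValueError("every gene set has zero overlap with the matrix")
    return pd.DataFrame(rows).T.loc[[n for n in collection.names if n in rows]]


def differential_pathways(
    scores: pd.DataFrame,
    binary_labels,
    n_top: int | None = 1000,
    fdr: float | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Differentially regulated pathways between two sample groups.

    Scores are z-normalized per pathway first; each pathway gets an
    unpaired two-sample t test (Welch by default) and a BH-adjusted p.
    ``n_top`` selects the n smallest adjusted p (ties by larger \\|t\\|);
    ``fdr`` instead selects all pathways with adjusted p below the cutoff.
    Returns a frame with columns ``t, p_value, adj_p, selected``.
    """
    if (n_top is None) == (fdr is None):
        raise ValueError("supply exactly one of n_top or fdr")
    labels = np.asarray(list(binary_labels))
    if len(labels) != scores.shape[1]:
        raise ValueError("labels length must equal number of samples")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 label groups, got {len(groups)}")
    idx_a = labels == groups[0]
    idx_b = labels == groups[1]
    if idx_a.sum() < 2 or idx_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    z = zscore_by_gene(scores).to_numpy()
    t, p = ttest_ind(z[:, idx_a], z[:, idx_b], axis=1, equal_var=equal_var)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    adj = multipletests(p, method="fdr_bh")[1]

    res = pd.DataFrame(
        {"t": t, "p_value": p, "adj_p": adj}, index=scores.index
    )
    if fdr is not None:
        res["selected"] = res["adj_p"] < fdr
    else:
        order = res.assign(abs_t=res["t"].abs()).sort_values(
            ["adj_p", "abs_t"], ascending=[True, False], kind="mergesort"
        )
        chosen = set(order.index[: min(n_top, len(res))])
        res["selected"] = res.index.isin(chosen)
    return res


def cluster_on_pathways(scores: pd.DataFrame, k: int = 2):
    """Cluster tumors on z-normalized pathway scores.

    Agglomerative clustering with Euclidean distance and complete
    linkage. Returns ``(cluster_ids, linkage_matrix)``.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 tumors")
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 pathways")
    z = zscore_by_gene(scores)
    if np.allclose(z.to_numpy(), 0.0):
        raise ValueError("degenerate input: all tumors identical")
    lnk = linkage(z.to_numpy().T, method="complete", metric="euclidean")
    return fcluster(lnk, t=k, criterion="maxclust"), lnk


def nev2_score_and_label(
    scores: pd.DataFrame,
    nev2_pathways: list[str],
) -> Nev2Result:
    """NEv2-like score: z-normalized sum of the named pathway scores.

    A tumor is NEv2-like iff its cohort z exceeds 1 strictly; a z of
    exactly 1 is not NEv2-like.
    """
    missing = [p for p in nev2_pathways if p not in scores.index]
    if missing:
        raise ValueError(f"pathways missing from score matrix: {missing[:5]}")
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 tumors for a stable z-score")
    sums = scores.loc[list(nev2_pathways)].sum(axis=0)
    sd = sums.std(ddof=1)
    if sd == 0:
        warnings.warn("all tumors have identical summed scores; z undefined")
        z = pd.Series(0.0, index=sums.index)
    else:
        z = (sums - sums.mean()) / sd
    return Nev2Result(
        samples=list(scores.columns),
        sum_scores=sums.to_numpy(),
        z_scores=z.to_numpy(),
        nev2_like=(z > 1.0).to_numpy(),
    )
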