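"""Per-sample signature scoring.

Three flavors of signature drive the analysis:

* gene sets scored by single-sample GSEA (ssGSEA) — a rank-weighted
  ECDF-difference statistic computed independently per sample;
* the 50-gene neuroendocrine (NE) centroid signature, scored as half the
  difference between a sample's Pearson correlation with the NE and the
  non-NE centroid profiles, giving a score in [-1, 1] whose sign calls the
  NE / non-NE state;
* weighted sums of cohort z-scored expression, used for the 17-gene
  replication-stress (repstress) score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expr_io import NormalizedExpressionMatrix, zscore_by_gene

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "SsgseaParams",
    "CentroidSignature",
    "NeScoreResult",
    "WeightedSignature",
    "REPSTRESS_GENES",
    "parse_gmt",
    "write_gmt",
    "read_centroid_signature",
    "ssgsea_score",
    "ne_score",
    "weighted_zscore_score",
]

# 17 replication-stress response genes; default weight 1 each.
REPSTRESS_GENES = (
    "SRSF1", "SUV39H1", "GINS1", "PRPS1", "AURKB", "TNPO2", "ORC6",
    "CCNA2", "LIG3", "MTF2", "GADD45G", "POLA1", "POLD4", "POLE4",
    "RFC5", "RMI1", "RRM1",
)


@dataclass
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        self.genes = tuple(self.genes)
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class SsgseaParams:
    """Rank-weight exponent and normalization mode for ssGSEA."""

    alpha: float = 0.25
    normalize: str = "range"  # "none" | "range"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.normalize not in ("none", "range"):
            raise ValueError("normalize must be 'none' or 'range'")


@dataclass
class CentroidSignature:
    """Two centroid expression profiles over a common gene list.

    The canonical signature has 50 genes, 25 correlating positively and 25
    negatively with neuroendocrine differentiation.
    """

    genes: tuple[str, ...]
    ne_centroid: np.ndarray
    nonne_centroid: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.ne_centroid = np.asarray(self.ne_centroid, dtype=float)
        self.nonne_centroid = np.asarray(self.nonne_centroid, dtype=float)
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate genes in centroid signature")
        if self.ne_centroid.shape != (len(self.genes),):
            raise ValueError("ne_centroid length mismatch")
        if self.nonne_centroid.shape != (len(self.genes),):
            raise ValueError("nonne_centroid length mismatch")


@dataclass
class NeScoreResult:
    """Per-sample NE score in [-1, 1] and the NE / non-NE call by sign."""

    samples: list[str]
    scores: np.ndarray
    labels: list[str]  # "NE" | "non-NE"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ne_score": self.scores, "ne_label": self.labels}, index=self.samples
        )


@dataclass
class WeightedSignature:
    """Gene -> weight mapping for weighted z-score signatures."""

    weights: dict

    def __post_init__(self) -> None:
        if len(self.weights) < 1:
            raise ValueError("weighted signature needs at least one gene")
        vals = np.array(list(self.weights.values()), dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite weight")

    @classmethod
    def repstress(cls) -> "WeightedSignature":
        return cls({g: 1.0 for g in REPSTRESS_GENES})


def parse_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    The description field is discarded; duplicate genes within a line are
    de-duplicated with a warning.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, genes = fields[0], [g for g in fields[2:] if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(f"GMT set {name!r}: duplicate genes de-duplicated")
            sets.append(GeneSet(name, tuple(uniq)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


def read_centroid_signature(path) -> CentroidSignature:
    """Read a centroid TSV with columns ``gene, ne, non_ne``."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "ne", "non_ne"}.issubset(df.columns):
        raise ValueError("centroid TSV must have columns gene, ne, non_ne")
    return CentroidSignature(
        genes=tuple(df["gene"].astype(str)),
        ne_centroid=df["ne"].to_numpy(float),
        nonne_centroid=df["non_ne"].to_numpy(float),
    )


def _as_frame(expr) -> pd.DataFrame:
    return expr.to_frame() if isinstance(expr, NormalizedExpressionMatrix) else expr


def ssgsea_score(
    expr: NormalizedExpressionMatrix | pd.DataFrame,
    gene_set: GeneSet,
    params: SsgseaParams | None = None,
) -> pd.Series:
    """Single-sample GSEA enrichment score, one value per sample.

    Per sample, genes are ranked by expression (ties get average ranks,
    the top gene rank N); walking the ranked list from the top, a
    rank^alpha-weighted in-set ECDF minus a uniform out-of-set ECDF is
    accumulated, and the score is the sum of the running differences.
    With ``normalize='range'`` all scores from the run are divided by the
    max - min of the scores across samples.
    """
    params = params or SsgseaParams()
    df = _as_frame(expr)
    n_genes = df.shape[0]
    if n_genes < 2:
        raise ValueError("expression matrix must have at least 2 genes")
    in_set = df.index.isin(gene_set.genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    if n_in < len(gene_set):
        missing = len(gene_set) - n_in
        warnings.warn(
            f"set {gene_set.name!r}: {missing} gene(s) absent from the matrix, dropped"
        )

    values = df.to_numpy(float)
    scores = np.empty(df.shape[1])
    for j in range(df.shape[1]):
        x = values[:, j]
        ranks = rankdata(x)  # highest expression -> rank n_genes
        order = np.argsort(-x, kind="stable")  # descending walk
        w = ranks[order] ** params.alpha
        members = in_set[order]
        w_in = np.where(members, w, 0.0)
        denom_in = w_in.sum()
        step_in = np.cumsum(w_in) / denom_in if denom_in > 0 else np.zeros(n_genes)
        step_out = np.cumsum(~members) / (n_genes - n_in)
        scores[j] = float(np.sum(step_in - step_out))

    out = pd.Series(scores, index=df.columns, name=gene_set.name)
    if params.normalize == "range":
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
    return out


def ne_score(
    expr: NormalizedExpressionMatrix | pd.DataFrame,
    sig: CentroidSignature,
) -> NeScoreResult:
    """NE score and NE / non-NE call from the two-centroid signature.

    ``score = (corr(sample, ne_centroid) - corr(sample, nonne_centroid)) / 2``
    with Pearson correlations over the signature genes present in the
    matrix. Positive scores call NE; zero ties resolve to non-NE.
    """
    df = _as_frame(expr)
    present = [g for g in sig.genes if g in df.index]
    if len(present) < 3:
        raise ValueError(
            f"only {len(present)} signature genes present; need at least 3"
        )
    if len(present) < len(sig.genes):
        warnings.warn(
            f"{len(sig.genes) - len(present)} centroid genes absent from the matrix"
        )
    idx = [sig.genes.index(g) for g in present]
    ne_c = sig.ne_centroid[idx]
    non_c = sig.nonne_centroid[idx]
    sub = df.loc[present]

    scores = np.empty(sub.shape[1])
    for j, s in enumerate(sub.columns):
        x = sub[s].to_numpy(float)
        if np.std(x) == 0:
            raise ValueError(
                f"sample {s!r} is constant over the signature genes; "
                "correlation undefined"
            )
        r_ne = np.corrcoef(x, ne_c)[0, 1]
        r_non = np.corrcoef(x, non_c)[0, 1]
        scores[j] = (r_ne - r_non) / 2.0

    labels = ["NE" if s > 0 else "non-NE" for s in scores]
    return NeScoreResult(list(df.columns), scores, labels)


def weighted_zscore_score(
    expr: NormalizedExpressionMatrix | pd.DataFrame,
    sig: WeightedSignature,
) -> pd.Series:
    """Weighted sum of cohort z-scored expression over the signature genes."""
    df = _as_frame(expr)
    present = [g for g in sig.weights if g in df.index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if len(present) < len(sig.weights):
        warnings.warn(
            f"{len(sig.weights) - len(present)} signature genes absent, dropped"
        )
    z = zscore_by_gene(df.loc[present])
    w = np.array([sig.weights[g] for g in present])
    return pd.Series(w @ z.to_numpy(), index=df.columns, name="weighted_score")
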