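"""Expression matrix I/O and TMM-FPKM normalization.

Bulk RNA-seq counts are normalized with the trimmed mean of M-values (TMM)
to correct for library composition, converted to FPKM using per-gene
effective lengths, and log2(x+1)-transformed. The resulting matrix is the
substrate of every downstream scoring step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawCountMatrix",
    "GeneLengths",
    "NormalizedExpressionMatrix",
    "TmmParams",
    "read_counts",
    "read_gene_lengths",
    "tmm_factors",
    "tmm_fpkm_log2",
    "zscore_by_gene",
    "write_matrix",
]


@dataclass
class RawCountMatrix:
    """Gene x sample matrix of non-negative integer counts."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)


# Gene symbol -> effective length (bp, positive).
GeneLengths = dict


@dataclass
class NormalizedExpressionMatrix:
    """log2(TMM-FPKM + 1) expression, genes x samples; all values >= 0."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape mismatch")
        if (self.values < 0).any():
            raise ValueError("normalized values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormalizedExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class TmmParams:
    """TMM trim fractions and reference choice.

    ``trim_m``/``trim_a`` are the two-sided trim fractions applied to the
    log-ratio (M) and average-abundance (A) distributions. The reference
    sample is the column whose 75th percentile of scaled counts is closest
    to the mean 75th percentile, the method's canonical default.
    """

    trim_m: float = 0.30
    trim_a: float = 0.05
    reference: str | None = None  # sample ID; None = auto by upper quartile


def read_counts(path) -> RawCountMatrix:
    """Read a counts TSV: first column ``gene``, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError("no genes in counts file")
    if df.shape[1] == 0:
        raise ValueError("no samples in counts file")
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene symbols in counts file: {dupes}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("non-numeric cell in counts file")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("non-integer cell in counts file")
    return RawCountMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        counts=arr.astype(np.int64),
    )


def read_gene_lengths(path) -> GeneLengths:
    """Read a lengths TSV with columns ``gene`` and ``length_bp``."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "length_bp"}.issubset(df.columns):
        raise ValueError("lengths TSV must have columns 'gene' and 'length_bp'")
    lengths = dict(zip(df["gene"].astype(str), df["length_bp"].astype(int)))
    bad = [g for g, l in lengths.items() if l <= 0]
    if bad:
        raise ValueError(f"non-positive gene lengths: {bad[:5]}")
    return lengths


def _tmm_factor_pair(obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float) -> float:
    """TMM scaling factor of one sample against the reference.

    Trimmed, precision-weighted mean of per-gene log2 ratios (M-values)
    after removing genes with a zero count in either sample and trimming
    the tails of both the M and A distributions.
    """
    n_obs = obs.sum()
    n_ref = ref.sum()
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    p_o = o / n_obs
    p_r = r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(m)) < 1e-10:  # identical composition
        return 1.0

    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.nansum(m[keep2] / w[keep2]) / np.nansum(1.0 / w[keep2])
    factor = 2.0**f
    return factor if np.isfinite(factor) else 1.0


def tmm_factors(counts: RawCountMatrix, params: TmmParams | None = None) -> np.ndarray:
    """Per-sample TMM scaling factors, re-centered to geometric mean 1."""
    params = params or TmmParams()
    mat = counts.counts.astype(float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = [counts.samples[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"zero library size for samples: {bad}")

    if params.reference is not None:
        if params.reference not in counts.samples:
            raise ValueError(f"reference sample {params.reference!r} not found")
        ref_idx = counts.samples.index(params.reference)
    else:
        uq = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.array(
        [
            _tmm_factor_pair(mat[:, j], mat[:, ref_idx], params.trim_m, params.trim_a)
            for j in range(mat.shape[1])
        ]
    )
    # re-center so the factors multiply to 1
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def tmm_fpkm_log2(
    counts: RawCountMatrix,
    lengths: GeneLengths,
    params: TmmParams | None = None,
) -> NormalizedExpressionMatrix:
    """log2(TMM-FPKM + 1) normalization.

    FPKM uses the TMM-adjusted effective library size:
    ``fpkm = count * 1e9 / (lib_size * tmm_factor * length_bp)``.
    """
    missing = [g for g in counts.genes if g not in lengths]
    if missing:
        raise ValueError(f"genes missing from lengths: {missing[:5]}")
    factors = tmm_factors(counts, params)
    lib = counts.counts.sum(axis=0).astype(float)
    eff_lib = lib * factors
    lens = np.array([lengths[g] for g in counts.genes], dtype=float)
    fpkm = counts.counts * 1e9 / (eff_lib[None, :] * lens[:, None])
    return NormalizedExpressionMatrix(
        genes=list(counts.genes),
        samples=list(counts.samples),
        values=np.log2(fpkm + 1.0),
    )


def zscore_by_gene(expr: NormalizedExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across samples (sample sd, ddof=1).

    Constant genes map to all-zero rows so that signature sums never
    propagate NaN.
    """
    df = expr.to_frame() if isinstance(expr, NormalizedExpressionMatrix) else expr
    if df.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    # constant rows: sd may be a float-noise epsilon rather than exact 0
    tol = 1e-12 * (df.abs().max(axis=1) + 1.0)
    z = df.sub(mu, axis=0).div(sd.mask(sd <= tol), axis=0)
    return z.fillna(0.0)


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    """Write a matrix as TSV with 6 decimal places."""
    df.to_csv(path, sep="\t", float_format="%.6f", index_label=index_label)
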