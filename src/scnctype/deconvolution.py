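"""Cell-state fraction estimation from bulk expression.

A signature matrix holds a reference expression profile per cell state
(e.g. NE vs non-NE archetypes, six leukocyte subsets, or four stages of
MYC-driven tumor progression). Each bulk sample is modeled as a
non-negative combination of the reference profiles; coefficients are
renormalized to the simplex so they read as relative fractions.
Significance of a sample's fit is assessed by permuting the mixture's
gene labels and refitting (add-one permutation p-value), mirroring the
support-vector deconvolution convention of running 100 permutations with
quantile normalization disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .expr_io import NormalizedExpressionMatrix

__all__ = [
    "SignatureMatrix",
    "DeconvolutionParams",
    "FractionEstimate",
    "read_signature_matrix",
    "estimate_fractions",
    "permutation_pvalue",
]


@dataclass
class SignatureMatrix:
    """Reference expression per gene x cell state (non-negative)."""

    genes: list[str]
    states: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.states) < 2:
            raise ValueError("signature matrix needs >= 2 states")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature matrix")
        if self.values.shape != (len(self.genes), len(self.states)):
            raise ValueError("signature values shape mismatch")
        if (self.values < 0).any():
            raise ValueError("signature values must be non-negative")
        for i in range(len(self.states)):
            for j in range(i + 1, len(self.states)):
                if np.allclose(self.values[:, i], self.values[:, j]):
                    raise ValueError(
                        f"identical signature columns: {self.states[i]!r}, "
                        f"{self.states[j]!r}"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.states)


@dataclass
class DeconvolutionParams:
    method: str = "nnls"  # "nnls" | "nu_svr"
    n_permutations: int = 100
    quantile_normalize: bool = False  # disabled by convention

    def __post_init__(self) -> None:
        if self.method not in ("nnls", "nu_svr"):
            raise ValueError("method must be 'nnls' or 'nu_svr'")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")


@dataclass
class FractionEstimate:
    """Per-sample simplex of state fractions with fit diagnostics."""

    samples: list[str]
    states: list[str]
    fractions: np.ndarray  # (n_samples, n_states), rows sum to 1
    fit_r: np.ndarray
    rmse: np.ndarray
    p_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sample, state, fraction, fit_r, rmse, p_value."""
        rows = []
        for i, s in enumerate(self.samples):
            for k, st in enumerate(self.states):
                rows.append(
                    {
                        "sample": s,
                        "state": st,
                        "fraction": self.fractions[i, k],
                        "fit_r": self.fit_r[i],
                        "rmse": self.rmse[i],
                        "p_value": self.p_values[i],
                    }
                )
        return pd.DataFrame(rows)

    def wide(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.samples, columns=self.states)


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a signature TSV: ``gene`` column then one column per state."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(
        genes=[str(g) for g in df.index],
        states=[str(s) for s in df.columns],
        values=df.to_numpy(float),
    )


def _joint_standardize(sig: np.ndarray, mix: np.ndarray):
    """Standardize signature and mixture with one shared mean and sd.

    A shared affine transform preserves convex combinations exactly
    (coefficients summing to 1 absorb the shift), so noiseless mixtures
    remain exactly representable after standardization.
    """
    pool = np.concatenate([sig.ravel(), mix])
    mu, sd = pool.mean(), pool.std()
    if sd == 0:
        raise ValueError("degenerate (constant) signature and mixture")
    return (sig - mu) / sd, (mix - mu) / sd


def _fit_one(sig_std: np.ndarray, mix_std: np.ndarray, method: str):
    """Fit one standardized mixture; return raw non-negative coefficients."""
    if method == "nnls":
        coef, _ = nnls(sig_std, mix_std)
    else:  # nu_svr, CIBERSORT-style: best of nu in {0.25, 0.5, 0.75}
        from sklearn.svm import NuSVR

        best_coef, best_rmse = None, np.inf
        for nu in (0.25, 0.5, 0.75):
            svr = NuSVR(kernel="linear", nu=nu, C=1.0)
            svr.fit(sig_std, mix_std)
            c = np.clip(svr.coef_.ravel(), 0.0, None)
            resid = sig_std @ c - mix_std
            rmse = float(np.sqrt(np.mean(resid**2)))
            if rmse < best_rmse:
                best_coef, best_rmse = c, rmse
        coef = best_coef
    return coef


def _fit_stats(sig_std: np.ndarray, mix_std: np.ndarray, coef: np.ndarray):
    recon = sig_std @ coef
    resid = recon - mix_std
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.std(recon) == 0 or np.std(mix_std) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(recon, mix_std)[0, 1])
    return r, rmse


def _subspace_r(sig_std: np.ndarray, mix_std: np.ndarray) -> float:
    """Correlation between the mixture and its unconstrained least-squares
    projection onto the signature column space.

    Used as the permutation statistic: unlike the non-negative fit, it has
    no point mass (a degenerate NNLS fit pins R at 0), so null p-values
    stay uniform.
    """
    coef, *_ = np.linalg.lstsq(sig_std, mix_std, rcond=None)
    recon = sig_std @ coef
    if np.std(recon) == 0 or np.std(mix_std) == 0:
        return 0.0
    return float(np.corrcoef(recon, mix_std)[0, 1])


def permutation_pvalue(
    mixture: np.ndarray,
    sig: SignatureMatrix,
    n_perm: int = 100,
    seed: int | None = None,
) -> float:
    """Add-one permutation p-value for one sample's deconvolution fit.

    The statistic is the correlation between the mixture and its
    least-squares projection onto the signature column space; the null
    distribution permutes the mixture's gene labels and refits;
    ``p = (1 + #{null R >= observed R}) / (1 + n_perm)``.
    """
    if n_perm == 0:
        warnings.warn("n_permutations = 0: p-value undefined, returning 1")
        return 1.0
    mixture = np.asarray(mixture, dtype=float)
    sig_std, mix_std = _joint_standardize(sig.values, mixture)
    r_obs = _subspace_r(sig_std, mix_std)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(mixture))
        if _subspace_r(sig_std, mix_std[perm]) >= r_obs:
            n_ge += 1
    return (1 + n_ge) / (1 + n_perm)


def estimate_fractions(
    expr: NormalizedExpressionMatrix | pd.DataFrame,
    sig: SignatureMatrix,
    params: DeconvolutionParams | None = None,
    seed: int | None = None,
) -> FractionEstimate:
    """Estimate per-sample cell-state fractions against a signature matrix.

    Restricts to genes shared by mixture and signature (signature genes
    absent from the mixture are dropped, not zero-filled), standardizes
    jointly, solves non-negative least squares (or nu-SVR), and
    renormalizes coefficients to the simplex.
    """
    params = params or DeconvolutionParams()
    df = expr.to_frame() if isinstance(expr, NormalizedExpressionMatrix) else expr
    common = [g for g in sig.genes if g in df.index]
    if len(common) < 2:
        raise ValueError("fewer than 2 signature genes overlap the matrix")
    if len(common) < len(sig.genes):
        warnings.warn(
            f"{len(sig.genes) - len(common)} signature genes absent from the "
            "mixture, dropped"
        )
    sig_sub = sig.to_frame().loc[common].to_numpy()
    mix_mat = df.loc[common].to_numpy(float)

    n_samples = mix_mat.shape[1]
    n_states = len(sig.states)
    fractions = np.zeros((n_samples, n_states))
    fit_r = np.zeros(n_samples)
    rmse = np.zeros(n_samples)
    pvals = np.ones(n_samples)

    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = ss.spawn(n_samples)

    for j in range(n_samples):
        mix = mix_mat[:, j]
        if np.all(mix == 0):
            raise ValueError(
                f"sample {df.columns[j]!r} is all-zero over the signature genes"
            )
        sig_std, mix_std = _joint_standardize(sig_sub, mix)
        coef = _fit_one(sig_std, mix_std, params.method)
        fit_r[j], rmse[j] = _fit_stats(sig_std, mix_std, coef)
        total = coef.sum()
        if total == 0:
            fractions[j] = 1.0 / n_states  # uninformative fit: uniform
        else:
            fractions[j] = coef / total
        if params.n_permutations > 0:
            pvals[j] = permutation_pvalue(
                mix,
                SignatureMatrix(common, list(sig.states), sig_sub),
                n_perm=params.n_permutations,
                seed=child_seeds[j].generate_state(1)[0],
            )
        else:
            pvals[j] = 1.0

    return FractionEstimate(
        samples=list(df.columns),
        states=list(sig.states),
        fractions=fractions,
        fit_r=fit_r,
        rmse=rmse,
        p_values=pvals,
    )
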