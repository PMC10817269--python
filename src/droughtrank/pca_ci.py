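"""Comprehensive indices from a correlation-matrix PCA of treatment means.

The traits entering the evaluation carry incommensurate units
(μmol·m⁻²·s⁻¹, percentages, enzyme activities per gram), so the analysis is
a correlation-matrix PCA: each trait column of the treatment-mean matrix is
standardised to zero mean and unit sample variance (n − 1 denominator), and
the eigendecomposition of the resulting trait correlation matrix yields
eigenvalues λ_j, unit-norm loadings v_j and contribution rates
P_j = 100·λ_j / p with p the number of traits (the trace of a correlation
matrix).  The j-th comprehensive index is the component score rescaled to
unit sample variance,

    CI_j = (Z v_j) / sqrt(λ_j),

one value per treatment — the factor-score convention, under which every CI
column has sample standard deviation exactly 1.

Eigenvector signs are a free choice of the decomposition; they are fixed by
orienting each component so its largest-magnitude loading is positive (ties
broken by the lowest trait index).  The computation runs on numpy's SVD of
the standardised matrix; the explicit eigendecomposition of the correlation
matrix is retained as an independent route for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trait_io import MeanMatrix

__all__ = [
    "PCAResult",
    "standardize",
    "pca",
    "pca_eig",
    "select_components",
    "comprehensive_indices",
]

_EIGENVALUE_TOL = 1e-10


@dataclass
class PCAResult:
    """Eigenstructure of the trait correlation matrix.

    Attributes
    ----------
    eigenvalues : ndarray
        λ_j in descending order; all components, including (numerically)
        zero ones when treatments are fewer than traits.
    loadings : pandas.DataFrame
        Unit-norm eigenvectors, traits × components, sign-oriented.
    contribution_rates : ndarray
        P_j = 100·λ_j / (number of traits), in percent; sums to 100 over all
        components.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    contribution_rates: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def cumulative_rate(self, k: int) -> float:
        """Cumulative contribution of the first ``k`` components, in percent."""
        return float(self.contribution_rates[:k].sum())


def standardize(means: MeanMatrix | pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores of the treatment-mean matrix (n − 1 denominator).

    Raises
    ------
    ValueError
        if fewer than 2 treatments, or a trait has zero variance across
        treatments (it carries no ranking information and breaks the
        correlation normalisation); the error names the trait.
    """
    mat = means.mean if isinstance(means, MeanMatrix) else means
    if mat.shape[0] < 2:
        raise ValueError("standardization needs >= 2 treatments")
    sd = mat.std(ddof=1)
    dead = sd[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance trait(s): {', '.join(map(str, dead.index))}")
    return (mat - mat.mean()) / sd


def _orient_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so each column's largest |entry| is positive.

    Ties on |entry| resolve to the lowest row (trait) index, which numpy's
    argmax already guarantees.
    """
    flip = np.sign(vectors[np.abs(vectors).argmax(axis=0), np.arange(vectors.shape[1])])
    flip[flip == 0] = 1.0
    return vectors * flip


def pca(z: pd.DataFrame) -> PCAResult:
    """PCA of the standardised matrix via singular value decomposition.

    Eigenvalues are s²/(n − 1) for singular values s, padded with zeros up to
    the number of traits so that Σλ equals the trait count (trace of the
    correlation matrix) and contribution rates sum to 100%.
    """
    zv = np.asarray(z, dtype=float)
    n_obs, n_traits = zv.shape
    if n_obs < 2:
        raise ValueError("PCA needs >= 2 treatments")
    # full_matrices=True so V spans the null space too (zero eigenvalues)
    _, s, vt = np.linalg.svd(zv, full_matrices=True)
    eigenvalues = np.zeros(n_traits)
    eigenvalues[: len(s)] = s**2 / (n_obs - 1)
    vectors = _orient_signs(vt.T)
    loadings = pd.DataFrame(
        vectors,
        index=z.columns,
        columns=[f"PC{j + 1}" for j in range(n_traits)],
    )
    rates = 100.0 * eigenvalues / n_traits
    return PCAResult(eigenvalues=eigenvalues, loadings=loadings, contribution_rates=rates)


def pca_eig(z: pd.DataFrame) -> PCAResult:
    """Independent route: explicit eigendecomposition of the correlation matrix.

    Kept separate from :func:`pca` so the two can be compared; both must
    agree on eigenvalues and (up to the sign rule) loadings.
    """
    zv = np.asarray(z, dtype=float)
    n_obs, n_traits = zv.shape
    corr = zv.T @ zv / (n_obs - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), _orient_signs(v[:, order])
    loadings = pd.DataFrame(
        v, index=z.columns, columns=[f"PC{j + 1}" for j in range(n_traits)]
    )
    return PCAResult(
        eigenvalues=w, loadings=loadings, contribution_rates=100.0 * w / n_traits
    )


def select_components(
    res: PCAResult,
    policy: str = "fixed_k",
    *,
    k: int = 3,
    threshold: float = 85.0,
) -> int:
    """Choose how many components to retain.

    Policies: ``fixed_k`` retains exactly ``k``; ``kaiser`` retains all
    components with λ > 1; ``cumulative_threshold`` retains the smallest k
    whose cumulative contribution reaches ``threshold`` percent.
    """
    if policy == "fixed_k":
        if not 1 <= k <= res.n_components:
            raise ValueError(f"fixed_k={k} outside [1, {res.n_components}]")
        return k
    if policy == "kaiser":
        return max(int((res.eigenvalues > 1.0).sum()), 1)
    if policy == "cumulative_threshold":
        if not 0.0 < threshold <= 100.0:
            raise ValueError(f"cumulative threshold {threshold} outside (0, 100]")
        cum = np.cumsum(res.contribution_rates)
        return int(np.searchsorted(cum, threshold - 1e-9) + 1)
    raise ValueError(f"unknown policy {policy!r}")


def comprehensive_indices(z: pd.DataFrame, res: PCAResult, k: int) -> pd.DataFrame:
    """Unit-variance component scores CI_1..CI_k per treatment.

    CI_j = (Z v_j)/√λ_j, so every returned column has sample standard
    deviation 1 and distinct columns are uncorrelated across treatments.

    Raises
    ------
    ValueError
        if a requested component has a numerically zero eigenvalue (its
        score direction is undefined).
    """
    lam = res.eigenvalues[:k]
    if np.any(lam <= _EIGENVALUE_TOL):
        j = int(np.argmax(lam <= _EIGENVALUE_TOL)) + 1
        raise ValueError(f"component {j} has a degenerate (zero) eigenvalue")
    scores = np.asarray(z, dtype=float) @ res.loadings.to_numpy()[:, :k]
    ci = scores / np.sqrt(lam)
    return pd.DataFrame(
        ci, index=z.index, columns=[f"CI{j + 1}" for j in range(k)]
    )
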