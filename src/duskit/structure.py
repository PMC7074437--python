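"""Dosage PCA and genomic (VanRaden) kinship for distinctness cross-checks.

Both operations work on the column-centered dosage matrix with per-locus
mean imputation of missing calls: imputing a missing dosage with the locus
mean contributes exactly zero after centering, so it neither creates nor
destroys structure — unlike pairwise deletion, it keeps the matrix dense,
which eigendecompositions require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .markers_io import GenotypeMatrix


@dataclass
class PCAResult:
    """Scores for the first k components and all variance-explained fractions."""

    ids: list[str]
    scores: np.ndarray  # (n_plants, k)
    variance_fractions: np.ndarray  # (n_components,), sums to 1

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def cumulative_variance(self, k: int) -> float:
        return float(self.variance_fractions[:k].sum())


@dataclass
class KinshipMatrix:
    """Plants x plants genomic relationship values with the method recorded."""

    ids: list[str]
    values: np.ndarray
    method: str = "vanraden"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("kinship matrix must be symmetric")


def _imputed_centered(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, column-centered dosages and per-locus alt frequencies."""
    called = matrix.called
    if not called.any(axis=1).all():
        bad = [p for p, ok in zip(matrix.plants, called.any(axis=1)) if not ok]
        raise ValueError(f"plant(s) with no called loci: {bad}")
    calls = matrix.calls.astype(np.float64)
    n_called = called.sum(axis=0)
    n_called = np.maximum(n_called, 1)
    mean = np.where(called, calls, 0.0).sum(axis=0) / n_called
    x = np.where(called, calls, mean[None, :])
    return x - mean[None, :], mean / 2.0


def pca_genotypes(matrix: GenotypeMatrix, k: int = 3) -> PCAResult:
    """PCA of the centered dosage matrix via SVD.

    Component signs follow a fixed convention — the largest-magnitude locus
    loading of each component is made positive — so results are reproducible
    across platforms.  ``k`` larger than the available rank is clipped with a
    warning.
    """
    x, _ = _imputed_centered(matrix)
    n = matrix.n_plants
    max_k = min(n - 1, matrix.n_loci) if n > 1 else 0
    if k > max_k:
        warnings.warn(f"k={k} clipped to {max_k} available components", stacklevel=2)
        k = max_k
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention applied to loadings (rows of vt)
    for comp in range(min(len(s), x.shape[1])):
        j = int(np.argmax(np.abs(vt[comp])))
        if vt[comp, j] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    ev = s**2
    total = ev.sum()
    fractions = ev / total if total > 0 else np.zeros_like(ev)
    scores = u[:, :k] * s[:k]
    return PCAResult(
        ids=list(matrix.plants), scores=scores, variance_fractions=fractions
    )


def kinship_matrix(matrix: GenotypeMatrix, method: str = "vanraden") -> KinshipMatrix:
    """VanRaden genomic relationship matrix.

    K = Z Zᵀ / (2 Σ_l p_l (1 - p_l)) with Z the centered (mean-imputed)
    dosage matrix and p_l the alternate allele frequency at locus l.
    """
    if method != "vanraden":
        raise ValueError(f"unknown kinship method: {method!r}")
    z, p = _imputed_centered(matrix)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all loci are monomorphic; kinship denominator is zero")
    values = (z @ z.T) / denom
    values = (values + values.T) / 2.0
    return KinshipMatrix(ids=list(matrix.plants), values=values, method=method)
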