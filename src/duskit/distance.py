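"""Plant-pairwise genetic distances from SNP dosages and SSR allele sizes.

SNP distance is the allele-sharing distance

    d(i, j) = sum_L |g_i - g_j| / (2 * n_shared(i, j))

over loci called in both plants (pairwise deletion).  On complete data this
equals the p-distance on alleles of the concatenated genotypes: identical
plants are at 0, opposite homozygotes at every locus at 1.

SSR distance is the shared-allele distance: per marker, with ``s`` the size
of the multiset intersection of the two fragment-size pairs (0, 1 or 2), the
marker distance is ``1 - s/2``; plant-pair distance averages over markers
called in both plants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .markers_io import MISSING, GenotypeMatrix, SSRGenotypeTable


class UndefinedPairError(ValueError):
    """Some plant pair shares no called markers, so its distance is undefined."""

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = pairs
        shown = ", ".join(f"({a}, {b})" for a, b in pairs[:10])
        super().__init__(
            f"{len(pairs)} plant pair(s) share no called markers: {shown}"
        )


@dataclass
class DistanceMatrix:
    """Symmetric plant-pairwise distances in [0, 1] with per-pair marker counts."""

    ids: list[str]
    values: np.ndarray
    n_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        index = [self.ids.index(i) for i in ids]
        return DistanceMatrix(
            ids=list(ids),
            values=self.values[np.ix_(index, index)].copy(),
            n_used=None if self.n_used is None else self.n_used[np.ix_(index, index)],
        )

    # -- export -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("plant_id\t" + "\t".join(self.ids) + "\n")
            for i, pid in enumerate(self.ids):
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{pid}\t{row}\n")

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, pid in enumerate(self.ids):
                row = " ".join(f"{v:.10f}" for v in self.values[i])
                fh.write(f"{pid:<10s} {row}\n")


def _resolve_undefined(
    values: np.ndarray,
    n_used: np.ndarray,
    ids: list[str],
    allow_missing_pairs: bool,
) -> np.ndarray:
    undef = n_used == 0
    np.fill_diagonal(undef, False)
    if not undef.any():
        return values
    pairs = [
        (ids[i], ids[j]) for i, j in zip(*np.nonzero(np.triu(undef, k=1)))
    ]
    offdiag = ~np.eye(len(ids), dtype=bool)
    if not allow_missing_pairs or not (~undef & offdiag).any():
        raise UndefinedPairError(pairs)
    fill = float(np.nanmean(values[~undef & offdiag]))
    warnings.warn(
        f"{len(pairs)} undefined plant pair(s) imputed with matrix mean {fill:.4f}",
        stacklevel=3,
    )
    values = values.copy()
    values[undef] = fill
    return values


def distance_from_calls(
    calls: np.ndarray, ids: list[str], allow_missing_pairs: bool = False
) -> DistanceMatrix:
    """Allele-sharing distance from a raw dosage array (columns may repeat).

    The workhorse behind :func:`snp_distance_matrix` and the locus bootstrap.
    """
    called = calls != MISSING
    # One-hot decomposition of dosage makes sum |g_i - g_j| a set of matmuls:
    # |0-1| = |1-2| = 1, |0-2| = 2.
    g0 = ((calls == 0) & called).astype(np.float64)
    g1 = (calls == 1).astype(np.float64)
    g2 = (calls == 2).astype(np.float64)
    cross01 = g0 @ g1.T
    cross12 = g1 @ g2.T
    cross02 = g0 @ g2.T
    abs_diff = cross01 + cross01.T + cross12 + cross12.T + 2.0 * (cross02 + cross02.T)
    m = called.astype(np.float64)
    n_shared = (m @ m.T + 0.5).astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(n_shared > 0, abs_diff / (2.0 * n_shared), np.nan)
    np.fill_diagonal(values, 0.0)
    values = _resolve_undefined(values, n_shared, ids, allow_missing_pairs)
    return DistanceMatrix(ids=list(ids), values=values, n_used=n_shared)


def snp_distance_matrix(
    matrix: GenotypeMatrix, allow_missing_pairs: bool = False
) -> DistanceMatrix:
    """Allele-sharing distance with pairwise deletion of missing calls.

    A pair of plants with no jointly called locus is an error by default (a
    DUS verdict must not rest on silently imputed distances);
    ``allow_missing_pairs`` substitutes the matrix-wide mean with a warning.
    """
    if matrix.n_plants < 2:
        raise ValueError("need at least two plants")
    return distance_from_calls(matrix.calls, matrix.plants, allow_missing_pairs)


def _shared_alleles(a: np.ndarray, b: np.ndarray) -> int:
    """Multiset intersection size of two sorted fragment-size pairs."""
    if a[0] == b[0]:
        return 2 if a[1] == b[1] else 1
    # sorted pairs: compare across
    s = 0
    used = [False, False]
    for x in a:
        for k, y in enumerate(b):
            if not used[k] and x == y:
                used[k] = True
                s += 1
                break
    return s


def ssr_distance_matrix(
    table: SSRGenotypeTable, allow_missing_pairs: bool = False
) -> DistanceMatrix:
    """Shared-allele distance averaged over markers called in both plants."""
    if table.n_plants < 2:
        raise ValueError("need at least two plants")
    n = table.n_plants
    values = np.zeros((n, n))
    n_used = np.zeros((n, n), dtype=np.int64)
    called = table.called
    for i in range(n):
        n_used[i, i] = int(called[i].sum())
        for j in range(i + 1, n):
            both = called[i] & called[j]
            k = int(both.sum())
            n_used[i, j] = n_used[j, i] = k
            if k == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            total = 0.0
            for m in np.flatnonzero(both):
                s = _shared_alleles(table.sizes[i, m], table.sizes[j, m])
                total += 1.0 - s / 2.0
            values[i, j] = values[j, i] = total / k
    values = _resolve_undefined(values, n_used, table.plants, allow_missing_pairs)
    return DistanceMatrix(ids=list(table.plants), values=values, n_used=n_used)
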