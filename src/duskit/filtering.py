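"""Per-locus quality statistics, marker-retention filtering and gap statistics.

A locus enters the working panel when it is both *polymorphic* (minor allele
frequency at or above ``maf_min``, default 0.05) and *well genotyped*
(integrity — the fraction of plants with a non-missing call — at or above
``integrity_min``, default 0.8).  Both thresholds are inclusive; the MAF rule
is applied in the retention direction (keep common-enough minor alleles),
which is the only direction compatible with building a polymorphic
fingerprinting panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers_io import GenotypeMatrix, Locus, natural_chrom_key


def locus_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF, integrity and called-plant count.

    The alternate allele frequency ``p`` is computed over called alleles only:
    ``p = sum(dosage) / (2 * n_called)``; ``maf = min(p, 1 - p)``.  A locus
    with no calls at all gets ``maf = NaN`` and never passes a filter.
    """
    if matrix.n_plants < 1:
        raise ValueError("locus_stats requires at least one plant")
    called = matrix.called
    n_called = called.sum(axis=0)
    alt = np.where(called, matrix.calls, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(p, 1.0 - p)
    integrity = n_called / matrix.n_plants
    return pd.DataFrame(
        {
            "chrom": [l.chrom for l in matrix.loci],
            "pos": [l.pos for l in matrix.loci],
            "maf": maf,
            "integrity": integrity,
            "n_called": n_called,
        }
    )


def filter_markers(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    integrity_min: float = 0.8,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain loci with ``maf >= maf_min`` and ``integrity >= integrity_min``.

    Returns the filtered matrix (plant set unchanged) and a per-locus report
    with columns ``maf``, ``integrity``, ``retained`` and ``fail_reason``
    (``maf``, ``integrity``, ``maf+integrity`` or ``no_calls``).
    Idempotent: filtering an already-filtered matrix removes nothing.
    """
    for name, value in (("maf_min", maf_min), ("integrity_min", integrity_min)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    report = locus_stats(matrix)
    no_calls = report["n_called"] == 0
    fail_maf = ~no_calls & (report["maf"] < maf_min)
    fail_int = ~no_calls & (report["integrity"] < integrity_min)
    retained = ~(no_calls | fail_maf | fail_int)
    reason = np.select(
        [
            no_calls,
            fail_maf & fail_int,
            fail_maf,
            fail_int,
        ],
        ["no_calls", "maf+integrity", "maf", "integrity"],
        default="",
    )
    report = report.assign(retained=retained, fail_reason=reason)
    return matrix.subset_loci(np.flatnonzero(retained.to_numpy())), report


@dataclass
class GapStats:
    """Distances between consecutive loci within each chromosome.

    ``fraction_below`` is None when there are no gaps at all (at most one
    locus per chromosome).
    """

    threshold_bp: int
    gaps_by_chrom: dict[str, np.ndarray] = field(default_factory=dict)
    loci_per_chrom: dict[str, int] = field(default_factory=dict)

    @property
    def all_gaps(self) -> np.ndarray:
        if not self.gaps_by_chrom:
            return np.array([], dtype=np.int64)
        return np.concatenate(list(self.gaps_by_chrom.values()))

    @property
    def mean_gap(self) -> float | None:
        gaps = self.all_gaps
        return float(gaps.mean()) if gaps.size else None

    @property
    def fraction_below(self) -> float | None:
        gaps = self.all_gaps
        if not gaps.size:
            return None
        return float((gaps < self.threshold_bp).mean())


def gap_stats(loci: list[Locus], threshold_bp: int = 150_000) -> GapStats:
    """Adjacent-locus gap statistics, computed within chromosomes only.

    Loci must already be sorted by (chrom, pos); an unsorted list is a
    contract error, not silently reordered.
    """
    order = sorted(range(len(loci)), key=lambda i: loci[i].sort_key)
    if order != list(range(len(loci))):
        raise ValueError("loci must be sorted by (chrom, pos)")
    stats = GapStats(threshold_bp=threshold_bp)
    by_chrom: dict[str, list[int]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus.pos)
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        positions = np.asarray(by_chrom[chrom], dtype=np.int64)
        stats.loci_per_chrom[chrom] = positions.size
        stats.gaps_by_chrom[chrom] = np.diff(positions)
    return stats
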