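"""Headline DUS statistics: purity, stable heterozygous loci, off-type
classification, cultivar distinctness and the SNP-downsampling robustness
study.

Definitions
-----------
*Purity* of a plant is the fraction of its called loci that are homozygous
(dosage 0 or 2); cultivar purity summarizes plant purities (mean/min/max/sd,
in percent).  Inbred cultivars propagated by selfing are expected above 90%.

A locus is *stable heterozygous* within a cultivar when every non-missing
call among the cultivar's plants is heterozygous and the within-cultivar call
rate is at least 0.8 — tolerant of sporadic missingness, strict on zygosity.

An *off-type* plant (contaminant or mislabeled seed) sits far from its
declared cultivar on the tree: with r(p) the mean patristic distance from p
to its co-cultivar plants, p is flagged when both

    r(p) > median_c(r) + mad_k * MAD_c(r)      (outlier rule)
    r(p) > ratio_alpha * median_c(r)           (ratio guard)

hold.  Observed off-types show mean distances 6x-12x the within-cultivar
average, so the defaults (mad_k=5, ratio_alpha=3) flag that regime while the
ratio guard keeps tight homogeneous clusters free of false flags.

A cultivar is *distinct* when its (non-flagged) plants are exactly one side
of some bipartition of the tree; two cultivars are *separated* when some
edge splits the tree with one cultivar entirely on each side.  Bipartitions
are scale-free, so the verdicts do not depend on branch-length units.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, snp_distance_matrix
from .markers_io import GenotypeMatrix, SampleSheet
from .phylo import PhyloTree, nj_tree


# ---------------------------------------------------------------------------
# Purity
# ---------------------------------------------------------------------------

def plant_purity(matrix: GenotypeMatrix) -> pd.Series:
    """Per-plant fraction of called loci that are homozygous.

    Missing calls are excluded from both numerator and denominator.  A plant
    with zero called loci has undefined purity and raises, naming the plant.
    """
    called = matrix.called
    n_called = called.sum(axis=1)
    if (n_called == 0).any():
        bad = [p for p, n in zip(matrix.plants, n_called) if n == 0]
        raise ValueError(f"plant(s) with zero called loci: {bad}")
    hom = (((matrix.calls == 0) | (matrix.calls == 2)) & called).sum(axis=1)
    return pd.Series(hom / n_called, index=pd.Index(matrix.plants, name="plant_id"))


def cultivar_purity_table(purities: pd.Series, sheet: SampleSheet) -> pd.DataFrame:
    """Per-cultivar purity summary in percent (mean, min, max, sample sd).

    A single-plant cultivar gets sd 0 and a ``single_plant`` flag; a cultivar
    with no plants in `purities` is omitted with a warning.
    """
    sheet.check_covers(purities.index)
    rows = []
    for cultivar in sorted(set(sheet.labels.values())):
        plants = [p for p in purities.index if sheet[p] == cultivar]
        if not plants:
            warnings.warn(f"cultivar {cultivar!r} has no plants; omitted", stacklevel=2)
            continue
        values = purities.loc[plants] * 100.0
        single = len(values) == 1
        rows.append(
            {
                "cultivar": cultivar,
                "n_plants": len(values),
                "purity_pct": float(values.mean()),
                "min_pct": float(values.min()),
                "max_pct": float(values.max()),
                "std_pct": 0.0 if single else float(values.std(ddof=1)),
                "single_plant": single,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stable heterozygous loci
# ---------------------------------------------------------------------------

@dataclass
class HetSharing:
    """Stable-heterozygous locus sets per cultivar and their pairwise overlaps.

    ``counts`` is a symmetric cultivar x cultivar table: the diagonal holds
    the set sizes, off-diagonals the intersection sizes (never larger than
    either diagonal).
    """

    sets: dict[str, np.ndarray]  # cultivar -> sorted locus indices
    counts: pd.DataFrame

    @property
    def cultivars(self) -> list[str]:
        return list(self.counts.index)


def stable_het_loci(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    min_within_callrate: float = 0.8,
) -> HetSharing:
    """Identify per-cultivar stable heterozygous loci and their sharing matrix."""
    sheet.check_covers(matrix.plants)
    plant_row = {p: i for i, p in enumerate(matrix.plants)}
    cultivars = sorted({sheet[p] for p in matrix.plants})
    sets: dict[str, np.ndarray] = {}
    for cultivar in cultivars:
        rows = [plant_row[p] for p in matrix.plants if sheet[p] == cultivar]
        sub = matrix.calls[rows, :]
        called = sub != -1
        callrate = called.mean(axis=0)
        any_non_het = (called & (sub != 1)).any(axis=0)
        stable = (callrate >= min_within_callrate) & ~any_non_het
        sets[cultivar] = np.flatnonzero(stable)
    counts = pd.DataFrame(0, index=cultivars, columns=cultivars, dtype=int)
    for a in cultivars:
        sa = set(sets[a].tolist())
        for b in cultivars:
            counts.loc[a, b] = len(sa & set(sets[b].tolist()))
    return HetSharing(sets=sets, counts=counts)


# ---------------------------------------------------------------------------
# Off-type classification
# ---------------------------------------------------------------------------

@dataclass
class OffTypeReport:
    """Per-plant mean co-cultivar patristic distances and off-type flags."""

    per_plant: pd.DataFrame  # plant_id, cultivar, r, median_r, mad_r, flagged
    per_cultivar: pd.DataFrame  # within-cultivar max/min/average, flagged excluded
    mad_k: float
    ratio_alpha: float

    @property
    def flagged(self) -> frozenset:
        return frozenset(self.per_plant.loc[self.per_plant["flagged"], "plant_id"])


def classify_offtypes(
    patristic: DistanceMatrix,
    sheet: SampleSheet,
    mad_k: float = 5.0,
    ratio_alpha: float = 3.0,
) -> OffTypeReport:
    """Flag plants whose mean distance to co-cultivar plants is an outlier.

    Cultivars with fewer than three plants provide no baseline and are
    skipped with a warning.  The decision is invariant to plant ordering and
    to uniform rescaling of all distances.
    """
    sheet.check_covers(patristic.ids)
    index = {p: i for i, p in enumerate(patristic.ids)}
    cultivars = sorted({sheet[p] for p in patristic.ids})
    plant_rows = []
    cultivar_rows = []
    for cultivar in cultivars:
        plants = sorted(p for p in patristic.ids if sheet[p] == cultivar)
        if len(plants) < 3:
            warnings.warn(
                f"cultivar {cultivar!r} has fewer than 3 plants; off-type "
                "assessment skipped",
                stacklevel=2,
            )
            for p in plants:
                plant_rows.append(
                    {
                        "plant_id": p,
                        "cultivar": cultivar,
                        "r": np.nan,
                        "median_r": np.nan,
                        "mad_r": np.nan,
                        "flagged": False,
                    }
                )
            continue
        rows = np.array([index[p] for p in plants])
        sub = patristic.values[np.ix_(rows, rows)]
        n = len(plants)
        r = sub.sum(axis=1) / (n - 1)
        med = float(np.median(r))
        mad = float(np.median(np.abs(r - med)))
        flags = (r > med + mad_k * mad) & (r > ratio_alpha * med)
        for p, ri, fl in zip(plants, r, flags):
            plant_rows.append(
                {
                    "plant_id": p,
                    "cultivar": cultivar,
                    "r": float(ri),
                    "median_r": med,
                    "mad_r": mad,
                    "flagged": bool(fl),
                }
            )
        clean = np.flatnonzero(~flags)
        if len(clean) >= 2:
            pair = sub[np.ix_(clean, clean)]
            upper = pair[np.triu_indices(len(clean), k=1)]
            cultivar_rows.append(
                {
                    "cultivar": cultivar,
                    "n_plants": n,
                    "n_flagged": int(flags.sum()),
                    "max": float(upper.max()),
                    "min": float(upper.min()),
                    "average": float(upper.mean()),
                }
            )
    per_plant = pd.DataFrame(plant_rows).sort_values("plant_id", ignore_index=True)
    per_cultivar = pd.DataFrame(cultivar_rows)
    return OffTypeReport(
        per_plant=per_plant,
        per_cultivar=per_cultivar,
        mad_k=mad_k,
        ratio_alpha=ratio_alpha,
    )


# ---------------------------------------------------------------------------
# Distinctness
# ---------------------------------------------------------------------------

@dataclass
class DistinctnessReport:
    """Per-cultivar distinctness and pairwise separation on the NJ tree."""

    distinct: dict[str, bool]
    separated: dict[tuple[str, str], bool]
    excluded: frozenset = frozenset()

    @property
    def non_separated_pairs(self) -> list[tuple[str, str]]:
        return sorted(pair for pair, ok in self.separated.items() if not ok)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cultivar": list(self.distinct),
                "distinct": list(self.distinct.values()),
            }
        )


def distinctness_check(
    tree: PhyloTree,
    sheet: SampleSheet,
    flagged: frozenset | set = frozenset(),
) -> DistinctnessReport:
    """Tree-bipartition distinctness of cultivars, optionally excluding
    flagged off-type plants.

    A cultivar is distinct iff its retained plants are exactly one side of a
    bipartition (restricted to retained leaves).  Two cultivars are separated
    iff some edge has one entirely on each side; a shared-ancestry pair whose
    plants intermingle reports as non-separated.
    """
    leaves = set(tree.leaf_labels)
    sheet.check_covers(leaves)
    flagged = frozenset(flagged)
    keep = leaves - flagged
    cultsets = {
        c: frozenset(p for p in keep if sheet[p] == c)
        for c in sorted({sheet[p] for p in keep})
    }
    sides = set()
    for side in tree.bipartition_sides():
        restricted = frozenset(side & keep)
        sides.add(restricted)
        sides.add(frozenset(keep - restricted))
    distinct = {
        c: bool(plants) and plants in sides for c, plants in cultsets.items()
    }
    separated: dict[tuple[str, str], bool] = {}
    names = list(cultsets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ok = any(
                cultsets[a] <= side and not (cultsets[b] & side) for side in sides
            )
            separated[(a, b)] = ok
    return DistinctnessReport(distinct=distinct, separated=separated, excluded=flagged)


# ---------------------------------------------------------------------------
# Downsampling robustness
# ---------------------------------------------------------------------------

@dataclass
class RobustnessReport:
    """Outcome grid of the SNP-downsampling study.

    One row per (subset size, replicate): the derived child seed, a hash of
    the locus subset (for exact replay), the distinctness verdicts, the
    non-separated cultivar pairs and the flagged plants.
    """

    master_seed: int | None
    sizes: list[int]
    replicates: int
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            records.append(
                {
                    "size": row["size"],
                    "replicate": row["replicate"],
                    "subset_sha1": row["subset_sha1"],
                    "distinct": ";".join(
                        c for c, ok in sorted(row["distinct"].items()) if ok
                    ),
                    "non_separated_pairs": ";".join(
                        f"{a}|{b}" for a, b in row["non_separated_pairs"]
                    ),
                    "flagged": ";".join(sorted(row["flagged"])),
                }
            )
        return pd.DataFrame(records)


def downsample_robustness(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    sizes: list[int] = (10_000, 5_000, 1_000, 500),
    replicates: int = 3,
    seed: int | None = None,
    mad_k: float = 5.0,
    ratio_alpha: float = 3.0,
) -> RobustnessReport:
    """Re-run distance + NJ + off-type + distinctness on random locus subsets.

    Loci are sampled uniformly without replacement; the child generator for
    (size index, replicate) is spawned deterministically from the master
    seed, so the whole grid replays exactly.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    sizes = list(sizes)
    for size in sizes:
        if size < 1 or size > matrix.n_loci:
            raise ValueError(
                f"subset size {size} outside [1, {matrix.n_loci}] available loci"
            )
    report = RobustnessReport(master_seed=seed, sizes=sizes, replicates=replicates)
    for si, size in enumerate(sizes):
        for rep in range(replicates):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(si, rep))
            rng = np.random.default_rng(ss)
            idx = np.sort(rng.choice(matrix.n_loci, size=size, replace=False))
            sub = matrix.subset_loci(idx)
            tree = nj_tree(snp_distance_matrix(sub))
            off = classify_offtypes(
                tree.patristic(), sheet, mad_k=mad_k, ratio_alpha=ratio_alpha
            )
            dc = distinctness_check(tree, sheet, off.flagged)
            report.rows.append(
                {
                    "size": size,
                    "replicate": rep,
                    "child_seed_key": (si, rep),
                    "subset_sha1": hashlib.sha1(idx.tobytes()).hexdigest(),
                    "distinct": dc.distinct,
                    "non_separated_pairs": dc.non_separated_pairs,
                    "flagged": sorted(off.flagged),
                }
            )
    return report
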