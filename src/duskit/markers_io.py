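"""Genotype containers and readers/writers for the standard marker formats.

The central substrate of the whole pipeline is the :class:`GenotypeMatrix`:
plants x loci diploid genotype calls encoded as alternate-allele *dosage*
(0, 1, 2) with ``MISSING = -1`` for no-calls.  For biallelic diploid SNPs
every downstream statistic (minor allele frequency, heterozygosity, genetic
distance, kinship) is a function of dosage, so allele strings are dropped at
the door.

Supported formats:

* VCF 4.x with ``GT`` calls (read via :mod:`cyvcf2`, written as plain text);
* a plant sample sheet (TSV: ``plant_id``, ``cultivar``);
* an SSR fragment-size table (TSV: ``plant_id``, ``marker``, ``allele1_bp``,
  ``allele2_bp``, optional ``chrom``; ``NA`` marks a failed amplification).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing diploid call.
MISSING: int = -1

_BASES = {"A", "C", "G", "T"}


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class DuplicateLocusError(FormatError):
    """Two records share the same (chrom, pos)."""


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key ordering chromosome names with numeric awareness.

    ``chr2 < chr10`` and ``Gm01 < Gm02 < Gm10``.
    """
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP site: 1-based position, single-base ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def sort_key(self) -> tuple:
        return (natural_chrom_key(self.chrom), self.pos)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


def sort_loci_order(loci: Sequence[Locus]) -> np.ndarray:
    """Indices that sort loci by (natural chromosome name, position)."""
    return np.array(
        sorted(range(len(loci)), key=lambda i: loci[i].sort_key), dtype=int
    )


@dataclass
class GenotypeMatrix:
    """Plants x loci diploid dosage calls.

    ``calls[i, j]`` is the number of alternate alleles carried by plant ``i``
    at locus ``j`` (0, 1, 2) or :data:`MISSING`.
    """

    plants: list[str]
    loci: list[Locus]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.plants), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.plants)} plants x {len(self.loci)} loci"
            )
        if len(set(self.plants)) != len(self.plants):
            raise ValueError("plant IDs must be unique")
        ok = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid dosage codes: {bad.tolist()}")
        keys = [(l.chrom, l.pos) for l in self.loci]
        if len(set(keys)) != len(keys):
            raise DuplicateLocusError("duplicate (chrom, pos) among loci")

    # -- shape ------------------------------------------------------------
    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    # -- slicing ----------------------------------------------------------
    def subset_loci(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            plants=list(self.plants),
            loci=[self.loci[i] for i in index],
            calls=self.calls[:, index].copy(),
        )

    def subset_plants(self, plants: Sequence[str]) -> "GenotypeMatrix":
        pos = {p: i for i, p in enumerate(self.plants)}
        index = [pos[p] for p in plants]
        return GenotypeMatrix(
            plants=list(plants),
            loci=list(self.loci),
            calls=self.calls[index, :].copy(),
        )

    def sorted_by_plant(self) -> "GenotypeMatrix":
        return self.subset_plants(sorted(self.plants))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.plants == other.plants
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class SampleSheet:
    """Mapping of plant ID to declared cultivar label, in file order."""

    labels: dict[str, str]

    @property
    def plants(self) -> list[str]:
        return list(self.labels)

    @property
    def cultivars(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.labels.values():
            seen.setdefault(c)
        return list(seen)

    def plants_of(self, cultivar: str) -> list[str]:
        return [p for p, c in self.labels.items() if c == cultivar]

    def __getitem__(self, plant: str) -> str:
        return self.labels[plant]

    def __len__(self) -> int:
        return len(self.labels)

    def check_covers(self, plants: Iterable[str]) -> None:
        """Raise if any of `plants` has no declared cultivar."""
        orphans = [p for p in plants if p not in self.labels]
        if orphans:
            raise FormatError(
                f"{len(orphans)} plant(s) missing from sample sheet: "
                + ", ".join(orphans[:10])
            )


@dataclass
class SSRGenotypeTable:
    """Plants x SSR markers; each call is an unordered pair of fragment sizes.

    ``sizes[i, j]`` is a sorted ``(low_bp, high_bp)`` pair, or ``(-1, -1)``
    for a failed call.  Homozygotes carry the same size twice.
    """

    plants: list[str]
    markers: list[str]
    sizes: np.ndarray  # (n_plants, n_markers, 2) int
    marker_chrom: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int32)
        if self.sizes.shape != (len(self.plants), len(self.markers), 2):
            raise ValueError("sizes shape mismatch")
        called = self.sizes[..., 0] != MISSING
        if (self.sizes[called] <= 0).any():
            raise ValueError("fragment sizes must be positive")
        if (self.sizes[..., 0] > self.sizes[..., 1])[called].any():
            raise ValueError("allele pairs must be stored sorted")

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def called(self) -> np.ndarray:
        return self.sizes[..., 0] != MISSING


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, strict: bool = False) -> GenotypeMatrix:
    """Read diploid biallelic SNP genotypes from a VCF 4.x file.

    Dosage is the count of alternate alleles in ``GT``; ``./.`` (phased or
    unphased) becomes :data:`MISSING`.  Phasing separators are ignored.
    Multiallelic records and indels are skipped with a logged count, or
    rejected when ``strict`` is true.  Loci are returned sorted by natural
    chromosome name, then position.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    plants = list(vcf.samples)
    if not plants:
        raise FormatError(f"{path}: VCF contains no samples")

    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    skipped = 0
    seen: set[tuple[str, int]] = set()
    for var in vcf:
        if "GT" not in (var.FORMAT or []):
            raise FormatError(f"{path}: record {var.CHROM}:{var.POS} lacks GT")
        if (
            len(var.ALT) != 1
            or len(var.REF) != 1
            or len(var.ALT[0]) != 1
            or var.REF.upper() not in _BASES
            or var.ALT[0].upper() not in _BASES
        ):
            if strict:
                raise FormatError(
                    f"{path}: non-biallelic-SNP record at {var.CHROM}:{var.POS}"
                )
            skipped += 1
            continue
        key = (var.CHROM, var.POS)
        if key in seen:
            raise DuplicateLocusError(f"{path}: duplicate locus {var.CHROM}:{var.POS}")
        seen.add(key)
        loci.append(Locus(var.CHROM, var.POS, var.REF.upper(), var.ALT[0].upper()))
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if skipped:
        logger.info("%s: skipped %d non-biallelic-SNP record(s)", path, skipped)

    calls = (
        np.stack(rows, axis=1) if rows else np.zeros((len(plants), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(plants=plants, loci=loci, calls=calls)
    order = sort_loci_order(matrix.loci)
    return matrix.subset_loci(order)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 file that round-trips through :func:`read_vcf`."""
    if matrix.n_plants == 0:
        raise ValueError("cannot write a VCF with no plants")
    path = Path(path)
    chroms: dict[str, None] = {}
    for locus in matrix.loci:
        chroms.setdefault(locus.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=duskit\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.plants)
            + "\n"
        )
        for j, locus in enumerate(matrix.loci):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in matrix.calls[:, j])
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref}\t{locus.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV with columns ``plant_id`` and ``cultivar``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("plant_id", "cultivar"):
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet lacks column '{col}'")
    if df["plant_id"].duplicated().any():
        dup = df.loc[df["plant_id"].duplicated(), "plant_id"].iloc[0]
        raise FormatError(f"{path}: duplicate plant ID '{dup}'")
    return SampleSheet(labels=dict(zip(df["plant_id"], df["cultivar"])))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        {"plant_id": sheet.plants, "cultivar": [sheet[p] for p in sheet.plants]}
    ).to_csv(path, sep="\t", index=False)


def read_ssr_table(path: str | Path) -> SSRGenotypeTable:
    """Read a long-format SSR TSV into a plants x markers size table.

    Columns ``plant_id``, ``marker``, ``allele1_bp``, ``allele2_bp`` are
    required; ``chrom`` is kept if present.  ``NA`` in either size column
    marks the whole call missing.  Allele order within a row is irrelevant.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("plant_id", "marker", "allele1_bp", "allele2_bp")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: SSR table lacks column '{col}'")
    if df.duplicated(subset=["plant_id", "marker"]).any():
        raise FormatError(f"{path}: duplicate (plant, marker) rows")

    plants: list[str] = list(dict.fromkeys(df["plant_id"]))
    markers: list[str] = list(dict.fromkeys(df["marker"]))
    p_idx = {p: i for i, p in enumerate(plants)}
    m_idx = {m: j for j, m in enumerate(markers)}
    sizes = np.full((len(plants), len(markers), 2), MISSING, dtype=np.int32)
    marker_chrom: dict[str, str] = {}
    has_chrom = "chrom" in df.columns
    for row in df.itertuples(index=False):
        a1, a2 = row.allele1_bp, row.allele2_bp
        if pd.isna(a1) or pd.isna(a2) or a1 == "NA" or a2 == "NA":
            continue
        try:
            pair = sorted((int(a1), int(a2)))
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-integer fragment size for "
                f"{row.plant_id}/{row.marker}: {a1!r}, {a2!r}"
            ) from exc
        if pair[0] <= 0:
            raise FormatError(
                f"{path}: non-positive fragment size for {row.plant_id}/{row.marker}"
            )
        sizes[p_idx[row.plant_id], m_idx[row.marker]] = pair
        if has_chrom and not pd.isna(row.chrom):
            marker_chrom[row.marker] = row.chrom
    return SSRGenotypeTable(
        plants=plants, markers=markers, sizes=sizes, marker_chrom=marker_chrom
    )


def write_ssr_table(table: SSRGenotypeTable, path: str | Path) -> None:
    rows = []
    for i, plant in enumerate(table.plants):
        for j, marker in enumerate(table.markers):
            a1, a2 = table.sizes[i, j]
            rows.append(
                {
                    "plant_id": plant,
                    "marker": marker,
                    "chrom": table.marker_chrom.get(marker, "NA"),
                    "allele1_bp": "NA" if a1 == MISSING else int(a1),
                    "allele2_bp": "NA" if a2 == MISSING else int(a2),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
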