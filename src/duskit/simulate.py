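"""Synthetic cultivar-panel generator with ground truth.

The generator emulates the genetic structure of registered inbred crop
cultivars (soybean-style: 20 chromosomes, biallelic SNPs):

* each cultivar descends from a biparental cross of two fully homozygous
  founders followed by ``g`` generations of single-seed-descent selfing —
  every sampled plant is an independent SSD lineage, so residual
  heterozygosity at founder-differing loci is ``0.5**g`` per locus in
  expectation;
* a small set of loci per cultivar is pinned permanently heterozygous
  (a phenomenological stand-in for the stably heterozygous loci observed in
  long-cultivated inbred lines; the pinned sets of different cultivars are
  drawn from a shared pool, so their pairwise overlaps are non-trivial);
* occasional plants are *off-types*: seeds of a different (donor) cultivar
  relabeled with the host cultivar;
* genotyping noise: calls dropped to missing with rate ``mu`` and perturbed
  with rate ``epsilon`` (hom -> het, het -> random hom).

Founder genomes derive from a common all-reference ancestor by independent
per-locus flips (``divergence`` = flip probability, relative to the named
``anchor`` founder or to the ancestor), or as a random fixation of a cross
of two earlier founders — which is how a "parent cultivar as founder"
pedigree is expressed.  Loci segregate independently (no linkage map): every
downstream statistic in this package is locus-exchangeable.

All outputs are exact functions of (config, master seed); every stage draws
from a generator spawned from the master ``SeedSequence`` with a fixed key.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers_io import (
    MISSING,
    GenotypeMatrix,
    Locus,
    SampleSheet,
    SSRGenotypeTable,
    sort_loci_order,
    write_sample_sheet,
    write_ssr_table,
    write_vcf,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FounderSpec:
    """A fully homozygous founder genome.

    Exactly one of three modes:
    ``anchor=None`` — flips from the all-reference ancestor with probability
    ``divergence``; ``anchor=name`` — flips from that founder; ``cross=(a,
    b)`` — each locus takes founder a's or b's allele with equal probability
    (an inbred line bred from that cross, usable as a pedigree parent).
    """

    name: str
    anchor: str | None = None
    divergence: float = 0.5
    cross: tuple[str, str] | None = None

    def validate(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ConfigError(f"founder {self.name}: divergence outside [0, 1]")
        if self.cross is not None and self.anchor is not None:
            raise ConfigError(f"founder {self.name}: cross and anchor are exclusive")


@dataclass
class CultivarSpec:
    name: str
    founder_a: str
    founder_b: str
    selfing_generations: int = 6
    n_plants: int = 20
    n_stable_het: int = 40
    #: reuse another (earlier) cultivar's pinned stable-het locus set — for
    #: sister cultivars released from the same cross, which must stay
    #: indistinguishable marker by marker.
    stable_het_like: str | None = None

    def validate(self) -> None:
        if self.selfing_generations < 0:
            raise ConfigError(f"cultivar {self.name}: selfing_generations < 0")
        if self.n_plants < 1:
            raise ConfigError(f"cultivar {self.name}: n_plants < 1")
        if self.n_stable_het < 0:
            raise ConfigError(f"cultivar {self.name}: n_stable_het < 0")


@dataclass
class OffTypeSpec:
    host: str
    donor: str
    count: int = 1

    def validate(self) -> None:
        if self.host == self.donor:
            raise ConfigError(f"off-type donor equals host cultivar {self.host!r}")
        if self.count < 0:
            raise ConfigError("off-type count < 0")


@dataclass
class SimulationConfig:
    n_loci: int = 40_000
    n_chromosomes: int = 20
    chromosome_length: int = 48_000_000
    founders: list[FounderSpec] = field(default_factory=list)
    cultivars: list[CultivarSpec] = field(default_factory=list)
    stable_het_pool: int = 150
    off_types: list[OffTypeSpec] = field(default_factory=list)
    missing_rate: float = 0.05
    error_rate: float = 0.01
    seed: int = 1

    def validate(self) -> None:
        if self.n_loci < 1 or self.n_chromosomes < 1:
            raise ConfigError("n_loci and n_chromosomes must be positive")
        if self.n_loci > self.n_chromosomes * self.chromosome_length:
            raise ConfigError("more loci than genome positions")
        for rate, name in (
            (self.missing_rate, "missing_rate"),
            (self.error_rate, "error_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} outside [0, 1]")
        known: set[str] = set()
        for f in self.founders:
            f.validate()
            if f.name in known:
                raise ConfigError(f"duplicate founder {f.name!r}")
            if f.anchor is not None and f.anchor not in known:
                raise ConfigError(f"founder {f.name}: anchor {f.anchor!r} not built yet")
            if f.cross is not None:
                for parent in f.cross:
                    if parent not in known:
                        raise ConfigError(
                            f"founder {f.name}: cross parent {parent!r} not built yet"
                        )
            known.add(f.name)
        cnames = set()
        for c in self.cultivars:
            c.validate()
            if c.name in cnames:
                raise ConfigError(f"duplicate cultivar {c.name!r}")
            if c.stable_het_like is not None and c.stable_het_like not in cnames:
                raise ConfigError(
                    f"cultivar {c.name}: stable_het_like refers to "
                    f"{c.stable_het_like!r}, which is not defined earlier"
                )
            cnames.add(c.name)
            for fname in (c.founder_a, c.founder_b):
                if fname not in known:
                    raise ConfigError(f"cultivar {c.name}: unknown founder {fname!r}")
        for o in self.off_types:
            o.validate()
            for cname in (o.host, o.donor):
                if cname not in cnames:
                    raise ConfigError(f"off-type spec: unknown cultivar {cname!r}")

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        raw["founders"] = [
            FounderSpec(
                name=f["name"],
                anchor=f.get("anchor"),
                divergence=f.get("divergence", 0.5),
                cross=tuple(f["cross"]) if f.get("cross") else None,
            )
            for f in raw.get("founders", [])
        ]
        raw["cultivars"] = [CultivarSpec(**c) for c in raw.get("cultivars", [])]
        raw["off_types"] = [OffTypeSpec(**o) for o in raw.get("off_types", [])]
        config = cls(**raw)
        config.validate()
        return config


def default_config(seed: int = 1) -> SimulationConfig:
    """The bundled five-cultivar study design.

    Five inbred cultivars of 20 plants each (g = 6 selfing generations):
    two sister cultivars released from the *same* biparental cross (the
    indistinguishable shared-ancestry pair), a parent-offspring pair (one
    cultivar's founder is an inbred line bred from the other cultivar's
    cross), and one unrelated cultivar.  One off-type seed from a distant
    donor is planted into each of the two sister cultivars.  Founder pairs
    within a cross are closely related (narrow elite background, 4% locus
    divergence) while cross ancestors differ at ~32% of loci, giving
    within-cultivar patristic distances near 0.02-0.03 and between-cultivar
    distances of 0.05-0.35 — the regime observed in real inbred panels.
    """
    return SimulationConfig(
        founders=[
            FounderSpec("fndY", divergence=0.2),
            FounderSpec("fndP", anchor="fndY", divergence=0.04),
            FounderSpec("fndP2", anchor="fndP", divergence=0.0),
            FounderSpec("fndC", divergence=0.2),
            FounderSpec("fndD", anchor="fndC", divergence=0.04),
            FounderSpec("lineCD", cross=("fndC", "fndD")),
            FounderSpec("fndK", anchor="lineCD", divergence=0.08),
            FounderSpec("fndG", divergence=0.2),
            FounderSpec("fndH", anchor="fndG", divergence=0.04),
        ],
        cultivars=[
            CultivarSpec("cv1", "fndY", "fndP"),
            CultivarSpec("cv2", "fndY", "fndP2", stable_het_like="cv1"),
            CultivarSpec("cv3", "fndC", "fndD"),
            CultivarSpec("cv4", "lineCD", "fndK"),
            CultivarSpec("cv5", "fndG", "fndH"),
        ],
        off_types=[
            OffTypeSpec(host="cv1", donor="cv5", count=1),
            OffTypeSpec(host="cv2", donor="cv3", count=1),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

@dataclass
class FounderPanel:
    """Homozygous founder genomes (0 = ref allele, 1 = alt) over shared loci."""

    loci: list[Locus]
    genomes: dict[str, np.ndarray]
    stable_sets: dict[str, np.ndarray]  # cultivar -> locus indices, pinned het


def _simulate_loci(config: SimulationConfig, rng: np.random.Generator) -> list[Locus]:
    per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per_chrom[: config.n_loci % config.n_chromosomes] += 1
    bases = np.array(list("ACGT"))
    loci: list[Locus] = []
    for ci in range(config.n_chromosomes):
        chrom = f"Gm{ci + 1:02d}"
        want = int(per_chrom[ci])
        positions: set[int] = set()
        while len(positions) < want:
            draw = rng.integers(1, config.chromosome_length + 1, size=want)
            positions.update(draw.tolist())
        for pos in sorted(positions)[:want]:
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + 1 + int(rng.integers(0, 3))) % 4
            loci.append(Locus(chrom, int(pos), str(bases[ref_i]), str(bases[alt_i])))
    order = sort_loci_order(loci)
    return [loci[i] for i in order]


def simulate_founders(
    config: SimulationConfig, seed: int | np.random.SeedSequence | None = None
) -> FounderPanel:
    """Build founder genomes, loci and the pinned stable-heterozygous sets.

    An anchored founder at divergence q differs from its anchor at a
    Binomial(n_loci, q) set of loci.  Each cultivar's stable-het loci are
    sampled from a shared candidate pool and the cultivar's second founder
    is forced to the opposite allele there, so pinned loci are always
    founder-differing.
    """
    config.validate()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed if seed is None else seed)
    )
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=ss.spawn_key + (0,)
    ))
    loci = _simulate_loci(config, rng)
    n = config.n_loci

    genomes: dict[str, np.ndarray] = {}
    for spec in config.founders:
        if spec.cross is not None:
            a, b = (genomes[p] for p in spec.cross)
            pick = rng.random(n) < 0.5
            genome = np.where(pick, a, b).astype(np.uint8)
        else:
            base = genomes[spec.anchor] if spec.anchor else np.zeros(n, dtype=np.uint8)
            flips = rng.random(n) < spec.divergence
            genome = (base ^ flips).astype(np.uint8)
        genomes[spec.name] = genome

    pool_size = min(config.stable_het_pool, n)
    pool = np.sort(rng.choice(n, size=pool_size, replace=False))
    stable_sets: dict[str, np.ndarray] = {}
    for cult in config.cultivars:
        if cult.stable_het_like is not None:
            chosen = stable_sets[cult.stable_het_like].copy()
        else:
            take = min(cult.n_stable_het, pool_size)
            chosen = np.sort(rng.choice(pool, size=take, replace=False))
        stable_sets[cult.name] = chosen
        fa, fb = genomes[cult.founder_a], genomes[cult.founder_b]
        fb[chosen] = 1 - fa[chosen]
    return FounderPanel(loci=loci, genomes=genomes, stable_sets=stable_sets)


# ---------------------------------------------------------------------------
# Cultivar populations
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """Noise-free genotypes of one cultivar's plants with per-plant truth."""

    cultivar: str
    ids: list[str]
    calls: np.ndarray  # true dosages (n_plants, n_loci)
    off_type: np.ndarray  # bool per plant
    true_cultivar: list[str]


def simulate_cultivar_population(
    founder_a: np.ndarray,
    founder_b: np.ndarray,
    selfing_generations: int,
    n_plants: int,
    stable_het_loci: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    cultivar: str = "cv",
) -> Population:
    """Independent single-seed-descent lineages from an F1 of two founders.

    Starting from the fully heterozygous F1 at founder-differing loci, each
    heterozygous locus per generation fixes to either homozygote with
    probability 1/4 each and stays heterozygous with probability 1/2
    (homozygous states are absorbing), so residual heterozygosity after g
    generations is ``0.5**g`` per segregating locus.  Loci in
    ``stable_het_loci`` (which must be founder-differing) stay pinned
    heterozygous in every plant.
    """
    rng = rng if rng is not None else np.random.default_rng()
    fa = np.asarray(founder_a, dtype=np.uint8)
    fb = np.asarray(founder_b, dtype=np.uint8)
    if fa.shape != fb.shape:
        raise ConfigError("founder genomes differ in length")
    seg = np.flatnonzero(fa != fb)
    stable = (
        np.asarray(stable_het_loci, dtype=int)
        if stable_het_loci is not None
        else np.array([], dtype=int)
    )
    if stable.size and not np.isin(stable, seg).all():
        raise ConfigError("stable_het_loci must be founder-differing loci")

    # SSD Markov chain over segregating loci: 0 = het, 1 = fixed A, 2 = fixed B
    state = np.zeros((n_plants, seg.size), dtype=np.uint8)
    for _ in range(selfing_generations):
        u = rng.random(state.shape)
        het = state == 0
        state[het & (u < 0.25)] = 1
        state[het & (u >= 0.25) & (u < 0.5)] = 2

    calls = np.broadcast_to(2 * fa, (n_plants, fa.size)).astype(np.int8).copy()
    seg_dosage = np.where(
        state == 0, 1, np.where(state == 1, 2 * fa[seg], 2 * fb[seg])
    ).astype(np.int8)
    calls[:, seg] = seg_dosage
    if stable.size:
        calls[:, stable] = 1

    ids = [f"{cultivar}-{i + 1:02d}" for i in range(n_plants)]
    return Population(
        cultivar=cultivar,
        ids=ids,
        calls=calls,
        off_type=np.zeros(n_plants, dtype=bool),
        true_cultivar=[cultivar] * n_plants,
    )


def inject_offtypes(
    population: Population,
    donor: Population,
    k: int,
    rng: np.random.Generator,
) -> Population:
    """Replace k random host plants with donor-drawn plants (labels kept).

    The replaced plants keep their host plant IDs (they sit in the host's
    seed lot) but the truth table records their real origin.
    """
    if population is donor or population.cultivar == donor.cultivar:
        raise ConfigError("off-type donor must be a different cultivar")
    n = len(population.ids)
    if k >= n:
        raise ConfigError("cannot replace every host plant: no baseline remains")
    if k == 0:
        return population
    if k > len(donor.ids):
        raise ConfigError("donor population smaller than requested off-type count")
    host_idx = np.sort(rng.choice(n, size=k, replace=False))
    donor_idx = rng.choice(len(donor.ids), size=k, replace=False)
    calls = population.calls.copy()
    off = population.off_type.copy()
    true_cv = list(population.true_cultivar)
    for hi, di in zip(host_idx, donor_idx):
        calls[hi] = donor.calls[di]
        off[hi] = True
        true_cv[hi] = donor.cultivar
    return Population(
        cultivar=population.cultivar,
        ids=list(population.ids),
        calls=calls,
        off_type=off,
        true_cultivar=true_cv,
    )


def apply_noise(
    calls: np.ndarray,
    missing_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotyping noise: dropout to MISSING, then per-call perturbation.

    Surviving calls are perturbed with probability ``error_rate``:
    homozygotes become heterozygous, heterozygotes become a random
    homozygote — the two dominant biallelic miscall modes.
    """
    for rate in (missing_rate, error_rate):
        if not 0.0 <= rate <= 1.0:
            raise ConfigError("noise rates must lie in [0, 1]")
    noisy = calls.astype(np.int8).copy()
    miss = rng.random(noisy.shape) < missing_rate
    err = (rng.random(noisy.shape) < error_rate) & ~miss
    hom_err = err & ((noisy == 0) | (noisy == 2))
    het_err = err & (noisy == 1)
    noisy[hom_err] = 1
    to_hom = rng.random(noisy.shape) < 0.5
    noisy[het_err & to_hom] = 0
    noisy[het_err & ~to_hom] = 2
    noisy[miss] = MISSING
    return noisy


# ---------------------------------------------------------------------------
# SSR panel
# ---------------------------------------------------------------------------

def simulate_ssr_panel(
    config: SimulationConfig,
    plants: pd.DataFrame,
    n_markers: int = 42,
    seed: int | np.random.SeedSequence | None = None,
) -> SSRGenotypeTable:
    """Homozygous SSR fragment sizes per plant, >= 1 marker per chromosome.

    Marker alleles are drawn per *founder* (anchored founders inherit their
    anchor's allele and mutate with the anchor divergence; crosses pick a
    parent allele), and each cultivar fixes one parental allele per marker —
    so cultivars bred from the same founders share SSR profiles exactly as
    they share SNP profiles.  Off-type plants carry their true cultivar's
    profile.  `plants` needs columns plant_id and true_cultivar.
    """
    if n_markers < config.n_chromosomes:
        raise ConfigError("need at least one SSR marker per chromosome")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed if seed is None else seed)
    )
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=ss.spawn_key + (5,)
    ))
    markers = [f"SSR{m + 1:03d}" for m in range(n_markers)]
    marker_chrom = {}
    for m, name in enumerate(markers):
        ci = m % config.n_chromosomes if m < config.n_chromosomes else int(
            rng.integers(0, config.n_chromosomes)
        )
        marker_chrom[name] = f"Gm{ci + 1:02d}"

    founder_allele: dict[str, np.ndarray] = {}
    base = 120 + 4 * rng.integers(0, 40, size=n_markers)
    for spec in config.founders:
        if spec.cross is not None:
            a, b = (founder_allele[p] for p in spec.cross)
            pick = rng.random(n_markers) < 0.5
            founder_allele[spec.name] = np.where(pick, a, b)
        elif spec.anchor is not None:
            mut = rng.random(n_markers) < spec.divergence
            fresh = base + 2 * rng.integers(1, 20, size=n_markers)
            founder_allele[spec.name] = np.where(
                mut, fresh, founder_allele[spec.anchor]
            )
        else:
            founder_allele[spec.name] = base + 2 * rng.integers(0, 20, size=n_markers)

    cultivar_allele: dict[str, np.ndarray] = {}
    for cult in config.cultivars:
        pick = rng.random(n_markers) < 0.5
        cultivar_allele[cult.name] = np.where(
            pick, founder_allele[cult.founder_a], founder_allele[cult.founder_b]
        )

    ids = list(plants["plant_id"])
    sizes = np.full((len(ids), n_markers, 2), MISSING, dtype=np.int32)
    for i, (_, row) in enumerate(plants.iterrows()):
        allele = cultivar_allele[row["true_cultivar"]]
        sizes[i, :, 0] = allele
        sizes[i, :, 1] = allele
    miss = rng.random((len(ids), n_markers)) < config.missing_rate
    sizes[miss] = MISSING
    return SSRGenotypeTable(
        plants=ids, markers=markers, sizes=sizes, marker_chrom=marker_chrom
    )


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth of a simulated experiment.

    ``plants``: plant_id, declared_cultivar, true_cultivar, off_type.
    ``true_calls``: dosages before noise.  ``stable_sets``: per-cultivar
    pinned heterozygous locus indices (into the shared locus list).
    """

    plants: pd.DataFrame
    true_calls: np.ndarray
    stable_sets: dict[str, np.ndarray]


@dataclass
class SimulatedExperiment:
    matrix: GenotypeMatrix
    sheet: SampleSheet
    ssr: SSRGenotypeTable
    truth: TruthTable
    config: SimulationConfig


def simulate_experiment(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedExperiment:
    """Run the full generator; optionally write VCF / TSV outputs.

    Re-running with an identical config produces byte-identical files.
    """
    config = config if config is not None else default_config()
    config.validate()
    master = np.random.SeedSequence(config.seed)
    panel = simulate_founders(config, master)

    populations: dict[str, Population] = {}
    for ci, cult in enumerate(config.cultivars):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(2, ci))
        )
        populations[cult.name] = simulate_cultivar_population(
            panel.genomes[cult.founder_a],
            panel.genomes[cult.founder_b],
            cult.selfing_generations,
            cult.n_plants,
            stable_het_loci=panel.stable_sets[cult.name],
            rng=rng,
            cultivar=cult.name,
        )

    cult_by_name = {c.name: c for c in config.cultivars}
    for oi, off in enumerate(config.off_types):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(3, oi))
        )
        donor_spec = cult_by_name[off.donor]
        donor_extra = simulate_cultivar_population(
            panel.genomes[donor_spec.founder_a],
            panel.genomes[donor_spec.founder_b],
            donor_spec.selfing_generations,
            max(off.count, 1),
            stable_het_loci=panel.stable_sets[donor_spec.name],
            rng=rng,
            cultivar=donor_spec.name,
        )
        populations[off.host] = inject_offtypes(
            populations[off.host], donor_extra, off.count, rng
        )

    ids: list[str] = []
    declared: list[str] = []
    true_cv: list[str] = []
    off_flags: list[bool] = []
    blocks: list[np.ndarray] = []
    for cult in config.cultivars:
        pop = populations[cult.name]
        ids.extend(pop.ids)
        declared.extend([cult.name] * len(pop.ids))
        true_cv.extend(pop.true_cultivar)
        off_flags.extend(pop.off_type.tolist())
        blocks.append(pop.calls)
    true_calls = np.vstack(blocks)

    rng_noise = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(4,))
    )
    noisy = apply_noise(true_calls, config.missing_rate, config.error_rate, rng_noise)

    matrix = GenotypeMatrix(plants=ids, loci=panel.loci, calls=noisy)
    sheet = SampleSheet(labels=dict(zip(ids, declared)))
    plants_df = pd.DataFrame(
        {
            "plant_id": ids,
            "declared_cultivar": declared,
            "true_cultivar": true_cv,
            "off_type": off_flags,
        }
    )
    ssr = simulate_ssr_panel(config, plants_df, seed=master)
    truth = TruthTable(
        plants=plants_df, true_calls=true_calls, stable_sets=panel.stable_sets
    )
    experiment = SimulatedExperiment(
        matrix=matrix, sheet=sheet, ssr=ssr, truth=truth, config=config
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(matrix, out / "genotypes.vcf")
        write_sample_sheet(sheet, out / "samples.tsv")
        write_ssr_table(ssr, out / "ssr.tsv")
        plants_df.to_csv(out / "truth_plants.tsv", sep="\t", index=False)
        stable_rows = []
        for cultivar in sorted(panel.stable_sets):
            for idx in panel.stable_sets[cultivar]:
                locus = panel.loci[int(idx)]
                stable_rows.append(
                    {
                        "cultivar": cultivar,
                        "locus_index": int(idx),
                        "chrom": locus.chrom,
                        "pos": locus.pos,
                    }
                )
        pd.DataFrame(stable_rows).to_csv(
            out / "truth_stable_het.tsv", sep="\t", index=False
        )
        (out / "config.json").write_text(config.to_json())
    return experiment
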