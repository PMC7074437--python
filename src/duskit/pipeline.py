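"""One-shot analysis pipeline: filter -> distance -> tree -> structure -> DUS
reports, with a reproducibility manifest.

The pipeline canonicalizes plant order (sorted IDs) immediately after
reading, so every downstream artifact — distance matrix, NJ tree, reports —
is invariant to the row order of the input VCF.  All report files are
written with fixed float formatting and sorted rows; the manifest (written
last) records input/output SHA-256 hashes and every threshold and seed, so a
run can be replayed and verified bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distance import snp_distance_matrix
from .dus_assessment import (
    classify_offtypes,
    cultivar_purity_table,
    distinctness_check,
    downsample_robustness,
    plant_purity,
    stable_het_loci,
)
from .filtering import filter_markers, gap_stats
from .markers_io import (
    FormatError,
    read_sample_sheet,
    read_vcf,
    write_vcf,
)
from .phylo import bootstrap_support, nj_tree
from .structure import kinship_matrix, pca_genotypes

logger = logging.getLogger(__name__)

#: Pipeline defaults; every value is recorded in the manifest.
DEFAULT_PARAMS: dict = {
    "maf_min": 0.05,
    "integrity_min": 0.8,
    "gap_threshold_bp": 150_000,
    "mad_k": 5.0,
    "ratio_alpha": 3.0,
    "min_within_callrate": 0.8,
    "pca_components": 3,
    "bootstrap_replicates": 0,
    "robustness_sizes": [10_000, 5_000, 1_000, 500],
    "robustness_replicates": 3,
    "seed": 17,
}


@dataclass
class RunManifest:
    version: str
    inputs: dict[str, str]
    params: dict
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "inputs": self.inputs,
                "params": self.params,
                "stages": self.stages,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(
    vcf_path: str | Path,
    sheet_path: str | Path,
    out_dir: str | Path,
    params: dict | None = None,
) -> RunManifest:
    """Execute the full analysis and write the report bundle.

    Raises a reconciliation error when the VCF and sample sheet disagree on
    the plant set, naming the orphans on each side.
    """
    t0 = time.monotonic()
    merged = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown pipeline parameter(s): {sorted(unknown)}")
        merged.update(params)
    params = merged

    vcf_path, sheet_path = Path(vcf_path), Path(sheet_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        inputs={vcf_path.name: _sha256(vcf_path), sheet_path.name: _sha256(sheet_path)},
        params=params,
    )

    def _stage(name: str, **counts) -> None:
        manifest.stages[name] = counts
        logger.info("[%s] %s (%.1fs)", name, counts, time.monotonic() - t0)

    matrix = read_vcf(vcf_path)
    sheet = read_sample_sheet(sheet_path)
    vcf_only = sorted(set(matrix.plants) - set(sheet.plants))
    sheet_only = sorted(set(sheet.plants) - set(matrix.plants))
    if vcf_only or sheet_only:
        raise FormatError(
            "plant sets of VCF and sample sheet differ; "
            f"only in VCF: {vcf_only}; only in sheet: {sheet_only}"
        )
    matrix = matrix.sorted_by_plant()
    _stage("read", plants=matrix.n_plants, loci=matrix.n_loci)

    filtered, filter_report = filter_markers(
        matrix, maf_min=params["maf_min"], integrity_min=params["integrity_min"]
    )
    _write_df(filter_report, out / "filter_report.tsv")
    write_vcf(filtered, out / "filtered.vcf")
    gaps = gap_stats(filtered.loci, threshold_bp=params["gap_threshold_bp"])
    _stage("filter", retained=filtered.n_loci, removed=matrix.n_loci - filtered.n_loci)

    dm = snp_distance_matrix(filtered)
    dm.to_tsv(out / "distance.tsv")
    _stage("distance", pairs=dm.n * (dm.n - 1) // 2)

    if params["bootstrap_replicates"] > 0:
        tree = bootstrap_support(
            filtered,
            replicates=params["bootstrap_replicates"],
            seed=np.random.SeedSequence(entropy=params["seed"], spawn_key=(10,)),
        )
    else:
        tree = nj_tree(dm)
    (out / "tree.nwk").write_text(tree.write_newick())
    patristic = tree.patristic()
    patristic.to_tsv(out / "patristic.tsv")
    _stage("tree", leaves=len(tree.leaf_labels))

    offtypes = classify_offtypes(
        patristic, sheet, mad_k=params["mad_k"], ratio_alpha=params["ratio_alpha"]
    )
    _write_df(offtypes.per_plant, out / "offtype_plants.tsv")
    _write_df(offtypes.per_cultivar, out / "offtype_cultivars.tsv")
    _stage("offtype", flagged=len(offtypes.flagged))

    dist_report = distinctness_check(tree, sheet, offtypes.flagged)
    _write_df(dist_report.to_frame(), out / "distinctness.tsv")
    _stage("distinctness", distinct=sum(dist_report.distinct.values()))

    purities = plant_purity(filtered)
    purity_plants = purities.rename("purity").reset_index()
    purity_plants["purity_pct"] = purity_plants["purity"] * 100.0
    _write_df(purity_plants[["plant_id", "purity_pct"]], out / "purity_plants.tsv")
    _write_df(cultivar_purity_table(purities, sheet), out / "purity_cultivars.tsv")
    _stage("purity", plants=len(purities))

    sharing = stable_het_loci(
        filtered, sheet, min_within_callrate=params["min_within_callrate"]
    )
    sharing.counts.rename_axis("cultivar").reset_index().pipe(
        _write_df, out / "het_share.tsv"
    )
    het_rows = [
        {
            "cultivar": cultivar,
            "chrom": filtered.loci[int(i)].chrom,
            "pos": filtered.loci[int(i)].pos,
        }
        for cultivar in sorted(sharing.sets)
        for i in sharing.sets[cultivar]
    ]
    _write_df(pd.DataFrame(het_rows, columns=["cultivar", "chrom", "pos"]),
              out / "het_share_loci.tsv")
    _stage("het_share", loci=sum(len(s) for s in sharing.sets.values()))

    pca = pca_genotypes(filtered, k=params["pca_components"])
    scores = pd.DataFrame(
        pca.scores, columns=[f"PC{i + 1}" for i in range(pca.k)]
    ).assign(plant_id=pca.ids)
    _write_df(scores[["plant_id"] + [f"PC{i + 1}" for i in range(pca.k)]],
              out / "pca_scores.tsv")
    _write_df(
        pd.DataFrame(
            {
                "component": np.arange(1, len(pca.variance_fractions) + 1),
                "variance_fraction": pca.variance_fractions,
            }
        ),
        out / "pca_variance.tsv",
    )
    kin = kinship_matrix(filtered)
    pd.DataFrame(kin.values, index=kin.ids, columns=kin.ids).rename_axis(
        "plant_id"
    ).reset_index().pipe(_write_df, out / "kinship.tsv")
    _stage("structure", components=pca.k)

    sizes = [s for s in params["robustness_sizes"] if s <= filtered.n_loci]
    dropped = [s for s in params["robustness_sizes"] if s > filtered.n_loci]
    if dropped:
        logger.warning("robustness sizes %s exceed %d loci; dropped", dropped,
                       filtered.n_loci)
    if sizes:
        robustness = downsample_robustness(
            filtered,
            sheet,
            sizes=sizes,
            replicates=params["robustness_replicates"],
            seed=params["seed"],
            mad_k=params["mad_k"],
            ratio_alpha=params["ratio_alpha"],
        )
        _write_df(robustness.to_frame(), out / "robustness.tsv")
        _stage("robustness", runs=len(robustness.rows))

    summary = {
        "n_plants": matrix.n_plants,
        "n_loci_input": matrix.n_loci,
        "n_loci_retained": filtered.n_loci,
        "mean_adjacent_gap_bp": gaps.mean_gap,
        "fraction_gaps_below_threshold": gaps.fraction_below,
        "pca_variance_pct_cumulative": [
            round(100.0 * pca.cumulative_variance(i), 2) for i in (1, 2, 3)
        ],
        "flagged_offtypes": sorted(offtypes.flagged),
        "distinct_cultivars": sorted(
            c for c, ok in dist_report.distinct.items() if ok
        ),
        "non_separated_pairs": [list(p) for p in dist_report.non_separated_pairs],
        "cultivar_purity_pct": {
            row["cultivar"]: round(row["purity_pct"], 2)
            for _, row in cultivar_purity_table(purities, sheet).iterrows()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest.outputs[path.name] = _sha256(path)
    (out / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline finished in %.1fs", time.monotonic() - t0)
    return manifest
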