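import numpy as np
import pandas as pd
import pytest

from duskit.distance import DistanceMatrix, snp_distance_matrix
from duskit.dus_assessment import (
    classify_offtypes,
    cultivar_purity_table,
    distinctness_check,
    downsample_robustness,
    plant_purity,
    stable_het_loci,
)
from duskit.markers_io import MISSING, GenotypeMatrix, SampleSheet
from duskit.phylo import nj_tree, read_newick

from conftest import random_matrix, toy_loci


def matrix(calls, plants=None):
    calls = np.asarray(calls)
    return GenotypeMatrix(
        plants=plants or [f"p{i}" for i in range(calls.shape[0])],
        loci=toy_loci(calls.shape[1]),
        calls=calls,
    )


class TestPurity:
    def test_all_homozygous(self):
        assert plant_purity(matrix([[0, 2, 0, 2]])).iloc[0] == 1.0

    def test_direct_ratio(self):
        p = plant_purity(matrix([[0] * 9 + [1]]))
        assert p.iloc[0] == pytest.approx(0.9)

    def test_missing_excluded(self):
        p = plant_purity(matrix([[0, 2, 0, 2, 1] + [MISSING] * 5]))
        assert p.iloc[0] == pytest.approx(0.8)

    def test_zero_called_plant_named(self):
        m = matrix([[0, 1], [MISSING, MISSING]], plants=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            plant_purity(m)

    def test_agrees_with_bruteforce(self):
        rng = np.random.default_rng(77)
        m = random_matrix(rng, 10, 50)
        p = plant_purity(m)
        for i, plant in enumerate(m.plants):
            called = [int(d) for d in m.calls[i] if d != MISSING]
            hom = sum(1 for d in called if d in (0, 2))
            assert p[plant] == pytest.approx(hom / len(called))


class TestCultivarPurityTable:
    def test_two_plant_summary(self):
        purities = pd.Series({"p1": 0.90, "p2": 0.94})
        sheet = SampleSheet(labels={"p1": "A", "p2": "A"})
        table = cultivar_purity_table(purities, sheet)
        row = table.iloc[0]
        assert row["purity_pct"] == pytest.approx(92.0)
        assert row["min_pct"] == pytest.approx(90.0)
        assert row["max_pct"] == pytest.approx(94.0)

    def test_single_plant_flagged_with_zero_std(self):
        table = cultivar_purity_table(
            pd.Series({"p1": 0.95}), SampleSheet(labels={"p1": "A"})
        )
        assert table.iloc[0]["std_pct"] == 0.0
        assert bool(table.iloc[0]["single_plant"])

    def test_identical_purities_zero_std(self):
        purities = pd.Series({"p1": 0.9, "p2": 0.9, "p3": 0.9})
        sheet = SampleSheet(labels={p: "A" for p in purities.index})
        assert cultivar_purity_table(purities, sheet).iloc[0][
            "std_pct"
        ] == pytest.approx(0.0)

    def test_mean_between_min_and_max(self):
        rng = np.random.default_rng(1)
        purities = pd.Series(rng.uniform(0.9, 1.0, 12),
                             index=[f"p{i}" for i in range(12)])
        sheet = SampleSheet(
            labels={f"p{i}": "AB"[i % 2] for i in range(12)}
        )
        for _, row in cultivar_purity_table(purities, sheet).iterrows():
            assert row["min_pct"] <= row["purity_pct"] <= row["max_pct"]


class TestStableHetLoci:
    def test_hand_constructed_sharing(self):
        # locus 0: het in all plants of A and B, hom in C
        # locus 1: het only in A; locus 2: hom everywhere
        calls = np.array(
            [
                [1, 1, 0],  # A
                [1, 1, 2],  # A
                [1, 0, 0],  # B -> locus1 not stable in B
                [1, 0, 0],  # B
                [0, 0, 2],  # C
                [2, 0, 0],  # C
            ]
        )
        sheet = SampleSheet(
            labels={f"p{i}": c for i, c in enumerate("AABBCC")}
        )
        sharing = stable_het_loci(matrix(calls), sheet)
        assert sharing.counts.loc["A", "A"] == 2
        assert sharing.counts.loc["B", "B"] == 1
        assert sharing.counts.loc["C", "C"] == 0
        assert sharing.counts.loc["A", "B"] == 1
        assert sharing.counts.loc["B", "A"] == 1

    def test_no_heterozygotes_anywhere(self):
        calls = np.array([[0, 2], [2, 0], [0, 0], [2, 2]])
        sheet = SampleSheet(labels={f"p{i}": "AB"[i % 2] for i in range(4)})
        sharing = stable_het_loci(matrix(calls), sheet)
        assert (sharing.counts.values == 0).all()

    def test_callrate_threshold(self):
        # locus het in the single called plant but call rate 1/3 < 0.8
        calls = np.array([[1], [MISSING], [MISSING]])
        sheet = SampleSheet(labels={f"p{i}": "A" for i in range(3)})
        sharing = stable_het_loci(matrix(calls), sheet, min_within_callrate=0.8)
        assert sharing.counts.loc["A", "A"] == 0
        loose = stable_het_loci(matrix(calls), sheet, min_within_callrate=0.3)
        assert loose.counts.loc["A", "A"] == 1

    def test_agrees_with_bruteforce_sets(self):
        rng = np.random.default_rng(55)
        m = random_matrix(rng, 15, 30, missing_rate=0.15)
        sheet = SampleSheet(
            labels={p: "ABC"[i // 5] for i, p in enumerate(m.plants)}
        )
        sharing = stable_het_loci(m, sheet, min_within_callrate=0.8)
        for cultivar in "ABC":
            rows = [i for i, p in enumerate(m.plants) if sheet[p] == cultivar]
            expected = []
            for j in range(m.n_loci):
                col = m.calls[rows, j]
                called = col[col != MISSING]
                if len(called) / len(rows) < 0.8:
                    continue
                if len(called) and (called == 1).all():
                    expected.append(j)
            assert sharing.sets[cultivar].tolist() == expected

    def test_offdiagonal_bounded_by_diagonals(self):
        rng = np.random.default_rng(56)
        m = random_matrix(rng, 12, 40, missing_rate=0.2)
        sheet = SampleSheet(
            labels={p: "ABCD"[i // 3] for i, p in enumerate(m.plants)}
        )
        counts = stable_het_loci(m, sheet).counts
        for a in counts.index:
            for b in counts.columns:
                assert counts.loc[a, b] <= min(counts.loc[a, a], counts.loc[b, b])


def star_patristic(r_values, ids):
    """Patristic matrix of a star tree with given pendant radii."""
    r = np.asarray(r_values, dtype=float)
    values = r[:, None] + r[None, :]
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids=list(ids), values=values)


class TestOffTypeClassification:
    def test_homogeneous_cluster_unflagged(self):
        ids = [f"p{i}" for i in range(10)]
        p = star_patristic([0.01] * 10, ids)
        sheet = SampleSheet(labels={i: "A" for i in ids})
        report = classify_offtypes(p, sheet)
        assert report.flagged == frozenset()

    def test_table_regime_offtype_flagged(self):
        # 19 plants at mutual ~0.02 and one at ~0.13 mean distance
        ids = [f"p{i:02d}" for i in range(20)]
        p = star_patristic([0.01] * 19 + [0.12], ids)
        sheet = SampleSheet(labels={i: "A" for i in ids})
        report = classify_offtypes(p, sheet)
        assert report.flagged == frozenset({"p19"})
        # Table stats exclude the flagged plant
        row = report.per_cultivar.iloc[0]
        assert row["average"] == pytest.approx(0.02)
        assert row["n_flagged"] == 1

    def test_scale_invariance(self):
        ids = [f"p{i:02d}" for i in range(20)]
        sheet = SampleSheet(labels={i: "A" for i in ids})
        p = star_patristic([0.01] * 19 + [0.12], ids)
        scaled = DistanceMatrix(ids=ids, values=p.values * 37.0)
        assert (
            classify_offtypes(p, sheet).flagged
            == classify_offtypes(scaled, sheet).flagged
        )

    def test_plant_order_invariance(self):
        rng = np.random.default_rng(3)
        ids = [f"p{i:02d}" for i in range(12)]
        sheet = SampleSheet(labels={i: "A" for i in ids})
        radii = np.concatenate([rng.uniform(0.008, 0.012, 11), [0.2]])
        p = star_patristic(radii, ids)
        perm = list(rng.permutation(ids))
        assert (
            classify_offtypes(p, sheet).flagged
            == classify_offtypes(p.reorder(perm), sheet).flagged
        )

    def test_small_cultivar_skipped_with_warning(self):
        p = star_patristic([0.01, 0.5], ["p1", "p2"])
        sheet = SampleSheet(labels={"p1": "A", "p2": "A"})
        with pytest.warns(UserWarning):
            report = classify_offtypes(p, sheet)
        assert report.flagged == frozenset()

    def test_simulated_contaminant_flagged(self, small_experiment):
        exp = small_experiment
        tree = nj_tree(snp_distance_matrix(exp.matrix.sorted_by_plant()))
        report = classify_offtypes(tree.patristic(), exp.sheet)
        truth = frozenset(
            exp.truth.plants.loc[exp.truth.plants.off_type, "plant_id"]
        )
        assert report.flagged == truth


class TestDistinctness:
    def test_two_clean_clusters(self):
        tree = read_newick("((a1:0.1,a2:0.1):1,(b1:0.1,b2:0.1):1);")
        sheet = SampleSheet(
            labels={"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        report = distinctness_check(tree, sheet)
        assert report.distinct == {"A": True, "B": True}
        assert report.non_separated_pairs == []

    def test_interleaved_cultivars_not_separated(self):
        tree = read_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        sheet = SampleSheet(
            labels={"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        report = distinctness_check(tree, sheet)
        assert report.distinct == {"A": False, "B": False}
        assert report.non_separated_pairs == [("A", "B")]

    def test_flagged_offtype_excluded_from_host_and_neighbor(self):
        # contaminant x sits inside B's clade but is declared A
        tree = read_newick(
            "((a1:1,a2:1):1,((b1:1,(b2:1,x:1):1):1,(c1:1,c2:1):1):1);"
        )
        sheet = SampleSheet(
            labels={"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                    "c1": "C", "c2": "C", "x": "A"}
        )
        naive = distinctness_check(tree, sheet)
        assert not naive.distinct["A"] and not naive.distinct["B"]
        excl = distinctness_check(tree, sheet, flagged={"x"})
        assert excl.distinct == {"A": True, "B": True, "C": True}
        assert excl.non_separated_pairs == []

    def test_identical_cross_pair_non_separated(self, small_experiment):
        exp = small_experiment
        tree = nj_tree(snp_distance_matrix(exp.matrix.sorted_by_plant()))
        off = classify_offtypes(tree.patristic(), exp.sheet)
        report = distinctness_check(tree, exp.sheet, off.flagged)
        assert report.non_separated_pairs == [("cv1", "cv2")]
        for cultivar in ("cv3", "cv4", "cv5"):
            assert report.distinct[cultivar]


class TestDownsampleRobustness:
    def test_identity_subset_matches_full_analysis(self, small_experiment):
        exp = small_experiment
        m = exp.matrix.sorted_by_plant()
        report = downsample_robustness(
            m, exp.sheet, sizes=[m.n_loci], replicates=1, seed=0
        )
        tree = nj_tree(snp_distance_matrix(m))
        off = classify_offtypes(tree.patristic(), exp.sheet)
        full = distinctness_check(tree, exp.sheet, off.flagged)
        row = report.rows[0]
        assert row["distinct"] == full.distinct
        assert row["non_separated_pairs"] == full.non_separated_pairs
        assert row["flagged"] == sorted(off.flagged)

    def test_deterministic_replay(self, small_experiment):
        exp = small_experiment
        m = exp.matrix.sorted_by_plant()
        a = downsample_robustness(m, exp.sheet, sizes=[500], replicates=2, seed=9)
        b = downsample_robustness(m, exp.sheet, sizes=[500], replicates=2, seed=9)
        assert a.to_frame().equals(b.to_frame())

    def test_oversized_subset_rejected(self, small_experiment):
        exp = small_experiment
        with pytest.raises(ValueError):
            downsample_robustness(
                exp.matrix, exp.sheet, sizes=[exp.matrix.n_loci + 1], seed=0
            )
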