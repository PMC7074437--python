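import hashlib
from pathlib import Path

import numpy as np
import pytest

from duskit.simulate import (
    ConfigError,
    CultivarSpec,
    FounderSpec,
    SimulationConfig,
    apply_noise,
    default_config,
    inject_offtypes,
    simulate_cultivar_population,
    simulate_experiment,
    simulate_founders,
    simulate_ssr_panel,
)


def two_founder_config(divergence, n_loci=10_000):
    return SimulationConfig(
        n_loci=n_loci,
        founders=[
            FounderSpec("f1", divergence=0.5),
            FounderSpec("f2", anchor="f1", divergence=divergence),
        ],
        cultivars=[CultivarSpec("c1", "f1", "f2", n_stable_het=0)],
        stable_het_pool=0,
        off_types=[],
        seed=3,
    )


class TestFounders:
    def test_zero_divergence_identical(self):
        panel = simulate_founders(two_founder_config(0.0))
        assert np.array_equal(panel.genomes["f1"], panel.genomes["f2"])

    def test_full_divergence_opposite(self):
        panel = simulate_founders(two_founder_config(1.0))
        assert (panel.genomes["f1"] != panel.genomes["f2"]).all()

    def test_divergence_within_binomial_error(self):
        q, n = 0.3, 10_000
        panel = simulate_founders(two_founder_config(q, n_loci=n))
        observed = (panel.genomes["f1"] != panel.genomes["f2"]).mean()
        assert abs(observed - q) <= 3 * np.sqrt(q * (1 - q) / n)

    def test_loci_sorted_and_unique(self):
        panel = simulate_founders(two_founder_config(0.2, n_loci=2_000))
        keys = [(l.chrom, l.pos) for l in panel.loci]
        assert len(set(keys)) == len(keys)
        assert keys == sorted(keys, key=lambda k: (k[0], k[1]))

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ConfigError):
            simulate_founders(two_founder_config(1.5))

    def test_unknown_anchor_rejected(self):
        config = two_founder_config(0.1)
        config.founders[1] = FounderSpec("f2", anchor="ghost", divergence=0.1)
        with pytest.raises(ConfigError):
            simulate_founders(config)


class TestSelfingPopulation:
    @staticmethod
    def founders(n_loci):
        return np.zeros(n_loci, dtype=np.uint8), np.ones(n_loci, dtype=np.uint8)

    def test_f1_fully_heterozygous(self):
        fa, fb = self.founders(100)
        pop = simulate_cultivar_population(
            fa, fb, 0, 5, None, np.random.default_rng(0), "c"
        )
        assert (pop.calls == 1).all()

    def test_deep_selfing_reaches_fixation(self):
        fa, fb = self.founders(500)
        pop = simulate_cultivar_population(
            fa, fb, 30, 5, None, np.random.default_rng(1), "c"
        )
        assert (pop.calls == 1).mean() < 0.01

    @pytest.mark.parametrize("g", [2, 4, 6])
    def test_heterozygosity_decay_halves_per_generation(self, g):
        fa, fb = self.founders(20_000)
        pop = simulate_cultivar_population(
            fa, fb, g, 50, None, np.random.default_rng(10 + g), "c"
        )
        het = (pop.calls == 1).mean(axis=1)
        se = het.std(ddof=1) / np.sqrt(len(het))
        assert abs(het.mean() - 0.5**g) <= 3 * se

    def test_pinned_loci_stay_heterozygous(self):
        fa, fb = self.founders(200)
        pinned = np.array([3, 50, 199])
        pop = simulate_cultivar_population(
            fa, fb, 20, 8, pinned, np.random.default_rng(2), "c"
        )
        assert (pop.calls[:, pinned] == 1).all()

    def test_pinned_must_be_segregating(self):
        fa = np.zeros(50, dtype=np.uint8)
        fb = fa.copy()
        fb[:25] = 1  # only first 25 loci differ
        with pytest.raises(ConfigError):
            simulate_cultivar_population(
                fa, fb, 4, 3, np.array([40]), np.random.default_rng(0), "c"
            )


class TestOffTypes:
    @staticmethod
    def pops():
        fa = np.zeros(100, dtype=np.uint8)
        fb = np.ones(100, dtype=np.uint8)
        host = simulate_cultivar_population(
            fa, fa.copy(), 6, 10, None, np.random.default_rng(1), "host"
        )
        donor = simulate_cultivar_population(
            fb, fb.copy(), 6, 5, None, np.random.default_rng(2), "donor"
        )
        return host, donor

    def test_zero_injection_is_identity(self):
        host, donor = self.pops()
        out = inject_offtypes(host, donor, 0, np.random.default_rng(0))
        assert out is host

    def test_injection_recorded_in_truth(self):
        host, donor = self.pops()
        out = inject_offtypes(host, donor, 2, np.random.default_rng(3))
        assert out.off_type.sum() == 2
        for i in np.flatnonzero(out.off_type):
            assert out.true_cultivar[i] == "donor"
            assert (out.calls[i] == 2).all()  # donor genome is all-alt
        assert out.ids == host.ids  # labels keep the host positions

    def test_full_replacement_rejected(self):
        host, donor = self.pops()
        with pytest.raises(ConfigError):
            inject_offtypes(host, donor, len(host.ids), np.random.default_rng(0))

    def test_self_donation_rejected(self):
        host, _ = self.pops()
        with pytest.raises(ConfigError):
            inject_offtypes(host, host, 1, np.random.default_rng(0))


class TestNoise:
    def test_zero_rates_identity(self):
        calls = np.array([[0, 1, 2], [2, 1, 0]], dtype=np.int8)
        out = apply_noise(calls, 0.0, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, calls)

    def test_all_missing(self):
        calls = np.ones((4, 10), dtype=np.int8)
        out = apply_noise(calls, 1.0, 0.0, np.random.default_rng(0))
        assert (out == -1).all()

    def test_missing_rate_within_binomial_error(self):
        rng = np.random.default_rng(8)
        calls = np.zeros((100, 1000), dtype=np.int8)
        out = apply_noise(calls, 0.1, 0.0, rng)
        frac = (out == -1).mean()
        assert abs(frac - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / calls.size)

    def test_error_modes(self):
        rng = np.random.default_rng(9)
        hom = np.zeros((50, 100), dtype=np.int8)
        noisy = apply_noise(hom, 0.0, 1.0, rng)
        assert (noisy == 1).all()  # hom errors become het
        het = np.ones((50, 100), dtype=np.int8)
        noisy = apply_noise(het, 0.0, 1.0, rng)
        assert set(np.unique(noisy)) == {0, 2}  # het errors become random hom


class TestSsrPanel:
    def test_marker_per_chromosome(self, small_experiment):
        ssr = small_experiment.ssr
        chroms = set(ssr.marker_chrom.values())
        assert len(chroms) == small_experiment.config.n_chromosomes

    def test_too_few_markers_rejected(self):
        config = default_config()
        with pytest.raises(ConfigError):
            simulate_ssr_panel(config, plants=None, n_markers=5)

    def test_single_cultivar_zero_distances(self):
        from duskit.distance import ssr_distance_matrix

        config = two_founder_config(0.3, n_loci=1000)
        config.missing_rate = 0.0
        config.cultivars[0].n_plants = 6
        exp = simulate_experiment(config)
        d = ssr_distance_matrix(exp.ssr)
        assert d.values.max() == 0.0


class TestExperiment:
    def test_default_design_shape(self, default_experiment):
        exp = default_experiment
        assert exp.matrix.n_plants == 100
        assert len(exp.sheet) == 100
        assert exp.truth.plants.off_type.sum() == 2
        assert len({exp.sheet[p] for p in exp.matrix.plants}) == 5

    def test_byte_identical_reruns(self, tmp_path):
        config = default_config(seed=4)
        config.n_loci = 1_000
        hashes = []
        for run in ("a", "b"):
            out = tmp_path / run
            simulate_experiment(config, out_dir=out)
            digest = {
                f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                for f in sorted(Path(out).iterdir())
            }
            hashes.append(digest)
        assert hashes[0] == hashes[1]

    def test_truth_consistent_with_matrix(self, small_experiment):
        exp = small_experiment
        assert exp.truth.true_calls.shape == exp.matrix.calls.shape
        assert list(exp.truth.plants.plant_id) == exp.matrix.plants
        # noise-free entries agree with the truth wherever calls survived
        called = exp.matrix.calls != -1
        mismatch = (exp.matrix.calls != exp.truth.true_calls) & called
        assert mismatch.mean() < 3 * exp.config.error_rate

    def test_config_json_round_trip(self):
        config = default_config(seed=11)
        clone = SimulationConfig.from_json(config.to_json())
        assert clone == config

    def test_stable_sets_recovered_exactly_without_noise(self):
        from duskit.dus_assessment import stable_het_loci

        config = default_config(seed=5)
        config.n_loci = 3_000
        config.missing_rate = 0.0
        config.error_rate = 0.0
        config.off_types = []
        exp = simulate_experiment(config)
        sharing = stable_het_loci(exp.matrix, exp.sheet)
        for cultivar, expected in exp.truth.stable_sets.items():
            assert sharing.sets[cultivar].tolist() == sorted(expected.tolist())
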