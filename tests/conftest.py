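import numpy as np
import pytest

from duskit.markers_io import GenotypeMatrix, Locus


def toy_loci(n, chrom="Gm01", spacing=100):
    return [Locus(chrom, (i + 1) * spacing, "A", "G") for i in range(n)]


def random_matrix(rng, n_plants, n_loci, missing_rate=0.1):
    """Random dosage matrix with missingness, for oracle comparisons."""
    calls = rng.integers(0, 3, size=(n_plants, n_loci)).astype(np.int8)
    calls[rng.random((n_plants, n_loci)) < missing_rate] = -1
    return GenotypeMatrix(
        plants=[f"p{i:02d}" for i in range(n_plants)],
        loci=toy_loci(n_loci),
        calls=calls,
    )


def random_additive_newick(rng, n_leaves, min_len=0.01, max_len=1.0):
    """Random unrooted binary tree topology with uniform branch lengths."""

    def length():
        return rng.uniform(min_len, max_len)

    reprs = {f"t{i}": f"t{i}" for i in range(n_leaves)}
    active = [f"t{i}" for i in range(n_leaves)]
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        reprs[a] = f"({reprs[a]}:{length():.6f},{reprs[b]}:{length():.6f})"
        active.remove(b)
    parts = ",".join(f"{reprs[a]}:{length():.6f}" for a in active)
    if len(active) == 2:  # n_leaves == 2
        return f"({parts});"
    return f"({parts});"


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced five-cultivar panel (fast): same design, fewer loci."""
    from duskit.simulate import default_config, simulate_experiment

    config = default_config(seed=7)
    config.n_loci = 4_000
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def default_experiment():
    """The full bundled study design at seed 1."""
    from duskit.simulate import default_config, simulate_experiment

    return simulate_experiment(default_config(seed=1))
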