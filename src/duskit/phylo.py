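"""Neighbor-joining trees, bootstrap support, Newick I/O, patristic distances.

The tree builder is the classical Saitou–Nei agglomeration: at each step the
pair minimizing the Q-criterion

    Q(i, j) = (n - 2) d(i, j) - r_i - r_j,      r_i = sum_k d(i, k)

is joined, with pendant lengths from the standard formulas.  Ties on Q are
broken by the lexicographically smallest pair of cluster labels (the label of
a cluster is the smallest plant ID it contains), which makes the tree a pure
function of the distance matrix — independent of input row order and
platform.  Negative branch lengths are clamped to zero with the deficit moved
to the sibling edge, keeping the joined pair's path length intact.

Trees are unrooted; the trifurcation at the internal "seed" node is a
representation artifact and patristic distances and bipartitions do not
depend on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import dendropy
import numpy as np

from .distance import DistanceMatrix
from .markers_io import GenotypeMatrix

logger = logging.getLogger(__name__)


class NewickParseError(ValueError):
    """Malformed Newick input."""


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and optional bootstrap supports."""

    tree: dendropy.Tree

    # -- basic structure ---------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace)

    def _edges(self) -> Iterator[tuple[float, frozenset, dendropy.Node]]:
        """Yield (length, leaf-set below, node) for every real edge."""
        leafsets: dict[int, frozenset] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                leafsets[id(node)] = frozenset([node.taxon.label])
            else:
                acc: set = set()
                for child in node.child_nodes():
                    acc |= leafsets[id(child)]
                leafsets[id(node)] = frozenset(acc)
            if node is not self.tree.seed_node:
                length = node.edge.length if node.edge.length is not None else 0.0
                yield float(length), leafsets[id(node)], node

    def bipartition_sides(self) -> list[frozenset]:
        """Leaf sets under every edge (pendant edges included)."""
        return [side for _, side, _ in self._edges()]

    def internal_bipartitions(self) -> set[frozenset]:
        """Canonicalized non-trivial splits: the side not holding the smallest leaf."""
        labels = set(self.leaf_labels)
        ref = min(labels)
        out: set[frozenset] = set()
        for _, side, _ in self._edges():
            if len(side) < 2 or len(side) > len(labels) - 2:
                continue
            out.add(frozenset(labels - side) if ref in side else side)
        return out

    @property
    def supports(self) -> dict[frozenset, float]:
        """Bootstrap support (percent) per canonical internal bipartition."""
        labels = set(self.leaf_labels)
        ref = min(labels)
        out: dict[frozenset, float] = {}
        for _, side, node in self._edges():
            if len(side) < 2 or len(side) > len(labels) - 2:
                continue
            if node.label is None:
                continue
            try:
                value = float(node.label)
            except ValueError:
                continue
            key = frozenset(labels - side) if ref in side else side
            out[key] = value
        return out

    # -- patristic distances ----------------------------------------------
    def patristic(self) -> DistanceMatrix:
        """Path-length distances between all leaf pairs (sorted-ID order).

        d(i, j) sums the lengths of edges whose induced bipartition separates
        i from j; this is exactly the unique leaf-to-leaf path length.
        """
        ids = self.leaf_labels
        index = {label: k for k, label in enumerate(ids)}
        n = len(ids)
        edges = list(self._edges())
        if not edges and n > 1:
            raise ValueError("tree has no edges")
        b = np.zeros((len(edges), n), dtype=np.float64)
        w = np.zeros(len(edges))
        for e, (length, side, _) in enumerate(edges):
            w[e] = length
            for label in side:
                b[e, index[label]] = 1.0
        c = b.T @ (b * w[:, None])
        u = np.diag(c)
        values = u[:, None] + u[None, :] - 2.0 * c
        np.fill_diagonal(values, 0.0)
        values = np.maximum(values, 0.0)
        values = (values + values.T) / 2.0
        return DistanceMatrix(ids=ids, values=values)

    # -- Newick ------------------------------------------------------------
    def write_newick(self) -> str:
        text = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        )
        return text.strip() + "\n"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string; internal node labels are kept (as supports)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def write_newick(tree: PhyloTree) -> str:
    return tree.write_newick()


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _check_defined(D: DistanceMatrix) -> None:
    if np.isnan(D.values).any():
        raise ValueError("distance matrix contains undefined entries")


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a full distance matrix.

    Deterministic given D: Q-ties are broken by the smallest (sorted) pair of
    cluster labels.  For n == 2 the two leaves are connected by a single path
    of total length d12; for n == 3 the closed-form star is returned.
    """
    _check_defined(D)
    n = D.n
    if n < 2:
        raise ValueError("need at least two taxa")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in D.ids:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=label)
        nodes.append(node)
    labels = list(D.ids)  # canonical label = smallest leaf ID in the cluster
    d = D.values.astype(np.float64).copy()

    clamped = 0

    def _join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        nonlocal clamped
        if li < 0.0:
            lj = lj + li  # move deficit to sibling, keep li + lj fixed
            li = 0.0
            clamped += 1
        if lj < 0.0:
            li = li + lj
            lj = 0.0
            clamped += 1
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        return parent

    while len(labels) > 3:
        m = len(labels)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = np.argwhere(q == qmin)
        i, j = min(
            (tuple(sorted((labels[a], labels[b]))), (min(a, b), max(a, b)))
            for a, b in cands
        )[1]
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = _join(i, j, li, lj)
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        # replace cluster i with the merged cluster, drop j
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        keep = [k for k in range(m) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes = [nodes[k] for k in keep]
        labels = [labels[k] for k in keep]

    tree = dendropy.Tree(taxon_namespace=tns)
    if len(labels) == 2:
        d12 = d[0, 1]
        for k, length in ((0, d12 / 2.0), (1, d12 / 2.0)):
            tree.seed_node.add_child(nodes[k])
            nodes[k].edge.length = length
    else:
        # three-cluster closed form
        pend = [
            0.5 * (d[0, 1] + d[0, 2] - d[1, 2]),
            0.5 * (d[0, 1] + d[1, 2] - d[0, 2]),
            0.5 * (d[0, 2] + d[1, 2] - d[0, 1]),
        ]
        for k, length in enumerate(pend):
            if length < 0.0:
                clamped += 1
                length = 0.0
            tree.seed_node.add_child(nodes[k])
            nodes[k].edge.length = length
    if clamped:
        logger.info("clamped %d negative branch length(s) to zero", clamped)
    tree.is_rooted = False
    return PhyloTree(tree=tree)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    matrix: GenotypeMatrix,
    replicates: int = 500,
    seed: int | np.random.SeedSequence | None = None,
) -> PhyloTree:
    """NJ tree of the full data with locus-bootstrap supports on internal edges.

    Loci (columns) are resampled with replacement; each internal edge of the
    full-data tree is annotated with the percentage of replicate trees
    containing the same leaf bipartition.  Deterministic given the seed.
    """
    from .distance import distance_from_calls, snp_distance_matrix

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if matrix.n_plants < 3:
        raise ValueError("bootstrap requires at least three plants")

    full = nj_tree(snp_distance_matrix(matrix))
    target = full.internal_bipartitions()
    counts = {key: 0 for key in target}

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(replicates)
    n_loci = matrix.n_loci
    for child in children:
        rng = np.random.default_rng(child)
        cols = rng.integers(0, n_loci, size=n_loci)
        sub = distance_from_calls(
            matrix.calls[:, cols], matrix.plants, allow_missing_pairs=True
        )
        rep = nj_tree(sub)
        found = rep.internal_bipartitions()
        for key in counts:
            if key in found:
                counts[key] += 1

    labels = set(full.leaf_labels)
    ref = min(labels)
    for _, side, node in full._edges():
        if len(side) < 2 or len(side) > len(labels) - 2:
            continue
        key = frozenset(labels - side) if ref in side else side
        support = 100.0 * counts.get(key, 0) / replicates
        node.label = f"{support:g}"
    return full


def patristic(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-pairwise path-length distances (functional alias)."""
    return tree.patristic()
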