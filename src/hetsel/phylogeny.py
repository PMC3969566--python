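"""Distance computation, neighbor joining and bootstrap support.

The tree over the allele set is built with the Saitou–Nei neighbor-joining
algorithm from pairwise nucleotide distances (p-distance, JC69 or K2P) and
decorated with bootstrap supports from column resampling.  Branch lengths
are in substitutions per site; the occasional negative NJ length is
clamped to zero.  Trees are held as unrooted :mod:`dendropy` trees behind
a thin :class:`PhyloTree` wrapper.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_annotation import AlleleSet

log = logging.getLogger(__name__)

DISTANCE_MODELS = ("p", "jc69", "k2p")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with its substitution-model tag."""

    names: tuple[str, ...]
    values: np.ndarray
    model: str = "k2p"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match the number of names")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("distances must be finite and nonnegative")


def _pair_distance(a: str, b: str, model: str) -> float:
    n = len(a)
    mismatches = transitions = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if frozenset((x, y)) in ({"A", "G"}, {"C", "T"}):
                transitions += 1
    p = mismatches / n
    if model == "p":
        return p
    if model == "jc69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise ValueError(f"JC69 distance undefined for this pair (p={p:.3f})")
        return -0.75 * math.log(arg)
    if model == "k2p":
        P = transitions / n
        Q = (mismatches - transitions) / n
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            raise ValueError(f"K2P distance undefined for this pair (P={P:.3f}, Q={Q:.3f})")
        return -0.5 * math.log(a1) - 0.25 * math.log(a2)
    raise ValueError(f"unknown distance model {model!r}; choose from {DISTANCE_MODELS}")


def distance_matrix(alleles: AlleleSet, model: str = "k2p") -> DistanceMatrix:
    """All pairwise distances between the aligned alleles under one model."""
    n = len(alleles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = _pair_distance(
                    alleles.sequences[i], alleles.sequences[j], model
                )
            except ValueError as err:
                raise ValueError(
                    f"{err} [pair {alleles.names[i]!r} vs {alleles.names[j]!r}]"
                ) from None
    return DistanceMatrix(names=alleles.names, values=d, model=model)


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths (substitutions/site) and optional
    per-internal-edge bootstrap supports in percent."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def newick(self, min_support: float | None = None) -> str:
        """Newick string; internal-node labels carry integer percent supports.

        ``min_support`` suppresses labels below a threshold, the convention
        used for figure-style reporting (e.g. only supports above 95).
        """
        all_leaves = frozenset(self.leaf_names)
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            key = _canonical_split(_clade_key(node), all_leaves)
            if key in self.supports:
                s = self.supports[key]
                node.label = (
                    str(int(round(s)))
                    if (min_support is None or s >= min_support)
                    else None
                )
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(source: str) -> PhyloTree:
    """Parse a newick string (or ``path=``-style file contents) into a PhyloTree."""
    tree = dendropy.Tree.get(data=source, schema="newick")
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def _clade_key(node: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Name an unrooted bipartition by its canonical (smaller/sorted) side."""
    return min(side, all_leaves - side, key=lambda s: (len(s), tuple(sorted(s))))


def nj_tree(dm: DistanceMatrix, *, quiet: bool = False) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    At each step the pair minimizing ``Q(i,j) = (n-2) d(i,j) - R_i - R_j``
    is joined; ties break on the lowest (row, column) index pair so the
    result is reproducible.  Negative branch lengths are clamped to zero
    with a warning.
    """
    n = len(dm.names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(list(dm.names))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in dm.names:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)

    d = dm.values.astype(float).copy()
    active = list(range(n))
    clamped: list[float] = []

    def clamp(x: float) -> float:
        if x < 0:
            clamped.append(x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        vi = 0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))
        vj = sub[a, b] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(vi)
        nodes[j].edge.length = clamp(vj)

        # distances from the new cluster to every remaining one
        new_index = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            duc = 0.5 * (d[i, c] + d[j, c] - d[i, j])
            d[new_index, c] = d[c, new_index] = duc
        nodes.append(parent)
        active = [c for c in active if c not in (i, j)] + [new_index]

    i, j, k = active
    center = dendropy.Node()
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(v)
    tree.seed_node = center
    tree.is_rooted = False
    if clamped and not quiet:
        log.warning(
            "%d negative NJ branch length(s) clamped to 0 (most negative %.4g)",
            len(clamped), min(clamped),
        )
    return PhyloTree(tree=tree)


def _nontrivial_clades(pt: PhyloTree) -> set[frozenset]:
    """Unrooted bipartitions, each named by the smaller/canonical leaf side."""
    all_leaves = frozenset(pt.leaf_names)
    clades = set()
    for node in pt.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = _clade_key(node)
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue  # trivial split
        clades.add(_canonical_split(side, all_leaves))
    return clades


def bootstrap_support(
    alleles: AlleleSet,
    replicates: int = 1000,
    seed: int = 0,
    model: str = "k2p",
) -> PhyloTree:
    """NJ point-estimate tree with column-resampling bootstrap supports.

    Alignment columns are resampled with replacement; each internal edge's
    support is the percentage of replicate NJ trees containing the same
    bipartition.  Deterministic for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    point = nj_tree(distance_matrix(alleles, model))
    targets = _nontrivial_clades(point)
    counts = {c: 0 for c in targets}

    rng = np.random.default_rng(seed)
    length = alleles.length
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = AlleleSet(
            names=alleles.names,
            sequences=tuple("".join(s[c] for c in cols) for s in alleles.sequences),
        )
        try:
            rep = nj_tree(distance_matrix(resampled, model), quiet=True)
        except ValueError:
            continue  # distance undefined on this resample; replicate contributes 0
        found = _nontrivial_clades(rep)
        for c in targets & found:
            counts[c] += 1

    all_leaves = frozenset(point.leaf_names)
    for node in point.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = _clade_key(node)
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        canon = _canonical_split(side, all_leaves)
        point.supports[canon] = 100.0 * counts[canon] / replicates
    return point
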