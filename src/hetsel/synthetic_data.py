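"""Seeded generators for every input the pipeline consumes.

The analysis is exercised end to end on data with known ground truth:
codon alignments evolved along a tree under a site-class omega mixture
(with the true per-site class labels retained), incompatibility matrices
obeying declared implication hierarchies, and multinomial population
samples.  One global seed fans out into named substreams, so adding a new
generator never perturbs the draws of an existing one.

The default simulation regime mirrors the het-c study scale — about a
dozen alleles and ~200 codons with an elevated nonsynonymous rate — and
is used for the "het-c-like" scenario in the test-suite; larger regimes
(more taxa, more codons) are used where parameter recovery needs more
information.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codon_selection import (
    CodonModelSpec,
    _eig_factors,
    _generator_unscaled,
)
from .genetics import N_SENSE, SENSE_CODONS
from .io_annotation import CodonAlignment
from .phylogeny import PhyloTree
from .specificity import IncompatibilityMatrix


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# trees


def random_yule_tree(
    n_taxa: int,
    seed: int = 0,
    *,
    height: float = 0.5,
    names: tuple[str, ...] | None = None,
) -> PhyloTree:
    """Ultrametric pure-birth tree rescaled to the given root-to-tip height
    (in expected substitutions per codon site)."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = substream(seed, "yule-tree")
    if names is None:
        names = tuple(f"t{i + 1}" for i in range(n_taxa))
    taxa = dendropy.TaxonNamespace(list(names))
    tree = dendropy.Tree(taxon_namespace=taxa)

    root = tree.seed_node
    first, second = dendropy.Node(), dendropy.Node()
    root.add_child(first)
    root.add_child(second)
    active = [first, second]
    depth = {id(first): 0.0, id(second): 0.0}
    birth = {id(first): 0.0, id(second): 0.0}
    now = 0.0
    while len(active) < n_taxa:
        now += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        parent.edge.length = now - birth[id(parent)]
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth[id(child)] = now
            active.append(child)
    now += rng.exponential(1.0 / len(active))
    order = rng.permutation(len(active))
    for label_i, node_i in enumerate(order):
        node = active[node_i]
        node.edge.length = now - birth[id(node)]
        node.taxon = taxa.get_taxon(names[label_i])
    # rescale to the requested height
    factor = height / now
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    tree.is_rooted = False
    return PhyloTree(tree=tree)


# ---------------------------------------------------------------------------
# codon alignments


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to evolve one codon alignment."""

    spec: CodonModelSpec
    n_codons: int
    seed: int
    tree: PhyloTree | None = None  # random Yule tree when omitted
    n_taxa: int = 11
    tree_height: float = 0.5


def simulate_codon_alignment(cfg: SimulationConfig) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment site by site under a site-class mixture.

    Each site draws its omega class from the mixture, its root codon from
    the equilibrium distribution, and then evolves down the tree with the
    class's transition matrices.  Returns the leaf alignment and the true
    class label per site.  Identical seeds give identical output.
    """
    spec = cfg.spec
    tree = cfg.tree if cfg.tree is not None else random_yule_tree(
        cfg.n_taxa, cfg.seed, height=cfg.tree_height
    )
    rng = substream(cfg.seed, "codon-alignment")
    pi = spec.frequencies
    props = np.asarray(spec.proportions)
    h = cfg.n_codons

    labels = rng.choice(len(props), size=h, p=props)
    states = {id(tree.tree.seed_node): rng.choice(N_SENSE, size=h, p=pi)}

    # mixture-level scaling, exactly as the fitting engine defines time
    pairs = [_generator_unscaled(pi, spec.kappa, w) for w in spec.omegas]
    scale = float(np.dot(props, [r for _, r in pairs]))
    eigs = [_eig_factors(q / scale, pi) for q, _ in pairs]

    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = float(node.edge.length or 0.0)
        parent_states = states[id(node.parent_node)]
        child_states = np.empty(h, dtype=np.intp)
        for k in range(len(props)):
            sites = np.where(labels == k)[0]
            if sites.size == 0:
                continue
            a, b, w = eigs[k]
            p = (a * np.exp(w * t)) @ b
            np.clip(p, 0.0, None, out=p)
            p /= p.sum(axis=1, keepdims=True)
            rows = p[parent_states[sites]]
            u = rng.random(sites.size)
            child_states[sites] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        states[id(node)] = child_states

    names, rows = [], []
    for leaf in tree.tree.leaf_node_iter():
        names.append(leaf.taxon.label)
        rows.append("".join(SENSE_CODONS[s] for s in states[id(leaf)]))
    ca = CodonAlignment(names=tuple(names), rows=tuple(rows))
    return ca, labels


def hetc_like_scenario(seed: int = 0) -> tuple[CodonAlignment, np.ndarray, PhyloTree]:
    """Default synthetic regime at the het-c study scale: 11 alleles,
    ~200 codons, a conserved majority plus a positively selected minority
    of sites."""
    spec = CodonModelSpec.m2(p0=0.6, p1=0.25, omega0=0.1, omega2=3.0, kappa=2.0)
    tree = random_yule_tree(11, seed, height=0.3,
                            names=tuple(f"het-c{i + 1}" for i in range(11)))
    cfg = SimulationConfig(spec=spec, n_codons=208, seed=seed, tree=tree)
    ca, labels = simulate_codon_alignment(cfg)
    return ca, labels, tree


# ---------------------------------------------------------------------------
# incompatibility matrices


@dataclass(frozen=True)
class MatrixConstraints:
    """Structural rules for simulated reaction matrices.

    ``implications`` are (antecedent, consequent) tester pairs that hold
    strictly; ``exclusive`` pairs are mutually exclusive reactions, broken
    with probability ``exception_rate`` per allele (emulating the rare
    natural exception to the e1/e2 dichotomy).
    """

    implications: tuple[tuple[str, str], ...] = ()
    exclusive: tuple[tuple[str, str], ...] = ()
    exception_rate: float = 0.0
    density: float = 0.4


def _close_under_implications(row: dict[str, int], implications) -> None:
    changed = True
    while changed:
        changed = False
        for a, b in implications:
            if row[a] == 1 and row[b] == 0:
                row[b] = 1
                changed = True


def simulate_incompatibility_matrix(
    n_alleles: int,
    testers: tuple[str, ...],
    constraints: MatrixConstraints = MatrixConstraints(),
    seed: int = 0,
) -> IncompatibilityMatrix:
    """Random binary reaction matrix honoring the declared structure.

    Every allele reacts with at least one tester; implication rules hold
    strictly; exclusivity pairs are violated only by designated exception
    alleles (drawn at ``exception_rate``).  Raises if the constraints
    cannot be satisfied within the attempt budget.
    """
    import pandas as pd

    rng = substream(seed, "incompatibility-matrix")
    for a, b in constraints.implications:
        if a not in testers or b not in testers:
            raise ValueError(f"implication over unknown testers: {(a, b)}")

    rows = {}
    for i in range(n_alleles):
        is_exception = rng.random() < constraints.exception_rate
        for _attempt in range(1000):
            row = {t: int(rng.random() < constraints.density) for t in testers}
            if is_exception and constraints.exclusive:
                x, y = constraints.exclusive[rng.integers(len(constraints.exclusive))]
                row[x] = row[y] = 1
            _close_under_implications(row, constraints.implications)
            if sum(row.values()) == 0:
                continue
            violated = any(
                row[x] == 1 and row[y] == 1 for x, y in constraints.exclusive
            )
            if violated == is_exception:
                rows[f"a{i + 1}"] = row
                break
        else:
            raise ValueError(
                "could not satisfy the matrix constraints; they are likely "
                "contradictory (e.g. implications forcing an exclusive pair)"
            )
    return IncompatibilityMatrix(
        data=pd.DataFrame.from_dict(rows, orient="index")[list(testers)]
    )


# ---------------------------------------------------------------------------
# population samples


def sample_population(
    frequencies: dict[str, float], n: int, seed: int = 0, label: str = "simulated"
):
    """Multinomial isolate sample from given allele frequencies."""
    from .population_stats import PopulationSample

    if n <= 0:
        raise ValueError("sample size must be positive")
    probs = np.array(list(frequencies.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8 or np.any(probs < 0):
        raise ValueError("frequencies must be a probability vector")
    rng = substream(seed, "population-sample")
    draws = rng.multinomial(n, probs)
    return PopulationSample(
        counts=dict(zip(frequencies, (int(d) for d in draws))), label=label
    )
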