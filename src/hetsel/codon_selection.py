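"""Codon-substitution likelihood engine for detecting diversifying selection.

Implements the Goldman–Yang style codon model with Nielsen–Yang site-class
mixtures over the nonsynonymous/synonymous rate ratio omega = dN/dS:

* **M0** — one omega for all sites,
* **M1** — "neutral": a conserved class (omega0 <= 1) plus a neutral class
  (omega = 1),
* **M2** — "selection": M1 plus a third class with omega2 >= 1,
* **M3k3** — discrete, three free omega classes,
* **M7** — omega ~ Beta(p, q) on (0, 1), discretized,
* **M8** — M7 plus an extra class with omega_s >= 1.

Substitution between sense codons i and j has rate 0 if they differ at more
than one position, and otherwise is proportional to pi_j, multiplied by
kappa for a transition and by omega for an amino-acid-changing exchange.
The generator is scaled so that one unit of branch length equals one
expected substitution per codon site at the mixture level.  Likelihoods
are computed by Felsenstein pruning over the 61 sense-codon states, with
per-site rescaling to avoid underflow; transition matrices come from an
eigendecomposition of the reversible generator.  Site-class membership is
summarized by naive empirical Bayes (NEB) posteriors, the approach
contemporaneous with this class of models.

Nested model pairs (M1 vs M2, M7 vs M8) are compared by a likelihood
ratio test against chi-square with 2 degrees of freedom; no boundary
correction is applied (this makes the test conservative, see the methods
note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .genetics import (
    CHANGE_IS_NONSYN,
    CHANGE_IS_TRANSITION,
    N_SENSE,
    NUCLEOTIDES,
    ONE_CHANGE,
    SENSE_CODONS,
    SENSE_INDEX,
)
from .io_annotation import CodonAlignment
from .phylogeny import PhyloTree

log = logging.getLogger(__name__)

MODELS = ("M0", "M1", "M2", "M3k3", "M7", "M8")
#: models that contain a class allowed to have omega > 1
SELECTION_MODELS = ("M2", "M3k3", "M8")

_MIN_LENGTH = 1e-6
_MAX_LENGTH = 20.0


@dataclass(frozen=True)
class CodonModelSpec:
    """A fully specified site-class omega mixture, e.g. for simulation.

    ``proportions`` and ``omegas`` give the site-class mixture; ``pi`` the
    equilibrium sense-codon frequencies (uniform when omitted).
    """

    kappa: float
    proportions: tuple[float, ...]
    omegas: tuple[float, ...]
    pi: np.ndarray | None = None
    model: str = "custom"

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if len(self.proportions) != len(self.omegas) or not self.proportions:
            raise ValueError("need matching, nonempty proportions and omegas")
        if abs(sum(self.proportions) - 1.0) > 1e-8 or min(self.proportions) < 0:
            raise ValueError("class proportions must be a probability vector")
        if min(self.omegas) < 0:
            raise ValueError("omegas must be nonnegative")
        if self.pi is not None and (
            self.pi.shape != (N_SENSE,)
            or np.any(self.pi <= 0)
            or abs(float(self.pi.sum()) - 1.0) > 1e-8
        ):
            raise ValueError("pi must be a positive distribution over 61 codons")

    @property
    def frequencies(self) -> np.ndarray:
        if self.pi is None:
            return np.full(N_SENSE, 1.0 / N_SENSE)
        return self.pi

    @classmethod
    def m0(cls, omega: float, kappa: float = 2.0, pi: np.ndarray | None = None):
        return cls(kappa=kappa, proportions=(1.0,), omegas=(omega,), pi=pi, model="M0")

    @classmethod
    def m1(cls, p0: float, omega0: float, kappa: float = 2.0, pi=None):
        return cls(
            kappa=kappa,
            proportions=(p0, 1.0 - p0),
            omegas=(omega0, 1.0),
            pi=pi,
            model="M1",
        )

    @classmethod
    def m2(cls, p0: float, p1: float, omega0: float, omega2: float, kappa: float = 2.0, pi=None):
        return cls(
            kappa=kappa,
            proportions=(p0, p1, 1.0 - p0 - p1),
            omegas=(omega0, 1.0, omega2),
            pi=pi,
            model="M2",
        )


# ---------------------------------------------------------------------------
# equilibrium codon frequencies


def codon_frequencies(ca: CodonAlignment, method: str = "f3x4") -> np.ndarray:
    """Equilibrium frequencies of the 61 sense codons from the alignment.

    ``f3x4`` (default) uses position-specific nucleotide frequencies,
    ``f1x4`` a single nucleotide distribution, ``f61`` the observed codon
    frequencies (with a uniform pseudocount so no sense codon has
    probability zero).
    """
    rows = ca.rows
    if method == "f61":
        counts = np.ones(N_SENSE)  # add-one pseudocount
        for row in rows:
            for h in range(len(row) // 3):
                counts[SENSE_INDEX[row[3 * h : 3 * h + 3]]] += 1
        return counts / counts.sum()

    if method == "f3x4":
        freq = np.zeros((3, 4))
        for row in rows:
            for pos in range(3):
                for nt in row[pos::3]:
                    freq[pos, NUCLEOTIDES.index(nt)] += 1
        freq /= freq.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                freq[0, NUCLEOTIDES.index(c[0])]
                * freq[1, NUCLEOTIDES.index(c[1])]
                * freq[2, NUCLEOTIDES.index(c[2])]
                for c in SENSE_CODONS
            ]
        )
    elif method == "f1x4":
        freq = np.zeros(4)
        for row in rows:
            for nt in row:
                freq[NUCLEOTIDES.index(nt)] += 1
        freq /= freq.sum()
        pi = np.array(
            [np.prod([freq[NUCLEOTIDES.index(n)] for n in c]) for c in SENSE_CODONS]
        )
    else:
        raise ValueError(f"unknown frequency method {method!r}")
    if np.any(pi <= 0):
        # guard against a nucleotide absent from the alignment
        pi = pi + 1e-9
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# generator construction


def _generator_unscaled(pi: np.ndarray, kappa: float, omega: float) -> tuple[np.ndarray, float]:
    """Unscaled GY-style generator and its expected rate under pi."""
    rates = np.where(ONE_CHANGE, 1.0, 0.0)
    rates = np.where(CHANGE_IS_TRANSITION, rates * kappa, rates)
    rates = np.where(CHANGE_IS_NONSYN, rates * omega, rates)
    q = rates * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -float(np.dot(pi, np.diag(q)))
    return q, rate


def build_generator(
    pi: np.ndarray, kappa: float, omega: float, scale: float | None = None
) -> np.ndarray:
    """61x61 codon rate matrix.

    With ``scale=None`` the matrix is normalized so the expected number of
    substitutions per unit time is 1 under ``pi``; a mixture fit passes the
    mixture-averaged rate instead so that branch lengths are expected
    substitutions per codon site at the mixture level.
    """
    if pi.shape != (N_SENSE,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be a positive distribution over the 61 sense codons")
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be positive and omega nonnegative")
    q, rate = _generator_unscaled(pi, kappa, omega)
    return q / (rate if scale is None else scale)


def _eig_factors(q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible generator via symmetrization.

    Returns (A, B, w) with P(t) = (A * exp(w t)) @ B.
    """
    sqrt_pi = np.sqrt(pi)
    sym = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    sym = 0.5 * (sym + sym.T)  # shave asymmetry from rounding
    w, u = np.linalg.eigh(sym)
    a = u / sqrt_pi[:, None]
    b = u.T * sqrt_pi[None, :]
    return a, b, w


def transition_matrix(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) for a reversible, pi-stationary generator."""
    a, b, w = _eig_factors(q, pi)
    p = (a * np.exp(w * t)) @ b
    return np.clip(p, 0.0, None)


# ---------------------------------------------------------------------------
# tree indexing and pruning


class TreeIndex:
    """Flat postorder view of an (un)rooted dendropy tree for the pruning pass.

    Node i's branch is the edge to its parent; the root (seed node) has no
    branch.  Leaf nodes carry the row index of their taxon in the
    alignment.
    """

    def __init__(self, phylo: PhyloTree, taxa: tuple[str, ...]):
        tree = phylo.tree
        self.nodes = list(tree.postorder_node_iter())
        index_of = {id(n): i for i, n in enumerate(self.nodes)}
        self.root = index_of[id(tree.seed_node)]
        self.children: list[list[int]] = [[] for _ in self.nodes]
        self.parent = [-1] * len(self.nodes)
        self.leaf_row = [-1] * len(self.nodes)
        lengths = np.zeros(len(self.nodes))
        for i, node in enumerate(self.nodes):
            for ch in node.child_nodes():
                j = index_of[id(ch)]
                self.children[i].append(j)
                self.parent[j] = i
            if node.is_leaf():
                label = node.taxon.label
                if label not in taxa:
                    raise ValueError(f"tree leaf {label!r} not found among the alleles")
                self.leaf_row[i] = taxa.index(label)
            if node.edge.length is not None:
                lengths[i] = max(float(node.edge.length), 0.0)
        leaf_labels = {n.taxon.label for n in self.nodes if n.is_leaf()}
        if leaf_labels != set(taxa):
            raise ValueError(
                f"tree taxa {sorted(leaf_labels)} do not match alleles {sorted(taxa)}"
            )
        self.branch_nodes = [i for i in range(len(self.nodes)) if i != self.root]
        self.initial_lengths = lengths[self.branch_nodes]

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)

    def full_lengths(self, branch_lengths: np.ndarray) -> np.ndarray:
        full = np.zeros(len(self.nodes))
        full[self.branch_nodes] = branch_lengths
        return full

    def assign_lengths(self, branch_lengths: np.ndarray) -> None:
        for i, val in zip(self.branch_nodes, branch_lengths):
            self.nodes[i].edge.length = float(val)


def encode_alignment(ca: CodonAlignment) -> np.ndarray:
    """(n_alleles, H) matrix of sense-codon state indices."""
    mat = np.empty((len(ca.names), ca.n_codons), dtype=np.intp)
    for r, row in enumerate(ca.rows):
        for h in range(ca.n_codons):
            mat[r, h] = SENSE_INDEX[row[3 * h : 3 * h + 3]]
    return mat


def _prune_log_likelihoods(
    codon_mat: np.ndarray,
    tidx: TreeIndex,
    lengths_full: np.ndarray,
    q: np.ndarray,
    pi: np.ndarray,
) -> np.ndarray:
    """Per-site log-likelihood under a single generator (Felsenstein pruning)."""
    a, b, w = _eig_factors(q, pi)
    n_sites = codon_mat.shape[1]
    partial: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for i in range(len(tidx.nodes)):
        if not tidx.children[i]:
            continue
        prod = np.ones((N_SENSE, n_sites))
        for j in tidx.children[i]:
            p = (a * np.exp(w * lengths_full[j])) @ b
            np.clip(p, 0.0, None, out=p)
            if tidx.leaf_row[j] >= 0:
                contrib = p[:, codon_mat[tidx.leaf_row[j]]]
            else:
                contrib = p @ partial.pop(j)
            prod *= contrib
        top = np.maximum(prod.max(axis=0), 1e-300)
        log_scale += np.log(top)
        partial[i] = prod / top
    site = np.maximum(pi @ partial[tidx.root], 1e-300)
    return np.log(site) + log_scale


def _mixture_site_logliks(
    codon_mat: np.ndarray,
    tidx: TreeIndex,
    branch_lengths: np.ndarray,
    pi: np.ndarray,
    kappa: float,
    proportions: np.ndarray,
    omegas: np.ndarray,
) -> np.ndarray:
    """(K, H) per-class per-site log-likelihoods, mixture-level scaling."""
    pairs = [_generator_unscaled(pi, kappa, w) for w in omegas]
    scale = float(np.dot(proportions, [r for _, r in pairs]))
    full = tidx.full_lengths(branch_lengths)
    return np.vstack(
        [_prune_log_likelihoods(codon_mat, tidx, full, q / scale, pi) for q, _ in pairs]
    )


def site_log_likelihoods(
    ca: CodonAlignment, tree: PhyloTree, pi: np.ndarray, kappa: float, omega: float
) -> np.ndarray:
    """Per-site log-likelihood vector under a single-omega model."""
    tidx = TreeIndex(tree, ca.names)
    codon_mat = encode_alignment(ca)
    q = build_generator(pi, kappa, omega)
    return _prune_log_likelihoods(
        codon_mat, tidx, tidx.full_lengths(tidx.initial_lengths), q, pi
    )


def site_likelihoods(
    ca: CodonAlignment, tree: PhyloTree, pi: np.ndarray, kappa: float, omega: float
) -> np.ndarray:
    return np.exp(site_log_likelihoods(ca, tree, pi, kappa, omega))


# ---------------------------------------------------------------------------
# beta discretization (M7/M8)


def beta_categories(p: float, q: float, k: int = 10) -> np.ndarray:
    """Means of K equal-probability categories of Beta(p, q) on (0, 1)."""
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, k + 1), p, q)
    upper = special.betainc(p + 1.0, q, edges)
    means = (p / (p + q)) * np.diff(upper) * k
    return np.clip(means, 0.0, 1.0)


# ---------------------------------------------------------------------------
# model parameterizations


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


_LOGW_LO, _LOGW_HI = np.log(1e-4), np.log(50.0)
_LOGK_LO, _LOGK_HI = np.log(0.05), np.log(99.0)
_LOGB_LO, _LOGB_HI = np.log(0.05), np.log(99.0)
_STICK = 15.0


class _ModelForm:
    """Packing/unpacking of one site-class model's free parameters.

    The free vector starts with log(kappa); the model-specific block
    follows.  ``classes(x)`` returns (proportions, omegas, extras).
    """

    def __init__(self, model: str, k_beta: int = 10):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; available: {MODELS}")
        self.model = model
        self.k_beta = k_beta

    def initial(self) -> np.ndarray:
        x = {"kappa": np.log(2.0)}
        m = self.model
        if m == "M0":
            rest = [np.log(0.5)]
        elif m == "M1":
            rest = [_logit(0.7), np.log(0.2)]
        elif m == "M2":
            rest = [_logit(0.6), _logit(0.75), np.log(0.2), np.log(3.0)]
        elif m == "M3k3":
            rest = [_logit(1 / 3), _logit(0.5), np.log(0.1), np.log(0.8), np.log(3.0)]
        elif m == "M7":
            rest = [np.log(0.8), np.log(1.2)]
        else:  # M8
            rest = [_logit(0.9), np.log(0.8), np.log(1.2), np.log(3.0)]
        return np.array([x["kappa"], *rest])

    def bounds(self) -> list[tuple[float, float]]:
        kb = (_LOGK_LO, _LOGK_HI)
        stick = (-_STICK, _STICK)
        m = self.model
        if m == "M0":
            return [kb, (_LOGW_LO, _LOGW_HI)]
        if m == "M1":
            return [kb, stick, (_LOGW_LO, 0.0)]
        if m == "M2":
            return [kb, stick, stick, (_LOGW_LO, 0.0), (0.0, _LOGW_HI)]
        if m == "M3k3":
            return [kb, stick, stick] + [(_LOGW_LO, _LOGW_HI)] * 3
        if m == "M7":
            return [kb, (_LOGB_LO, _LOGB_HI), (_LOGB_LO, _LOGB_HI)]
        return [kb, stick, (_LOGB_LO, _LOGB_HI), (_LOGB_LO, _LOGB_HI), (0.0, _LOGW_HI)]

    def classes(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
        kappa = float(np.exp(x[0]))
        m = self.model
        if m == "M0":
            return np.array([1.0]), np.array([np.exp(x[1])]), {"kappa": kappa}
        if m == "M1":
            p0 = _sigmoid(x[1])
            return (
                np.array([p0, 1.0 - p0]),
                np.array([np.exp(x[2]), 1.0]),
                {"kappa": kappa, "p0": float(p0), "omega0": float(np.exp(x[2]))},
            )
        if m == "M2":
            p0 = _sigmoid(x[1])
            p1 = (1.0 - p0) * _sigmoid(x[2])
            p2 = 1.0 - p0 - p1
            w0, w2 = np.exp(x[3]), np.exp(x[4])
            return (
                np.array([p0, p1, p2]),
                np.array([w0, 1.0, w2]),
                {
                    "kappa": kappa,
                    "p0": float(p0),
                    "p1": float(p1),
                    "p2": float(p2),
                    "omega0": float(w0),
                    "omega2": float(w2),
                },
            )
        if m == "M3k3":
            p0 = _sigmoid(x[1])
            p1 = (1.0 - p0) * _sigmoid(x[2])
            ws = np.exp(x[3:6])
            return (
                np.array([p0, p1, 1.0 - p0 - p1]),
                ws,
                {"kappa": kappa},
            )
        if m == "M7":
            p, q = np.exp(x[1]), np.exp(x[2])
            return (
                np.full(self.k_beta, 1.0 / self.k_beta),
                beta_categories(p, q, self.k_beta),
                {"kappa": kappa, "beta_p": float(p), "beta_q": float(q)},
            )
        # M8
        p0 = _sigmoid(x[1])
        p, q = np.exp(x[2]), np.exp(x[3])
        ws = np.exp(x[4])
        props = np.append(np.full(self.k_beta, p0 / self.k_beta), 1.0 - p0)
        omegas = np.append(beta_categories(p, q, self.k_beta), ws)
        return props, omegas, {
            "kappa": kappa,
            "p0": float(p0),
            "beta_p": float(p),
            "beta_q": float(q),
            "omega_s": float(ws),
        }


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Maximum-likelihood fit of one site-class model."""

    model: str
    log_likelihood: float
    kappa: float
    class_proportions: np.ndarray
    class_omegas: np.ndarray
    parameters: dict[str, float]
    codon_frequencies: np.ndarray
    tree: PhyloTree
    branch_lengths: np.ndarray
    overall_omega: float
    converged: bool
    n_evaluations: int
    message: str = ""
    table_row: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "model": self.model,
            "log_likelihood": round(self.log_likelihood, 5),
            "overall_dn_ds": round(self.overall_omega, 4),
            "kappa": round(self.kappa, 4),
            "parameters": {k: round(v, 5) for k, v in self.parameters.items()},
            "converged": self.converged,
        }


class ConvergenceError(RuntimeError):
    """Optimization did not reach a usable optimum within the retry budget."""


def fit_model(
    ca: CodonAlignment,
    tree: PhyloTree,
    model: str,
    *,
    freqs: str = "f3x4",
    branch_lengths: str = "optimize",
    n_starts: int | None = None,
    seed: int = 0,
    k_beta: int = 10,
    maxiter: int = 500,
) -> FitResult:
    """Fit one site-class codon model by maximum likelihood.

    Branch lengths are re-estimated together with the substitution
    parameters by default (``branch_lengths="optimize"``); pass ``"fixed"``
    to keep the lengths of the supplied tree, e.g. when reusing lengths
    optimized once under M0 across a model series, or when fitting on a
    simulation's true tree.  Mixture models default to 3 random restarts
    seeded by ``seed``; the best optimum is kept.
    """
    if len(ca.names) < 3:
        raise ValueError("need at least 3 sequences")
    if ca.n_codons < 10:
        raise ValueError("need at least 10 codons")
    if branch_lengths not in ("optimize", "fixed"):
        raise ValueError("branch_lengths must be 'optimize' or 'fixed'")

    form = _ModelForm(model, k_beta=k_beta)
    if n_starts is None:
        n_starts = 1 if model == "M0" else 3

    pi = codon_frequencies(ca, freqs)
    # work on a private copy of the tree so the caller's lengths survive
    fitted_tree = PhyloTree(tree=tree.tree.clone(depth=1))
    tidx = TreeIndex(fitted_tree, ca.names)
    codon_mat = encode_alignment(ca)

    x0_model = form.initial()
    bounds = form.bounds()
    if branch_lengths == "optimize":
        init_lengths = np.clip(tidx.initial_lengths, 1e-3, _MAX_LENGTH)
    else:
        init_lengths = np.clip(tidx.initial_lengths, 0.0, _MAX_LENGTH)
    n_model = len(x0_model)
    if branch_lengths == "optimize":
        x0 = np.concatenate([x0_model, init_lengths])
        bounds = bounds + [(_MIN_LENGTH, _MAX_LENGTH)] * tidx.n_branches
    else:
        x0 = x0_model

    n_evals = 0

    def nll(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        props, omegas, extras = form.classes(x[:n_model])
        lens = x[n_model:] if branch_lengths == "optimize" else init_lengths
        logl = _mixture_site_logliks(
            codon_mat, tidx, lens, pi, extras["kappa"], props, omegas
        )
        top = logl.max(axis=0)
        site = top + np.log(np.dot(props, np.exp(logl - top)))
        val = -float(site.sum())
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        if start == 0:
            xs = x0.copy()
        else:
            xs = x0 + rng.normal(scale=0.6, size=x0.shape)
            xs = np.clip(xs, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        res = optimize.minimize(
            nll, xs, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise ConvergenceError(f"{model}: optimization failed ({best.message})")
    if not best.success:
        log.warning("%s: optimizer stopped without formal convergence: %s", model, best.message)

    props, omegas, extras = form.classes(best.x[:n_model])
    fit_lengths = (
        best.x[n_model:] if branch_lengths == "optimize" else init_lengths.copy()
    )
    tidx.assign_lengths(fit_lengths)
    kappa = extras.pop("kappa")
    lnl = -float(best.fun)
    return FitResult(
        model=model,
        log_likelihood=lnl,
        kappa=kappa,
        class_proportions=props,
        class_omegas=omegas,
        parameters=extras,
        codon_frequencies=pi,
        tree=fitted_tree,
        branch_lengths=fit_lengths,
        overall_omega=float(np.dot(props, omegas)),
        converged=bool(best.success),
        n_evaluations=n_evals,
        message=str(best.message),
    )


def fit_model_series(
    ca: CodonAlignment,
    tree: PhyloTree,
    models: tuple[str, ...] = ("M0", "M1", "M2", "M7", "M8"),
    *,
    freqs: str = "f3x4",
    seed: int = 0,
    reuse_m0_lengths: bool = True,
    **kwargs,
) -> dict[str, FitResult]:
    """Fit a series of models on one alignment/tree.

    With ``reuse_m0_lengths`` (default) branch lengths are optimized once
    under M0 and held fixed for the remaining models, which is much faster
    and changes log-likelihoods only marginally on data of this size.
    """
    fits: dict[str, FitResult] = {}
    work_tree = tree
    first = True
    for m in models:
        if reuse_m0_lengths and first:
            fit = fit_model(ca, work_tree, m, freqs=freqs, seed=seed,
                            branch_lengths="optimize", **kwargs)
            work_tree = fit.tree
            first = False
        else:
            bl = "fixed" if reuse_m0_lengths else "optimize"
            fit = fit_model(ca, work_tree, m, freqs=freqs, seed=seed,
                            branch_lengths=bl, **kwargs)
        fits[m] = fit
    return fits


# ---------------------------------------------------------------------------
# likelihood ratio test and NEB site identification


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(null: FitResult, alt: FitResult, df: int = 2) -> LRTResult:
    """2*(lnL_alt - lnL_null) against chi-square with ``df`` degrees of freedom."""
    delta = alt.log_likelihood - null.log_likelihood
    if delta < -1e-4:
        raise ConvergenceError(
            f"alternative model {alt.model} has lower lnL than {null.model} "
            f"(delta={delta:.6g}); an optimization failed"
        )
    statistic = max(2.0 * delta, 0.0)
    return LRTResult(
        statistic=statistic, df=df, p_value=float(stats.chi2.sf(statistic, df))
    )


def neb_sites(
    fit: FitResult,
    ca: CodonAlignment,
    tree: PhyloTree | None = None,
    levels: tuple[float, ...] = (0.95, 0.99),
) -> pd.DataFrame:
    """Naive empirical Bayes posteriors of class membership per codon site.

    ``P(k | x_h) = p_k L_h(omega_k) / sum_k' p_k' L_h(omega_k')`` at the
    maximum-likelihood estimates.  A site is flagged positively selected at
    a level when the total posterior over classes with omega > 1 reaches
    that level.  Only meaningful for models with such a class (M2, M3k3,
    M8).
    """
    if fit.model not in SELECTION_MODELS:
        raise ValueError(
            f"model {fit.model} has no omega > 1 class; NEB site identification "
            f"requires one of {SELECTION_MODELS}"
        )
    phylo = tree if tree is not None else fit.tree
    tidx = TreeIndex(phylo, ca.names)
    codon_mat = encode_alignment(ca)
    logl = _mixture_site_logliks(
        codon_mat,
        tidx,
        fit.branch_lengths,
        fit.codon_frequencies,
        fit.kappa,
        fit.class_proportions,
        fit.class_omegas,
    )
    top = logl.max(axis=0)
    weighted = fit.class_proportions[:, None] * np.exp(logl - top)
    posterior = weighted / weighted.sum(axis=0, keepdims=True)
    positive = fit.class_omegas > 1.0
    prob_pos = posterior[positive].sum(axis=0)
    out = pd.DataFrame(
        {
            "site": np.arange(1, ca.n_codons + 1),
            **{
                f"p_class{k}": posterior[k]
                for k in range(len(fit.class_omegas))
            },
            "p_positive": prob_pos,
        }
    )
    for level in levels:
        out[f"selected_{level:g}"] = prob_pos >= level
    return out


def positively_selected_sites(neb: pd.DataFrame, level: float = 0.99) -> list[int]:
    """1-based codon positions flagged at the given NEB level."""
    return [int(s) for s in neb.loc[neb[f"selected_{level:g}"], "site"]]
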