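"""Scenario simulator for tree-structured compositional counts.

Data are generated through the exact forward model of the likelihood:
covariates are multivariate normal with exchangeable correlation, a
sparse truth places ±effect coefficients on random branch x covariate
pairs, and counts are drawn top-down — at every internal node the
node total is split among children with Dirichlet(gamma) proportions
followed by a multinomial allocation.  Simulator and likelihood are
therefore mutually testing: parameter-recovery runs exercise both.

Defaults reflect a typical 16S amplicon study: 10,000 reads per
subject, standardized covariates, a handful of true effects of
magnitude ~1 on the log-concentration scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelState, link_concentrations
from .tree import CountMatrix, CovariateMatrix, PhyloTree, parse_newick

__all__ = [
    "SimulationScenario",
    "SimulatedData",
    "simulate_tree",
    "simulate_covariates",
    "make_truth",
    "simulate_counts",
    "simulate_scenario",
]


@dataclass(frozen=True)
class SimulationScenario:
    """A complete synthetic study design."""

    seed: int
    n: int = 200
    J: int = 4                      # leaves of a random bifurcating tree
    tree: PhyloTree | None = None   # overrides J when given
    P: int = 10
    rho: float = 0.0                # exchangeable covariate correlation
    n_active: int = 3
    effect: float = 1.0             # |beta| of true pairs, signs random
    intercept_range: tuple[float, float] = (-0.5, 0.5)
    depth: int | tuple[int, int] = 10_000  # reads/subject, fixed or range

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one subject")
        if self.tree is None and self.J < 2:
            raise ValueError("need at least 2 leaves")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")
        if self.effect < 0:
            raise ValueError("effect size must be nonnegative")
        lo = self.depth if isinstance(self.depth, int) else self.depth[0]
        if lo < 1:
            raise ValueError("sequencing depth must be >= 1")


@dataclass(frozen=True)
class SimulatedData:
    tree: PhyloTree
    X: CovariateMatrix
    truth: ModelState
    counts: CountMatrix


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def simulate_tree(J: int, seed) -> PhyloTree:
    """Random rooted bifurcating tree by sequential leaf attachment.

    Starting from a two-leaf root, each new leaf splits a uniformly
    chosen existing edge, yielding B = 2J - 2 branches.
    """
    if J < 2:
        raise ValueError("need at least 2 leaves")
    rng = _as_rng(seed)
    labels = [f"t{j+1}" for j in range(J)]
    # nested-list newick representation; edges = positions in the structure
    nodes = [labels[0], labels[1]]  # children of the root

    def all_edges(tree, prefix=()):  # (path to parent list, index) pairs
        out = []
        for i, child in enumerate(tree):
            out.append((tree, i))
            if isinstance(child, list):
                out.extend(all_edges(child))
        return out

    for j in range(2, J):
        edges = all_edges(nodes)
        parent, i = edges[rng.integers(len(edges))]
        parent[i] = [parent[i], labels[j]]

    def to_newick(x) -> str:
        if isinstance(x, list):
            return "(" + ",".join(to_newick(c) for c in x) + ")"
        return x

    return parse_newick(to_newick(nodes) + ";")


def simulate_covariates(n: int, P: int, rho: float, seed) -> CovariateMatrix:
    """MVN covariates with exchangeable correlation, then z-scored."""
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    if P > 1 and rho < -1.0 / (P - 1):
        raise ValueError("exchangeable correlation not positive definite")
    rng = _as_rng(seed)
    cov = np.full((P, P), rho, dtype=float)
    np.fill_diagonal(cov, 1.0)
    raw = rng.multivariate_normal(np.zeros(P), cov, size=n,
                                  method="cholesky")
    sd = raw.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    vals = (raw - raw.mean(axis=0)) / sd
    return CovariateMatrix(values=vals,
                           covariate_names=[f"x{p+1}" for p in range(P)],
                           standardized=True,
                           center=raw.mean(axis=0), scale=sd)


def make_truth(tree: PhyloTree, P: int, n_active: int, effect: float,
               seed, intercept_range=(-0.5, 0.5)) -> ModelState:
    """Sparse ground truth: n_active distinct pairs at ±effect, uniform
    intercepts (internal branches are eligible targets)."""
    B = tree.n_branches
    if n_active > B * P:
        raise ValueError(f"n_active={n_active} exceeds B*P={B * P}")
    rng = _as_rng(seed)
    alpha = rng.uniform(*intercept_range, size=B)
    beta = np.zeros((B, P))
    zeta = np.zeros((B, P), dtype=np.int8)
    if n_active > 0:
        flat = rng.choice(B * P, size=n_active, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_active)
        for idx, s in zip(flat, signs):
            b, p = divmod(int(idx), P)
            beta[b, p] = s * effect
            zeta[b, p] = 1
    return ModelState(alpha=alpha, beta=beta, zeta=zeta)


def simulate_counts(tree: PhyloTree, truth: ModelState, X: CovariateMatrix,
                    depths, seed) -> CountMatrix:
    """Draw leaf counts through the tree's Dirichlet-multinomial cascade.

    ``depths`` is an int, an (lo, hi) range, or a per-subject array of
    total reads.  Conservation (leaf sums = depth) holds by
    construction.
    """
    rng = _as_rng(seed)
    n = X.values.shape[0]
    if isinstance(depths, int):
        N = np.full(n, depths, dtype=np.int64)
    elif isinstance(depths, tuple):
        N = rng.integers(depths[0], depths[1] + 1, size=n)
    else:
        N = np.asarray(depths, dtype=np.int64)
        if N.shape != (n,):
            raise ValueError("per-subject depths must have length n")
    if (N < 1).any():
        raise ValueError("sequencing depth must be >= 1")
    gamma = link_concentrations(truth, X, tree)
    J = tree.n_leaves
    counts = np.zeros((n, J), dtype=np.int64)
    # per-subject top-down allocation, nodes visited parent-before-child
    node_totals = np.zeros((n, tree.n_internal), dtype=np.int64)
    node_totals[:, 0] = N
    for v, bs in enumerate(tree.node_branches):
        g = gamma[:, bs]
        for i in range(n):
            t = int(node_totals[i, v])
            if t == 0:
                alloc = np.zeros(len(bs), dtype=np.int64)
            else:
                probs = rng.dirichlet(g[i])
                alloc = rng.multinomial(t, probs)
            for j, b in enumerate(bs):
                child = tree.branch_child_node[b]
                if child >= 0:
                    node_totals[i, child] = alloc[j]
                else:
                    leaf = int(tree.branch_leaf_sets[b][0])
                    counts[i, leaf] = alloc[j]
    return CountMatrix(values=counts,
                       subject_ids=[f"s{i+1}" for i in range(n)],
                       taxon_labels=list(tree.leaf_labels))


def simulate_scenario(scenario: SimulationScenario) -> SimulatedData:
    """Generate a full dataset; all randomness derives from the scenario
    seed through independent child streams, so results are reproducible
    across platforms."""
    root = np.random.default_rng(scenario.seed)
    tree_rng, cov_rng, truth_rng, count_rng = root.spawn(4)
    tree = scenario.tree if scenario.tree is not None \
        else simulate_tree(scenario.J, tree_rng)
    X = simulate_covariates(scenario.n, scenario.P, scenario.rho, cov_rng)
    truth = make_truth(tree, scenario.P, scenario.n_active, scenario.effect,
                       truth_rng, scenario.intercept_range)
    counts = simulate_counts(tree, truth, X, scenario.depth, count_rng)
    return SimulatedData(tree=tree, X=X, truth=truth, counts=counts)
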