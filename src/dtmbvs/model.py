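"""Dirichlet-tree multinomial (DTM) regression likelihood.

The leaf-count vector of each subject factorizes along the rooted tree:
every internal node allocates its total to its children through an
independent Dirichlet-multinomial (DM) kernel.  The DM concentration of
branch b for subject i follows a log-linear link

    gamma[i, b] = exp(alpha_b + sum_p zeta_bp * beta_bp * x_ip),

where zeta_bp is a binary inclusion indicator: zeta_bp = 0 forces
beta_bp = 0 (the spike), so excluded covariates leave the likelihood
untouched.  On a star tree (one internal node) the model reduces
exactly to Dirichlet-multinomial regression on the raw count matrix.

All gamma-function ratios are evaluated in log space via ``gammaln``;
counts in the hundreds overflow the gamma function directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .tree import CovariateMatrix, NodeCounts, PhyloTree

__all__ = [
    "ModelState",
    "DtmData",
    "link_concentrations",
    "dm_node_loglik",
    "dtm_loglik",
    "ConcentrationError",
]


class ConcentrationError(FloatingPointError):
    """Raised when the link overflows to a nonfinite concentration."""


@dataclass
class ModelState:
    """Per-branch intercepts, coefficients, and inclusion indicators.

    Invariant: ``zeta[b, p] == 0`` implies ``beta[b, p] == 0``.
    """

    alpha: np.ndarray  # (B,)
    beta: np.ndarray   # (B, P)
    zeta: np.ndarray   # (B, P), 0/1

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        if self.alpha.ndim != 1 or self.beta.ndim != 2:
            raise ValueError("alpha must be (B,), beta must be (B, P)")
        if self.beta.shape != self.zeta.shape:
            raise ValueError("beta and zeta shapes differ")
        if self.beta.shape[0] != self.alpha.shape[0]:
            raise ValueError("alpha and beta disagree on B")
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.beta).all()):
            raise ValueError("state contains nonfinite values")
        if not np.isin(self.zeta, (0, 1)).all():
            raise ValueError("zeta must be binary")
        if np.any((self.zeta == 0) & (self.beta != 0.0)):
            raise ValueError("spike violated: beta != 0 where zeta == 0")

    @classmethod
    def empty(cls, B: int, P: int) -> "ModelState":
        return cls(alpha=np.zeros(B), beta=np.zeros((B, P)),
                   zeta=np.zeros((B, P), dtype=np.int8))

    def copy(self) -> "ModelState":
        return ModelState(alpha=self.alpha.copy(), beta=self.beta.copy(),
                          zeta=self.zeta.copy())

    @property
    def n_active(self) -> int:
        return int(self.zeta.sum())


@dataclass(frozen=True)
class DtmData:
    """Bundled model inputs.

    ``node_counts=None`` disables the likelihood term entirely, which is
    how prior-recovery runs of the sampler are configured.
    """

    tree: PhyloTree
    X: CovariateMatrix
    node_counts: NodeCounts | None

    @property
    def B(self) -> int:
        return self.tree.n_branches

    @property
    def P(self) -> int:
        return self.X.n_covariates

    @property
    def n_subjects(self) -> int:
        return self.X.values.shape[0]


def link_concentrations(state: ModelState, X: CovariateMatrix,
                        tree: PhyloTree) -> np.ndarray:
    """Subjects x branches concentration matrix gamma under the link."""
    B = tree.n_branches
    n, P = X.values.shape
    if state.alpha.shape != (B,) or state.beta.shape != (B, P):
        raise ValueError(
            f"state dims {state.beta.shape} do not match (B={B}, P={P})")
    eta = state.alpha[None, :] + X.values @ (state.zeta * state.beta).T
    with np.errstate(over="ignore"):
        gamma = np.exp(eta)
    if not np.isfinite(gamma).all():
        raise ConcentrationError(
            "link overflow: concentrations are nonfinite; consider "
            "standardizing covariates or shrinking coefficients")
    return gamma


def dm_node_loglik(y, gamma, include_coef: bool = False) -> float:
    """Dirichlet-multinomial log-likelihood of one child-count vector.

    With ``include_coef`` the multinomial coefficient is added, giving
    the full log pmf; without it the value is the kernel the sampler
    uses (the coefficient is constant in all model parameters).
    """
    y = np.asarray(y)
    gamma = np.asarray(gamma, dtype=float)
    if y.shape != gamma.shape or y.ndim != 1:
        raise ValueError("y and gamma must be 1-d vectors of equal length")
    if (y < 0).any() or not np.all(y == np.floor(y)):
        raise ValueError("counts must be nonnegative integers")
    if (gamma <= 0).any() or not np.isfinite(gamma).all():
        raise ValueError("concentrations must be positive and finite")
    gs = gamma.sum()
    n = y.sum()
    out = (gammaln(gs) - gammaln(gs + n)
           + np.sum(gammaln(gamma + y) - gammaln(gamma)))
    if include_coef:
        out += gammaln(n + 1) - np.sum(gammaln(y + 1))
    return float(out)


def _dm_table_loglik(Y: np.ndarray, G: np.ndarray) -> float:
    """Sum of DM kernels over the rows of a subjects x children table."""
    gs = G.sum(axis=1)
    ns = Y.sum(axis=1)
    return float(np.sum(gammaln(gs) - gammaln(gs + ns))
                 + np.sum(gammaln(G + Y) - gammaln(G)))


def dtm_loglik(node_counts: NodeCounts, state: ModelState,
               X: CovariateMatrix, tree: PhyloTree) -> float:
    """Full DTM log-likelihood: sum of per-node DM kernels over subjects.

    The multinomial coefficients are omitted (constant in parameters).
    """
    if len(node_counts.tables) != tree.n_internal:
        raise ValueError("node_counts does not match the tree")
    gamma = link_concentrations(state, X, tree)
    total = 0.0
    for v, bs in enumerate(tree.node_branches):
        total += _dm_table_loglik(node_counts.tables[v], gamma[:, bs])
    return total
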