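"""Priors: normal intercepts, spike-and-slab coefficients, and two
inclusion-indicator families.

* Beta-Binomial: a common Bernoulli inclusion probability is integrated
  against Beta(a, b), giving an exchangeable prior on the indicator
  configuration that depends only on the number of active entries.
  a = b = 1 is the non-informative default.
* Markov random field (MRF): an unnormalized Ising-type prior
  exp(d * 1'zeta + f * zeta' G zeta) over each branch's covariate
  indicator vector, sharing a covariate adjacency graph G across
  branches.  d < 0 encourages sparsity; f >= 0 encourages joint
  inclusion of graph-linked covariates.  Only prior ratios enter the
  sampler, so the intractable normalizing constant is never needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln

from .model import ModelState

__all__ = [
    "PriorConfig",
    "log_prior_alpha",
    "log_prior_beta",
    "log_prior_zeta_bb",
    "log_prior_zeta_mrf",
    "log_prior_zeta",
    "correlation_graph",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters for all prior components.

    Defaults: a = b = 1 (uniform inclusion probability), diffuse
    sigma2 = 10 slabs and intercepts, and for the MRF a sparsity
    log-odds d = -2.2 (~ logit 0.1) with mild smoothing f = 0.5.
    """

    a: float = 1.0
    b: float = 1.0
    sigma2_alpha: float = 10.0
    sigma2_beta: float = 10.0
    prior_kind: str = "beta_binomial"
    d: float = -2.2
    f: float = 0.5
    G: np.ndarray | None = None

    def __post_init__(self):
        if min(self.a, self.b, self.sigma2_alpha, self.sigma2_beta) <= 0:
            raise ValueError("a, b and prior variances must be positive")
        if self.prior_kind not in ("beta_binomial", "mrf"):
            raise ValueError(f"unknown prior_kind {self.prior_kind!r}")
        if self.f < 0:
            raise ValueError("MRF smoothing f must be >= 0")
        if self.prior_kind == "mrf":
            if self.G is None:
                raise ValueError("MRF prior requires an adjacency matrix G")
            G = np.asarray(self.G, dtype=float)
            if G.ndim != 2 or G.shape[0] != G.shape[1]:
                raise ValueError("G must be square")
            if not np.array_equal(G, G.T):
                raise ValueError("G must be symmetric")
            if np.any(np.diag(G) != 0):
                raise ValueError("G must have a zero diagonal")
            object.__setattr__(self, "G", G)


def _norm_logpdf(x: np.ndarray, sigma2: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(sigma2)) - 0.5 * np.square(x) / sigma2


def log_prior_alpha(alpha: np.ndarray, cfg: PriorConfig) -> float:
    """Independent mean-zero normal prior on the branch intercepts."""
    alpha = np.asarray(alpha, dtype=float)
    if not np.isfinite(alpha).all():
        raise ValueError("alpha must be finite")
    return float(np.sum(_norm_logpdf(alpha, cfg.sigma2_alpha)))


def log_prior_beta(state: ModelState, cfg: PriorConfig) -> float:
    """Slab density of the active coefficients; the spike contributes 0.

    An inactive (zeta = 0) coefficient sits in a point mass at zero and
    adds nothing, which is what makes between-model moves comparable
    across dimensions.
    """
    active = state.zeta == 1
    vals = state.beta[active]
    if not np.isfinite(vals).all():
        raise ValueError("active beta must be finite")
    return float(np.sum(_norm_logpdf(vals, cfg.sigma2_beta)))


def log_prior_zeta_bb(zeta: np.ndarray, cfg: PriorConfig) -> float:
    """Marginalized Beta-Binomial prior on the indicator configuration.

    P(zeta) = Beta(a + k, b + M - k) / Beta(a, b) with k active entries
    out of M; normalized over all 2^M configurations.
    """
    zeta = np.asarray(zeta)
    M = zeta.size
    if M < 1:
        raise ValueError("zeta must be nonempty")
    k = int(zeta.sum())
    return float(betaln(cfg.a + k, cfg.b + M - k) - betaln(cfg.a, cfg.b))


def log_prior_zeta_mrf(zeta: np.ndarray, cfg: PriorConfig) -> float:
    """Unnormalized MRF log-prior, applied within each branch row.

    d * sum(zeta) + f * sum_b zeta_b' G zeta_b with symmetric G, so each
    active edge pair is counted twice (both triangles of G).
    """
    if cfg.G is None:
        raise ValueError("MRF prior requires G")
    zeta = np.asarray(zeta, dtype=float)
    if zeta.ndim == 1:
        zeta = zeta[None, :]
    if zeta.shape[1] != cfg.G.shape[0]:
        raise ValueError("zeta covariate dimension does not match G")
    quad = float(np.einsum("bp,pq,bq->", zeta, cfg.G, zeta))
    return float(cfg.d * zeta.sum() + cfg.f * quad)


def log_prior_zeta(zeta: np.ndarray, cfg: PriorConfig) -> float:
    """Dispatch to the configured inclusion prior (log scale)."""
    if cfg.prior_kind == "beta_binomial":
        return log_prior_zeta_bb(zeta, cfg)
    return log_prior_zeta_mrf(zeta, cfg)


def correlation_graph(X: np.ndarray, cutoff: float = 0.7) -> np.ndarray:
    """Threshold an empirical covariate correlation matrix into a 0/1
    adjacency (|r| >= cutoff, zero diagonal) for the MRF prior."""
    R = np.corrcoef(np.asarray(X, dtype=float), rowvar=False)
    G = (np.abs(R) >= cutoff).astype(np.int64)
    np.fill_diagonal(G, 0)
    return G
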