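"""Posterior summaries and selection rules.

Selection operates on the marginal posterior probability of inclusion
(MPPI): the post-burn-in average of each inclusion indicator's MCMC
samples.  Two rules are provided:

* ``mppi``: include every branch x covariate pair with MPPI >= cutoff
  (0.50 by default, the median-model rule);
* ``bfdr``: choose the cutoff so that the Bayesian false discovery
  rate — the mean of (1 - MPPI) over the selected set — stays at or
  below a target alpha, controlling for multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import McmcSamples
from .tree import PhyloTree

__all__ = [
    "SelectionResult",
    "compute_mppi",
    "bfdr_threshold",
    "select",
    "network_edges",
    "convergence_traces",
    "TraceDiagnostics",
    "geweke_z",
    "mcse_mean",
]


@dataclass
class SelectionResult:
    mppi: np.ndarray                 # (B, P)
    rule: str                        # "mppi" or "bfdr"
    alpha: float | None              # BFDR target (None under plain MPPI)
    threshold: float | None          # implied cutoff; None => select none
    selected: list[tuple[int, int]]  # (branch, covariate) index pairs
    branch_labels: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        blab = self.branch_labels or [f"b{b}" for b in
                                      range(self.mppi.shape[0])]
        clab = self.covariate_names or [f"x{p}" for p in
                                        range(self.mppi.shape[1])]
        rows = [{"branch_index": b, "branch": blab[b], "covariate": clab[p],
                 "mppi": self.mppi[b, p]} for b, p in self.selected]
        return pd.DataFrame(rows,
                            columns=["branch_index", "branch", "covariate",
                                     "mppi"])


def compute_mppi(samples: McmcSamples, burn_in: int | None = None
                 ) -> np.ndarray:
    """Entrywise mean of the post-burn-in inclusion indicator draws."""
    skip = (samples.retained_burn if burn_in is None
            else min(burn_in // samples.thin, samples.n_draws))
    if skip >= samples.n_draws:
        raise ValueError("burn-in consumes all stored draws")
    return samples.zeta[skip:].mean(axis=0)


def bfdr_threshold(mppi, alpha: float) -> float | None:
    """Largest selection whose expected FDR stays within ``alpha``.

    Candidates are sorted by descending MPPI; selecting the top k has
    expected FDR mean(1 - mppi) over those k.  Returns the smallest
    MPPI among the largest qualifying k, or None when no nonempty
    selection qualifies.
    """
    vals = np.asarray(mppi, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty MPPI input")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("MPPI values must lie in [0, 1]")
    s = np.sort(vals)[::-1]
    fdr = np.cumsum(1.0 - s) / np.arange(1, s.size + 1)
    ok = np.flatnonzero(fdr <= alpha)
    if ok.size == 0:
        return None
    return float(s[ok[-1]])


def select(mppi: np.ndarray, rule: str = "mppi",
           alpha_or_cutoff: float = 0.5,
           branch_labels: list[str] | None = None,
           covariate_names: list[str] | None = None) -> SelectionResult:
    """Apply a selection rule to an MPPI matrix.

    Ties at the cutoff are included (>= comparison), matching the
    convention of the median-model rule.
    """
    mppi = np.asarray(mppi, dtype=float)
    if rule == "mppi":
        cutoff: float | None = float(alpha_or_cutoff)
        alpha = None
    elif rule == "bfdr":
        alpha = float(alpha_or_cutoff)
        cutoff = bfdr_threshold(mppi, alpha)
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if cutoff is None:
        pairs: list[tuple[int, int]] = []
    else:
        pairs = [(int(b), int(p))
                 for b, p in np.argwhere(mppi >= cutoff)]
    return SelectionResult(mppi=mppi, rule=rule, alpha=alpha,
                           threshold=cutoff, selected=sorted(pairs),
                           branch_labels=branch_labels or [],
                           covariate_names=covariate_names or [])


def network_edges(selection: SelectionResult, tree: PhyloTree,
                  covariate_names: list[str] | None = None,
                  path_taxa: list[str] | None = None) -> pd.DataFrame:
    """Taxon/node <-> covariate edge list from a selection.

    Each selected (branch, covariate) pair becomes an edge between the
    branch's child label (leaf name, or a stable ``node_<k>`` label for
    internal branches) and the covariate.  ``path_taxa`` restricts the
    output to branches on the root -> leaf paths of the named taxa,
    the view used to summarize genus-level results.
    """
    clab = (covariate_names or selection.covariate_names
            or [f"x{p}" for p in range(selection.mppi.shape[1])])
    keep: set[int] | None = None
    if path_taxa is not None:
        keep = set()
        for taxon in path_taxa:
            keep.update(tree.path_branches(taxon))
    rows = []
    for b, p in selection.selected:
        if keep is not None and b not in keep:
            continue
        rows.append({"source": tree.branch_labels[b], "target": clab[p],
                     "branch_index": b, "mppi": selection.mppi[b, p]})
    return pd.DataFrame(rows, columns=["source", "target", "branch_index",
                                       "mppi"])


def _spectral_var(x: np.ndarray) -> float:
    """Variance of the mean estimated by nonoverlapping batch means,
    robust to autocorrelation; returns n * Var(mean) (spectral density
    at frequency zero, up to 2*pi)."""
    n = x.size
    n_batches = max(2, int(math.floor(math.sqrt(n))))
    batch_len = n // n_batches
    if batch_len < 1:
        return float(np.var(x, ddof=1)) if n > 1 else 0.0
    trimmed = x[: n_batches * batch_len].reshape(n_batches, batch_len)
    means = trimmed.mean(axis=1)
    return float(batch_len * np.var(means, ddof=1))


def mcse_mean(x) -> float:
    """Monte Carlo standard error of a chain mean (batch means)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 draws")
    return math.sqrt(_spectral_var(x) / x.size)


def geweke_z(x, first: float = 0.1, last: float = 0.5) -> float | None:
    """Geweke convergence z-score comparing early and late chain means.

    Spectral variances are estimated by batch means within each
    segment.  Returns None for a (numerically) constant chain, where
    the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    n1 = max(2, int(first * n))
    n2 = max(2, int(last * n))
    a, b = x[:n1], x[n - n2:]
    va, vb = _spectral_var(a), _spectral_var(b)
    denom = va / n1 + vb / n2
    if denom <= 0 or not np.isfinite(denom):
        return None
    return float((a.mean() - b.mean()) / math.sqrt(denom))


@dataclass
class TraceDiagnostics:
    n_active: np.ndarray
    log_posterior: np.ndarray
    geweke_log_posterior: float | None  # None when undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"draw": np.arange(self.n_active.size),
                             "n_active": self.n_active,
                             "log_posterior": self.log_posterior})


def convergence_traces(samples: McmcSamples) -> TraceDiagnostics:
    """Per-draw traces of model size and log posterior, plus a Geweke
    z-score on the post-burn-in log posterior."""
    if samples.n_draws == 0:
        raise ValueError("no draws")
    lp_post = samples.log_posterior[samples.retained_burn:]
    z = geweke_z(lp_post) if lp_post.size >= 8 else None
    return TraceDiagnostics(n_active=samples.n_active.copy(),
                            log_posterior=samples.log_posterior.copy(),
                            geweke_log_posterior=z)
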