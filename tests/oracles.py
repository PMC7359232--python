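"""Independent reference implementations used only to check the package.

Everything here deliberately avoids the code paths under test:
enumeration instead of closed forms, scipy's compound distribution
instead of the hand-written kernel, mode-centered dense-grid quadrature
instead of MCMC.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import dirichlet_multinomial


def polya_urn_logpmf(y, gamma) -> float:
    """DM log pmf by exhaustive enumeration of draw sequences.

    Sums the sequential Pólya-urn probability over every distinct
    ordering of the observed counts.  Exponential in the total count;
    only usable for tiny configurations.
    """
    y = tuple(int(v) for v in y)
    gamma = np.asarray(gamma, dtype=float)
    n = sum(y)
    if n == 0:
        return 0.0
    total = 0.0
    items = [c for c, cnt in enumerate(y) for _ in range(cnt)]
    for seq in set(itertools.permutations(items)):
        counts = np.zeros(len(y))
        prob = 1.0
        for t, c in enumerate(seq):
            prob *= (gamma[c] + counts[c]) / (gamma.sum() + t)
            counts[c] += 1
        total += prob
    return math.log(total)


def dm_regression_loglik(Y, gamma, include_coef=False) -> float:
    """Dirichlet-multinomial regression log-likelihood via scipy.

    ``Y`` and ``gamma`` are subjects x categories; one compound pmf per
    subject.  scipy includes the multinomial coefficient, which is
    removed unless requested.
    """
    out = 0.0
    for yi, gi in zip(np.asarray(Y), np.asarray(gamma)):
        n = int(yi.sum())
        out += dirichlet_multinomial.logpmf(yi, gi, n)
        if not include_coef:
            out -= gammaln(n + 1) - np.sum(gammaln(yi + 1))
    return float(out)


def bfdr_bruteforce(mppi, alpha):
    """O(M^2) search over all candidate thresholds.

    For every distinct MPPI value as cutoff, compute the expected FDR
    of the implied selection; return the smallest qualifying cutoff
    (largest selection), or None.
    """
    vals = np.asarray(mppi, dtype=float).ravel()
    best = None
    for c in np.unique(vals):
        sel = vals[vals >= c]
        if sel.size == 0:
            continue
        if np.mean(1.0 - sel) <= alpha:
            best = float(c) if best is None else min(best, float(c))
    return best


def leafset_decompose(count_values, taxon_labels, newick_leaf_map):
    """Recompute node child counts by brute-force leaf-set membership.

    ``newick_leaf_map`` is {(node, child_position): set of taxon
    labels}; returns {(node, child_position): n-vector}.
    """
    col = {lab: j for j, lab in enumerate(taxon_labels)}
    out = {}
    for key, labels in newick_leaf_map.items():
        cols = [col[lab] for lab in labels]
        out[key] = count_values[:, cols].sum(axis=1)
    return out


def tiny_model_log_marginals(Y, x, sigma2_alpha, sigma2_beta,
                             n_grid=31, half=6.0):
    """Log marginal likelihood of each of the 4 models on a two-leaf
    star tree with one covariate, by dense-grid quadrature.

    The grid is centered at the posterior mode of each model and
    aligned with the Hessian eigen-axes (the integrand is far too
    peaked for a prior-scaled grid).  Deterministic; grid-converged to
    well below Monte Carlo resolution at these settings.

    Returns log marginals in zeta order (0,0), (0,1), (1,0), (1,1) —
    WITHOUT the model prior.
    """
    Y = np.asarray(Y)
    x = np.asarray(x, dtype=float)

    def log_kernel(TH, z1, z2):
        a1, a2 = TH[:, 0], TH[:, 1]
        i = 2
        b1 = TH[:, i] if z1 else np.zeros_like(a1)
        i += z1
        b2 = TH[:, i] if z2 else np.zeros_like(a1)
        with np.errstate(over="ignore"):
            g1 = np.exp(a1[:, None] + b1[:, None] * x)
            g2 = np.exp(a2[:, None] + b2[:, None] * x)
        gs = g1 + g2
        ys = Y.sum(1)
        ll = (gammaln(gs) - gammaln(gs + ys)
              + gammaln(g1 + Y[:, 0]) - gammaln(g1)
              + gammaln(g2 + Y[:, 1]) - gammaln(g2)).sum(1)
        lp = (-0.5 * (a1 ** 2 + a2 ** 2) / sigma2_alpha
              - np.log(2 * np.pi * sigma2_alpha))
        for z, b in ((z1, b1), (z2, b2)):
            if z:
                lp = lp - 0.5 * b ** 2 / sigma2_beta \
                     - 0.5 * np.log(2 * np.pi * sigma2_beta)
        out = ll + lp
        out[~np.isfinite(out)] = -np.inf
        return out

    def log_marginal(z1, z2):
        dims = 2 + z1 + z2

        def f(th):
            return -log_kernel(np.asarray(th)[None, :], z1, z2)[0]

        res = minimize(f, np.zeros(dims), method="Nelder-Mead",
                       options=dict(xatol=1e-8, fatol=1e-10,
                                    maxiter=5000, maxfev=10000))
        mode = res.x
        h = 1e-4
        H = np.zeros((dims, dims))
        for i in range(dims):
            for j in range(dims):
                ei = np.zeros(dims); ei[i] = h
                ej = np.zeros(dims); ej[j] = h
                H[i, j] = (f(mode + ei + ej) - f(mode + ei - ej)
                           - f(mode - ei + ej) + f(mode - ei - ej)) / (4 * h * h)
        w, V = np.linalg.eigh(H)
        s = 1.0 / np.sqrt(np.maximum(w, 1e-12))
        u = np.linspace(-half, half, n_grid)
        du = u[1] - u[0]
        grids = np.meshgrid(*([u] * dims), indexing="ij")
        U = np.stack([g.ravel() for g in grids], axis=-1)
        parts = []
        for k in range(0, U.shape[0], 40_000):
            TH = mode + (U[k:k + 40_000] * s) @ V.T
            parts.append(logsumexp(log_kernel(TH, z1, z2)))
        return logsumexp(np.array(parts)) + dims * np.log(du) + np.log(s).sum()

    return np.array([log_marginal(z1, z2)
                     for z1 in (0, 1) for z2 in (0, 1)])
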