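"""Metropolis-Hastings-within-Gibbs sampler over (alpha, beta, zeta).

Each iteration performs ``moves_per_iter`` between-model proposals
(add/delete/swap on the branch x covariate inclusion indicators, with
the coefficient proposed jointly) followed by one within-model sweep
(random-walk updates of every intercept and every active coefficient).

Between-model moves
-------------------
With probability ``1 - swap_prob`` a uniform (b, p) entry is toggled:
an *add* draws beta' ~ N(0, rw_sd_beta^2) and the proposal density
enters the acceptance ratio; a *delete* sets beta to zero.  With
probability ``swap_prob`` a branch is chosen uniformly and one active
and one inactive entry of its row exchange states with a fresh
coefficient for the newcomer; if the row has no active (or no inactive)
entry the swap degenerates to an add (or delete) on that row.

Because a single-entry toggle can be produced by two mechanisms (the
add/delete move anywhere, the degenerate swap on an all-inactive or
all-active row), the acceptance ratio uses the *total* proposal
probability of the transition summed over mechanisms in both
directions.  This keeps the chain exactly reversible, including in the
degenerate cases.

Likelihood bookkeeping is incremental: a move on branch b only touches
the Dirichlet-multinomial kernel of b's parent node, so one proposal
costs a single small subjects x children evaluation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln

from .model import (ConcentrationError, DtmData, ModelState,
                    link_concentrations, _dm_table_loglik)
from .priors import (PriorConfig, log_prior_alpha, log_prior_beta,
                     log_prior_zeta)

__all__ = [
    "SamplerConfig",
    "McmcSamples",
    "log_posterior",
    "between_model_step",
    "within_model_step",
    "run_mcmc",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.

    The 150,000-iteration / 75,000-burn-in defaults are the settings
    used for genus-level 16S analyses of ~100 subjects; desk-scale
    simulations run comfortably with far fewer.
    """

    seed: int
    iterations: int = 150_000
    burn_in: int = 75_000
    rw_sd_alpha: float = 0.5
    rw_sd_beta: float = 0.5
    moves_per_iter: int | None = None  # default: max(1, ceil(B*P/10))
    swap_prob: float = 0.5
    thin: int = 1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("require 0 <= burn_in < iterations")
        if self.rw_sd_alpha <= 0 or self.rw_sd_beta <= 0:
            raise ValueError("random-walk proposal sds must be positive")
        if not (0.0 <= self.swap_prob < 1.0):
            raise ValueError("require 0 <= swap_prob < 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.moves_per_iter is not None and self.moves_per_iter < 1:
            raise ValueError("moves_per_iter must be >= 1")

    def resolved_moves(self, B: int, P: int) -> int:
        if self.moves_per_iter is not None:
            return self.moves_per_iter
        return max(1, math.ceil(B * P / 10))


@dataclass
class McmcSamples:
    """Thinned draws of all parameters plus trace summaries.

    ``burn_in`` is on the iteration scale; ``retained_burn`` converts it
    to an index into the stored (thinned) draws.
    """

    alpha: np.ndarray          # (T, B)
    beta: np.ndarray           # (T, B, P)
    zeta: np.ndarray           # (T, B, P) uint8
    log_posterior: np.ndarray  # (T,)
    n_active: np.ndarray       # (T,)
    burn_in: int
    thin: int
    config: dict
    branch_labels: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.zeta.shape[0]

    @property
    def retained_burn(self) -> int:
        # draw t is iteration (t+1)*thin; drop draws inside the burn-in
        return min(self.burn_in // self.thin, self.n_draws)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("alpha", "beta", "zeta", "log_posterior", "n_active"):
                f.create_dataset(name, data=getattr(self, name),
                                 chunks=True, compression="gzip")
            f.attrs["burn_in"] = self.burn_in
            f.attrs["thin"] = self.thin
            f.attrs["config"] = json.dumps(self.config)
            f.attrs["branch_labels"] = json.dumps(self.branch_labels)
            f.attrs["covariate_names"] = json.dumps(self.covariate_names)

    @classmethod
    def load_hdf5(cls, path) -> "McmcSamples":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                alpha=f["alpha"][...], beta=f["beta"][...],
                zeta=f["zeta"][...],
                log_posterior=f["log_posterior"][...],
                n_active=f["n_active"][...],
                burn_in=int(f.attrs["burn_in"]), thin=int(f.attrs["thin"]),
                config=json.loads(f.attrs["config"]),
                branch_labels=json.loads(f.attrs["branch_labels"]),
                covariate_names=json.loads(f.attrs["covariate_names"]))

    def to_coda_csv(self, path) -> None:
        """Flat per-draw CSV readable by external MCMC diagnostics."""
        import pandas as pd

        T, B, P = self.beta.shape
        cols = {}
        blab = self.branch_labels or [f"b{b}" for b in range(B)]
        clab = self.covariate_names or [f"x{p}" for p in range(P)]
        for b in range(B):
            cols[f"alpha[{blab[b]}]"] = self.alpha[:, b]
        for b in range(B):
            for p in range(P):
                cols[f"beta[{blab[b]},{clab[p]}]"] = self.beta[:, b, p]
                cols[f"zeta[{blab[b]},{clab[p]}]"] = self.zeta[:, b, p]
        cols["log_posterior"] = self.log_posterior
        cols["n_active"] = self.n_active
        pd.DataFrame(cols).to_csv(path, index_label="draw")


def _rw_logpdf(x: float, sd: float) -> float:
    return -0.5 * _LOG_2PI - math.log(sd) - 0.5 * (x / sd) ** 2


def _slab_logpdf(x: float, sigma2: float) -> float:
    return -0.5 * (_LOG_2PI + math.log(sigma2)) - 0.5 * x * x / sigma2


def log_posterior(state: ModelState, data: DtmData,
                  cfg: PriorConfig) -> float:
    """Likelihood plus all log-prior terms; raises if any term is
    nonfinite, naming the offender."""
    from .model import dtm_loglik

    ll = 0.0
    if data.node_counts is not None:
        ll = dtm_loglik(data.node_counts, state, data.X, data.tree)
    terms = {
        "likelihood": ll,
        "prior_alpha": log_prior_alpha(state.alpha, cfg),
        "prior_beta": log_prior_beta(state, cfg),
        "prior_zeta": log_prior_zeta(state.zeta, cfg),
    }
    for name, val in terms.items():
        if not np.isfinite(val):
            raise ValueError(f"nonfinite log-posterior term: {name}")
    return float(sum(terms.values()))


class _Chain:
    """Mutable sampler state with incremental likelihood caching."""

    def __init__(self, state: ModelState, data: DtmData, prior_cfg: PriorConfig,
                 sampler_cfg: SamplerConfig):
        self.state = state.copy()
        self.data = data
        self.pc = prior_cfg
        self.sc = sampler_cfg
        self.B = data.B
        self.P = data.P
        self.has_lik = data.node_counts is not None
        tree = data.tree
        self.parent = tree.branch_parent_node
        self.node_branches = tree.node_branches
        # column position of each branch within its parent's table
        self.branch_pos = np.empty(self.B, dtype=np.int64)
        for v, bs in enumerate(self.node_branches):
            for j, b in enumerate(bs):
                self.branch_pos[b] = j
        if self.has_lik:
            self.gamma = link_concentrations(self.state, data.X, tree)
            self.node_ll = np.array([
                _dm_table_loglik(data.node_counts.tables[v],
                                 self.gamma[:, bs])
                for v, bs in enumerate(self.node_branches)])
            self.ll = float(self.node_ll.sum())
        else:
            self.gamma = None
            self.node_ll = None
            self.ll = 0.0
        self.lp_alpha = log_prior_alpha(self.state.alpha, prior_cfg)
        self.lp_beta = log_prior_beta(self.state, prior_cfg)
        self.lp_zeta = log_prior_zeta(self.state.zeta, prior_cfg)

    # -- likelihood deltas --------------------------------------------------

    def _node_ll_new(self, b: int, new_col: np.ndarray) -> float | None:
        """Parent-node kernel with branch b's gamma column replaced.

        Returns None if the proposed column is nonfinite (reject)."""
        if not np.isfinite(new_col).all() or (new_col <= 0).any():
            return None
        v = int(self.parent[b])
        bs = self.node_branches[v]
        G = self.gamma[:, bs].copy()
        G[:, self.branch_pos[b]] = new_col
        return _dm_table_loglik(self.data.node_counts.tables[v], G)

    def _apply_branch(self, b: int, new_col: np.ndarray,
                      new_node_ll: float) -> None:
        v = int(self.parent[b])
        self.ll += new_node_ll - self.node_ll[v]
        self.node_ll[v] = new_node_ll
        self.gamma[:, b] = new_col

    def _branch_col(self, b: int, beta_row: np.ndarray,
                    zeta_row: np.ndarray, alpha_b: float) -> np.ndarray:
        X = self.data.X.values
        eta = alpha_b + X @ (zeta_row * beta_row)
        with np.errstate(over="ignore"):
            return np.exp(eta)

    # -- between-model moves ------------------------------------------------

    def _log_toggle_prob(self, all_same_row: bool) -> float:
        """Total probability of proposing a specific single-entry toggle.

        add/delete path: (1-swap_prob) / (B*P); degenerate-swap path
        (only when the row is entirely inactive/active before the move):
        swap_prob / (B*P)."""
        q = (1.0 - self.sc.swap_prob) / (self.B * self.P)
        if all_same_row:
            q += self.sc.swap_prob / (self.B * self.P)
        return math.log(q)

    def _toggle(self, b: int, p: int, rng: np.random.Generator) -> bool:
        st = self.state
        adding = st.zeta[b, p] == 0
        row_zeta_before = st.zeta[b]
        if adding:
            beta_new = rng.normal(0.0, self.sc.rw_sd_beta)
            new_row_beta = st.beta[b].copy()
            new_row_zeta = row_zeta_before.copy()
            new_row_beta[p] = beta_new
            new_row_zeta[p] = 1
            d_lp_beta = _slab_logpdf(beta_new, self.pc.sigma2_beta)
            log_q_fwd = (self._log_toggle_prob(row_zeta_before.sum() == 0)
                         + _rw_logpdf(beta_new, self.sc.rw_sd_beta))
            log_q_rev = self._log_toggle_prob(new_row_zeta.sum() == self.P)
        else:
            beta_old = st.beta[b, p]
            new_row_beta = st.beta[b].copy()
            new_row_zeta = row_zeta_before.copy()
            new_row_beta[p] = 0.0
            new_row_zeta[p] = 0
            d_lp_beta = -_slab_logpdf(beta_old, self.pc.sigma2_beta)
            log_q_fwd = self._log_toggle_prob(row_zeta_before.sum() == self.P)
            log_q_rev = (self._log_toggle_prob(new_row_zeta.sum() == 0)
                         + _rw_logpdf(beta_old, self.sc.rw_sd_beta))

        zeta_new = st.zeta.copy()
        zeta_new[b] = new_row_zeta
        lp_zeta_new = log_prior_zeta(zeta_new, self.pc)
        d_ll = 0.0
        new_col = None
        new_node_ll = None
        if self.has_lik:
            new_col = self._branch_col(b, new_row_beta, new_row_zeta,
                                       st.alpha[b])
            new_node_ll = self._node_ll_new(b, new_col)
            if new_node_ll is None:
                return False
            d_ll = new_node_ll - self.node_ll[int(self.parent[b])]

        log_acc = (d_ll + d_lp_beta + (lp_zeta_new - self.lp_zeta)
                   + log_q_rev - log_q_fwd)
        if math.log(rng.random()) < log_acc:
            st.beta[b] = new_row_beta
            st.zeta[b] = new_row_zeta
            self.lp_beta += d_lp_beta
            self.lp_zeta = lp_zeta_new
            if self.has_lik:
                self._apply_branch(b, new_col, new_node_ll)
            return True
        return False

    def _swap(self, rng: np.random.Generator) -> bool:
        st = self.state
        b = int(rng.integers(self.B))
        row = st.zeta[b]
        active = np.flatnonzero(row == 1)
        inactive = np.flatnonzero(row == 0)
        if active.size == 0 or inactive.size == 0:
            # degenerate: add on an all-inactive row, delete on all-active
            pool = inactive if active.size == 0 else active
            p = int(pool[rng.integers(pool.size)])
            return self._toggle(b, p, rng)
        p_out = int(active[rng.integers(active.size)])
        p_in = int(inactive[rng.integers(inactive.size)])
        beta_old = st.beta[b, p_out]
        beta_new = rng.normal(0.0, self.sc.rw_sd_beta)
        new_row_beta = st.beta[b].copy()
        new_row_zeta = row.copy()
        new_row_beta[p_out] = 0.0
        new_row_zeta[p_out] = 0
        new_row_beta[p_in] = beta_new
        new_row_zeta[p_in] = 1
        zeta_new = st.zeta.copy()
        zeta_new[b] = new_row_zeta
        lp_zeta_new = log_prior_zeta(zeta_new, self.pc)
        d_lp_beta = (_slab_logpdf(beta_new, self.pc.sigma2_beta)
                     - _slab_logpdf(beta_old, self.pc.sigma2_beta))
        d_ll = 0.0
        new_col = None
        new_node_ll = None
        if self.has_lik:
            new_col = self._branch_col(b, new_row_beta, new_row_zeta,
                                       st.alpha[b])
            new_node_ll = self._node_ll_new(b, new_col)
            if new_node_ll is None:
                return False
            d_ll = new_node_ll - self.node_ll[int(self.parent[b])]
        # row active count is unchanged, so selection probabilities cancel;
        # only the fresh-coefficient densities remain
        log_acc = (d_ll + d_lp_beta + (lp_zeta_new - self.lp_zeta)
                   + _rw_logpdf(beta_old, self.sc.rw_sd_beta)
                   - _rw_logpdf(beta_new, self.sc.rw_sd_beta))
        if math.log(rng.random()) < log_acc:
            st.beta[b] = new_row_beta
            st.zeta[b] = new_row_zeta
            self.lp_beta += d_lp_beta
            self.lp_zeta = lp_zeta_new
            if self.has_lik:
                self._apply_branch(b, new_col, new_node_ll)
            return True
        return False

    def between_step(self, rng: np.random.Generator) -> None:
        if rng.random() < self.sc.swap_prob:
            self._swap(rng)
        else:
            b = int(rng.integers(self.B))
            p = int(rng.integers(self.P))
            self._toggle(b, p, rng)

    # -- within-model moves -------------------------------------------------

    def _update_alpha(self, b: int, rng: np.random.Generator) -> bool:
        st = self.state
        a_old = st.alpha[b]
        a_new = a_old + rng.normal(0.0, self.sc.rw_sd_alpha)
        d_lp = (_slab_logpdf(a_new, self.pc.sigma2_alpha)
                - _slab_logpdf(a_old, self.pc.sigma2_alpha))
        d_ll = 0.0
        new_col = None
        new_node_ll = None
        if self.has_lik:
            with np.errstate(over="ignore"):
                new_col = self.gamma[:, b] * math.exp(a_new - a_old)
            new_node_ll = self._node_ll_new(b, new_col)
            if new_node_ll is None:
                return False
            d_ll = new_node_ll - self.node_ll[int(self.parent[b])]
        if math.log(rng.random()) < d_ll + d_lp:
            st.alpha[b] = a_new
            self.lp_alpha += d_lp
            if self.has_lik:
                self._apply_branch(b, new_col, new_node_ll)
            return True
        return False

    def _update_beta(self, b: int, p: int, rng: np.random.Generator) -> bool:
        st = self.state
        beta_old = st.beta[b, p]
        beta_new = beta_old + rng.normal(0.0, self.sc.rw_sd_beta)
        d_lp = (_slab_logpdf(beta_new, self.pc.sigma2_beta)
                - _slab_logpdf(beta_old, self.pc.sigma2_beta))
        d_ll = 0.0
        new_col = None
        new_node_ll = None
        if self.has_lik:
            x = self.data.X.values[:, p]
            with np.errstate(over="ignore"):
                new_col = self.gamma[:, b] * np.exp((beta_new - beta_old) * x)
            new_node_ll = self._node_ll_new(b, new_col)
            if new_node_ll is None:
                return False
            d_ll = new_node_ll - self.node_ll[int(self.parent[b])]
        if math.log(rng.random()) < d_ll + d_lp:
            st.beta[b, p] = beta_new
            self.lp_beta += d_lp
            if self.has_lik:
                self._apply_branch(b, new_col, new_node_ll)
            return True
        return False

    def within_step(self, rng: np.random.Generator) -> None:
        for b in range(self.B):
            self._update_alpha(b, rng)
        for b, p in np.argwhere(self.state.zeta == 1):
            self._update_beta(int(b), int(p), rng)

    @property
    def log_post(self) -> float:
        return self.ll + self.lp_alpha + self.lp_beta + self.lp_zeta


def between_model_step(state: ModelState, data: DtmData,
                       prior_cfg: PriorConfig, sampler_cfg: SamplerConfig,
                       rng: np.random.Generator) -> ModelState:
    """One add/delete/swap proposal; returns the (possibly unchanged)
    state.  Convenience wrapper over the cached chain used by
    :func:`run_mcmc`."""
    chain = _Chain(state, data, prior_cfg, sampler_cfg)
    chain.between_step(rng)
    return chain.state


def within_model_step(state: ModelState, data: DtmData,
                      prior_cfg: PriorConfig, sampler_cfg: SamplerConfig,
                      rng: np.random.Generator) -> ModelState:
    """One full random-walk sweep over intercepts and active coefficients."""
    chain = _Chain(state, data, prior_cfg, sampler_cfg)
    chain.within_step(rng)
    return chain.state


def _initial_state(data: DtmData) -> ModelState:
    """Empty-model start: zeta = 0, beta = 0, intercepts set to the log
    mean observed child proportion (+0.01 guard for empty branches)."""
    B, P = data.B, data.P
    state = ModelState.empty(B, P)
    if data.node_counts is None:
        return state
    tree = data.tree
    for v, bs in enumerate(tree.node_branches):
        tab = data.node_counts.tables[v]
        totals = tab.sum(axis=1)
        ok = totals > 0
        for j, b in enumerate(bs):
            if ok.any():
                prop = float(np.mean(tab[ok, j] / totals[ok]))
            else:
                prop = 1.0 / len(bs)
            state.alpha[b] = math.log(prop + 0.01)
    return state


def run_mcmc(data: DtmData, prior_cfg: PriorConfig,
             sampler_cfg: SamplerConfig,
             initial_state: ModelState | None = None,
             progress_callback=None) -> McmcSamples:
    """Run the full sampler and return thinned draws.

    Identical (seed, data, config) inputs give bit-identical output.
    Draws are stored for every ``thin``-th iteration including burn-in;
    summary functions drop the burn-in segment themselves.
    """
    B, P = data.B, data.P
    if B < 1 or P < 1:
        raise ValueError("need at least one branch and one covariate")
    state = initial_state if initial_state is not None else _initial_state(data)
    rng = np.random.default_rng(sampler_cfg.seed)
    chain = _Chain(state, data, prior_cfg, sampler_cfg)
    if not np.isfinite(chain.log_post):
        raise ValueError(
            "nonfinite log-posterior at initialization; check covariate "
            "standardization and prior hyperparameters")
    moves = sampler_cfg.resolved_moves(B, P)
    T = sampler_cfg.iterations // sampler_cfg.thin
    alpha_s = np.empty((T, B))
    beta_s = np.empty((T, B, P))
    zeta_s = np.empty((T, B, P), dtype=np.uint8)
    lp_s = np.empty(T)
    na_s = np.empty(T, dtype=np.int64)
    t_out = 0
    for it in range(sampler_cfg.iterations):
        for _ in range(moves):
            chain.between_step(rng)
        chain.within_step(rng)
        if (it + 1) % sampler_cfg.thin == 0:
            alpha_s[t_out] = chain.state.alpha
            beta_s[t_out] = chain.state.beta
            zeta_s[t_out] = chain.state.zeta
            lp_s[t_out] = chain.log_post
            na_s[t_out] = chain.state.n_active
            t_out += 1
        if progress_callback is not None and (it + 1) % 1000 == 0:
            progress_callback(it + 1, chain.state.n_active, chain.log_post)
    cfg_snapshot = {"sampler": asdict(sampler_cfg),
                    "prior": {k: (v.tolist() if isinstance(v, np.ndarray)
                                  else v)
                              for k, v in asdict(prior_cfg).items()}}
    return McmcSamples(
        alpha=alpha_s[:t_out], beta=beta_s[:t_out], zeta=zeta_s[:t_out],
        log_posterior=lp_s[:t_out], n_active=na_s[:t_out],
        burn_in=sampler_cfg.burn_in, thin=sampler_cfg.thin,
        config=cfg_snapshot,
        branch_labels=list(data.tree.branch_labels),
        covariate_names=list(data.X.covariate_names))
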