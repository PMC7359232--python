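"""Shared fixtures.

The expensive posterior-sampling fixtures are session-scoped so the
sampler tests and the acceptance checks reuse one set of runs.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import dtmbvs as d

import oracles


@pytest.fixture(scope="session")
def simple_tree():
    return d.parse_newick("((A,B),C);")


@pytest.fixture(scope="session")
def recovery_results():
    """Parameter-recovery runs: 5 seeds of the reference scenario
    (n=200 subjects, random 4-leaf tree => 6 branches, 10 covariates,
    3 true pairs at |beta| = 1, depth 10^4; 20k iterations, 10k burn)."""
    results = []
    for seed in range(1, 6):
        sim = d.simulate_scenario(d.SimulationScenario(
            seed=seed, n=200, J=4, P=10, rho=0.0, n_active=3,
            effect=1.0, depth=10_000))
        nc = d.decompose_counts(sim.counts, sim.tree)
        data = d.DtmData(tree=sim.tree, X=sim.X, node_counts=nc)
        samples = d.run_mcmc(
            data, d.PriorConfig(),
            d.SamplerConfig(seed=seed + 100, iterations=20_000,
                            burn_in=10_000))
        mppi = d.compute_mppi(samples)
        true_mask = sim.truth.zeta.astype(bool)
        results.append({
            "min_true_mppi": float(mppi[true_mask].min()),
            "mean_null_mppi": float(mppi[~true_mask].mean()),
            "mppi": mppi,
            "truth": sim.truth,
        })
    return results


@pytest.fixture(scope="session")
def tiny_posterior():
    """Two-leaf star tree, one covariate, 50 subjects: the 4-model
    problem small enough for a deterministic quadrature oracle."""
    tree = d.star_tree(["A", "B"])
    rng = np.random.default_rng(5)
    x = rng.normal(size=50)
    x = (x - x.mean()) / x.std(ddof=1)
    X = d.CovariateMatrix(values=x[:, None], covariate_names=["x1"],
                          standardized=True)
    truth = d.ModelState(alpha=np.array([0.2, -0.1]),
                         beta=np.array([[0.8], [0.0]]),
                         zeta=np.array([[1], [0]]))
    counts = d.simulate_counts(tree, truth, X, 100, rng)
    nc = d.decompose_counts(counts, tree)
    prior_cfg = d.PriorConfig()

    log_ml = oracles.tiny_model_log_marginals(
        nc.tables[0], x, prior_cfg.sigma2_alpha, prior_cfg.sigma2_beta)
    log_post = log_ml + np.array([
        d.log_prior_zeta_bb(np.array([[z1], [z2]]), prior_cfg)
        for z1 in (0, 1) for z2 in (0, 1)])
    oracle_probs = np.exp(log_post - log_post.max())
    oracle_probs /= oracle_probs.sum()

    data = d.DtmData(tree=tree, X=X, node_counts=nc)
    samples = d.run_mcmc(
        data, prior_cfg,
        d.SamplerConfig(seed=3, iterations=50_000, burn_in=10_000,
                        moves_per_iter=2))
    keep = slice(samples.retained_burn, None)
    model_id = (samples.zeta[keep, 0, 0] * 2
                + samples.zeta[keep, 1, 0]).astype(int)
    freqs, mcses = [], []
    for m in range(4):
        ind = (model_id == m).astype(float)
        freqs.append(float(ind.mean()))
        mcses.append(d.mcse_mean(ind))
    return {"oracle_probs": oracle_probs, "freqs": np.array(freqs),
            "mcses": np.array(mcses), "samples": samples, "data": data,
            "model_id": model_id}


@pytest.fixture(scope="session")
def prior_only_samples():
    """Likelihood-free run under the a=b=1 Beta-Binomial prior.

    The add-proposal sd matches the slab sd so trans-dimensional moves
    mix well against a diffuse slab."""
    tree = d.star_tree(["A", "B"])
    X = d.CovariateMatrix(
        values=np.random.default_rng(1).normal(size=(10, 2)),
        covariate_names=["x1", "x2"])
    data = d.DtmData(tree=tree, X=X, node_counts=None)
    prior_cfg = d.PriorConfig()
    samples = d.run_mcmc(
        data, prior_cfg,
        d.SamplerConfig(seed=17, iterations=50_000, burn_in=0,
                        moves_per_iter=4,
                        rw_sd_beta=math.sqrt(prior_cfg.sigma2_beta)))
    return samples
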