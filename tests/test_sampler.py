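"""Sampler correctness: determinism, prior recovery, exhaustive-posterior
agreement on a tiny model, reversibility, and the gating invariant."""

import math

import numpy as np
import pytest

import dtmbvs as d


def _tiny_data(seed=0, n=12, J=3, P=2, depth=100):
    sim = d.simulate_scenario(d.SimulationScenario(
        seed=seed, n=n, J=J, P=P, n_active=1, effect=1.0, depth=depth))
    nc = d.decompose_counts(sim.counts, sim.tree)
    return d.DtmData(tree=sim.tree, X=sim.X, node_counts=nc)


class TestLogPosterior:
    def test_manual_term_sum(self):
        data = _tiny_data()
        state = d.ModelState.empty(data.B, data.P)
        cfg = d.PriorConfig()
        expected = (d.dtm_loglik(data.node_counts, state, data.X, data.tree)
                    + d.log_prior_alpha(state.alpha, cfg)
                    + d.log_prior_beta(state, cfg)
                    + d.log_prior_zeta(state.zeta, cfg))
        assert d.log_posterior(state, data, cfg) == pytest.approx(
            expected, rel=1e-12)

    def test_active_beta_difference_decomposes(self):
        """Two states differing in one active beta differ by likelihood
        plus slab density differences only."""
        data = _tiny_data(seed=1)
        cfg = d.PriorConfig()
        zeta = np.zeros((data.B, data.P), dtype=int)
        zeta[0, 0] = 1
        s1 = d.ModelState(alpha=np.zeros(data.B),
                          beta=np.where(zeta, 0.4, 0.0), zeta=zeta)
        s2 = d.ModelState(alpha=np.zeros(data.B),
                          beta=np.where(zeta, -0.3, 0.0), zeta=zeta)
        dl = (d.dtm_loglik(data.node_counts, s1, data.X, data.tree)
              - d.dtm_loglik(data.node_counts, s2, data.X, data.tree))
        dslab = (d.log_prior_beta(s1, cfg) - d.log_prior_beta(s2, cfg))
        assert (d.log_posterior(s1, data, cfg)
                - d.log_posterior(s2, data, cfg)) == pytest.approx(
            dl + dslab, rel=1e-10)


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            d.SamplerConfig(seed=1, iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            d.SamplerConfig(seed=1, rw_sd_beta=0.0)
        with pytest.raises(ValueError):
            d.SamplerConfig(seed=1, swap_prob=1.0)
        with pytest.raises(ValueError):
            d.SamplerConfig(seed=1, thin=0)

    def test_moves_per_iter_default_scales_with_model(self):
        cfg = d.SamplerConfig(seed=1)
        assert cfg.resolved_moves(6, 10) == 6
        assert cfg.resolved_moves(2, 1) == 1

    def test_paper_scale_defaults_valid(self):
        cfg = d.SamplerConfig(seed=1)
        assert cfg.iterations == 150_000
        assert cfg.burn_in == 75_000


class TestDeterminism:
    def test_identical_seed_bit_identical_samples(self):
        data = _tiny_data(seed=2)
        cfg = d.SamplerConfig(seed=99, iterations=400, burn_in=100)
        s1 = d.run_mcmc(data, d.PriorConfig(), cfg)
        s2 = d.run_mcmc(data, d.PriorConfig(), cfg)
        assert np.array_equal(s1.alpha, s2.alpha)
        assert np.array_equal(s1.beta, s2.beta)
        assert np.array_equal(s1.zeta, s2.zeta)
        assert np.array_equal(s1.log_posterior, s2.log_posterior)

    def test_different_seed_differs(self):
        data = _tiny_data(seed=2)
        s1 = d.run_mcmc(data, d.PriorConfig(),
                        d.SamplerConfig(seed=1, iterations=300, burn_in=0))
        s2 = d.run_mcmc(data, d.PriorConfig(),
                        d.SamplerConfig(seed=2, iterations=300, burn_in=0))
        assert not np.array_equal(s1.alpha, s2.alpha)


class TestGatingInvariant:
    def test_zeta_zero_implies_beta_zero_in_every_draw(self):
        data = _tiny_data(seed=3)
        s = d.run_mcmc(data, d.PriorConfig(),
                       d.SamplerConfig(seed=5, iterations=2000, burn_in=0))
        assert np.all(s.beta[s.zeta == 0] == 0.0)
        assert np.array_equal(s.n_active,
                              s.zeta.reshape(s.n_draws, -1).sum(axis=1))


class TestPriorRecovery:
    def test_marginal_inclusion_matches_beta_binomial(
            self, prior_only_samples):
        """Likelihood off, a=b=1: P(zeta=1) = 1/2 within 3 MC ses."""
        s = prior_only_samples
        series = s.zeta.reshape(s.n_draws, -1).mean(axis=1)
        se = d.mcse_mean(series)
        assert abs(series.mean() - 0.5) <= 3 * se

    def test_alpha_recovers_prior_moments(self, prior_only_samples):
        s = prior_only_samples
        sd = float(np.asarray(s.alpha).std())
        target = math.sqrt(10.0)
        assert abs(sd - target) / target < 0.05

    def test_active_beta_recovers_slab_moments(self, prior_only_samples):
        s = prior_only_samples
        vals = s.beta[s.zeta == 1]
        assert abs(vals.std() - math.sqrt(10.0)) / math.sqrt(10.0) < 0.05


class TestExhaustivePosterior:
    def test_model_frequencies_match_quadrature(self, tiny_posterior):
        """MCMC model-visit frequencies vs deterministic grid quadrature
        on the 4-model two-leaf problem, within 3 MC standard errors."""
        tp = tiny_posterior
        for m in range(4):
            diff = abs(tp["freqs"][m] - tp["oracle_probs"][m])
            assert diff <= 3 * tp["mcses"][m] + 1e-12, \
                f"model {m}: diff {diff:.4f} > 3*mcse {3*tp['mcses'][m]:.4f}"

    def test_reversibility_of_model_transitions(self, tiny_posterior):
        """Detailed-balance smoke test: i->j and j->i transition counts
        agree within Poisson-scale error on the stationary chain."""
        mid = tiny_posterior["model_id"]
        trans = np.zeros((4, 4))
        np.add.at(trans, (mid[:-1], mid[1:]), 1)
        for i in range(4):
            for j in range(i + 1, 4):
                nij, nji = trans[i, j], trans[j, i]
                tot = nij + nji
                if tot < 10:
                    continue
                assert abs(nij - nji) <= 4 * math.sqrt(tot), (i, j)


class TestStepFunctions:
    def test_between_model_step_returns_valid_state(self):
        data = _tiny_data(seed=4)
        state = d.ModelState.empty(data.B, data.P)
        rng = np.random.default_rng(0)
        out = d.between_model_step(state, data, d.PriorConfig(),
                                   d.SamplerConfig(seed=1), rng)
        out.validate()

    def test_within_model_step_keeps_zeta(self):
        data = _tiny_data(seed=4)
        zeta = np.zeros((data.B, data.P), dtype=int)
        zeta[1, 0] = 1
        state = d.ModelState(alpha=np.zeros(data.B),
                             beta=np.where(zeta, 0.2, 0.0), zeta=zeta)
        rng = np.random.default_rng(0)
        out = d.within_model_step(state, data, d.PriorConfig(),
                                  d.SamplerConfig(seed=1), rng)
        assert np.array_equal(out.zeta, state.zeta)
        out.validate()


def test_samples_roundtrip_hdf5_and_csv(tmp_path):
    data = _tiny_data(seed=5)
    s = d.run_mcmc(data, d.PriorConfig(),
                   d.SamplerConfig(seed=7, iterations=200, burn_in=50))
    path = tmp_path / "samples.h5"
    s.save_hdf5(path)
    s2 = d.McmcSamples.load_hdf5(path)
    assert np.array_equal(s.beta, s2.beta)
    assert s2.burn_in == s.burn_in
    assert s2.branch_labels == s.branch_labels
    s.to_coda_csv(tmp_path / "samples.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "samples.csv")
    assert len(df) == s.n_draws
    assert "log_posterior" in df.columns
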