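"""Sampler correctness and the behaviour of the intake posterior."""

import math

import numpy as np
import pytest

from otrisk.errors import DomainError, NumericalError, ValidationError
from otrisk.hbm import get_study
from otrisk.reconstruct import (ExposureReconstruction, ReconstructionConfig,
                                differential_evolution_mc, effective_sample_size,
                                gelman_rubin, log_posterior, metropolis_hastings)


class TestMetropolisHastings:
    @staticmethod
    def lognormal_target(point):
        x = point[0]
        if x <= 0:
            return -math.inf
        z = math.log(x)
        return -math.log(x) - 0.5 * z * z  # standard lognormal, constants dropped

    def test_recovers_analytic_moments(self):
        rng = np.random.default_rng(7)
        chain, _, acc = metropolis_hastings(self.lognormal_target, np.array([1.0]),
                                            50000, 2.4, rng)
        log_draws = np.log(chain[5000:, 0])
        ess = effective_sample_size(chain[None, 5000:, 0])
        se = 1.0 / math.sqrt(ess)
        assert abs(log_draws.mean()) < 3 * se
        assert log_draws.std() == pytest.approx(1.0, rel=0.05)
        assert 0.2 < acc < 0.8

    def test_degenerate_proposal_accepts_everything(self):
        rng = np.random.default_rng(0)
        chain, _, acc = metropolis_hastings(self.lognormal_target, np.array([2.0]),
                                            500, 1e-12, rng)
        assert acc > 0.999
        assert np.var(np.log(chain[:, 0])) < 1e-20

    def test_same_seed_identical_chains(self):
        chains = [metropolis_hastings(self.lognormal_target, np.array([1.0]), 1000,
                                      1.0, np.random.default_rng(123))[0]
                  for _ in range(2)]
        np.testing.assert_array_equal(chains[0], chains[1])

    def test_zero_acceptance_raises_diagnostics_error(self):
        def needle(point):  # sharp spike at 1; any move is astronomically worse
            return -1e8 * abs(math.log(point[0]))

        with pytest.raises(NumericalError, match="proposal_scale"):
            metropolis_hastings(needle, np.array([1.0]), 200, 50.0,
                                np.random.default_rng(1))

    def test_invalid_init_rejected(self):
        with pytest.raises(DomainError):
            metropolis_hastings(self.lognormal_target, np.array([-1.0]), 10, 1.0,
                                np.random.default_rng(0))


def test_differential_evolution_sampler_contract():
    def target(point):
        z = math.log(point[0])
        return -math.log(point[0]) - 0.5 * z * z

    rng = np.random.default_rng(5)
    init = np.exp(rng.standard_normal((6, 1)) * 0.5)
    chains, _, acc = differential_evolution_mc(target, init, 4000, rng)
    log_draws = np.log(chains[1000:, :, 0].ravel())
    assert abs(log_draws.mean()) < 0.1
    assert log_draws.std() == pytest.approx(1.0, rel=0.1)
    assert acc > 0.1


class TestLogPosterior:
    def setup_method(self):
        self.config = ReconstructionConfig(seed=0)
        self.forward = lambda d, mbw, mmet: d * 1000.0 / mbw

    def test_zero_residual_hits_lognormal_density_maximum(self):
        observed = 10.0
        lp = log_posterior(0.01, (1.0, 1.0), observed, self.forward,
                           self.config, prior_median=0.01)
        # analytic decomposition at the zero-residual point: likelihood at its
        # lognormal maximum plus the three prior densities at their medians
        sigma_err = math.log(self.config.error_gsd)
        sigma_n = math.sqrt(math.log1p(0.3 ** 2))
        max_loglik = -math.log(observed * sigma_err * math.sqrt(2 * math.pi))
        prior_intake = -math.log(0.01 * math.log(3.0) * math.sqrt(2 * math.pi))
        prior_nuisance = -2.0 * math.log(sigma_n * math.sqrt(2 * math.pi))
        assert lp == pytest.approx(max_loglik + prior_intake + prior_nuisance,
                                   rel=1e-9)
        # and any nonzero residual scores lower
        lp_off = log_posterior(0.02, (1.0, 1.0), observed, self.forward,
                               self.config, prior_median=0.02)
        assert lp_off < lp + (-math.log(0.02) + math.log(0.01)) + 1e-9

    def test_support_boundary(self):
        assert log_posterior(0.0, (1.0, 1.0), 10.0, self.forward,
                             self.config, 0.01) == -math.inf
        assert log_posterior(1e-300, (1.0, 1.0), 10.0, self.forward,
                             self.config, 0.01) < -100

    def test_scale_invariance_of_likelihood_in_linear_regime(self):
        lp1 = log_posterior(0.01, (1.0, 1.0), 10.0, self.forward,
                            self.config, prior_median=0.01)
        lp2 = log_posterior(0.02, (1.0, 1.0), 20.0, self.forward,
                            self.config, prior_median=0.02)
        # likelihood term unchanged; prior term identical by construction;
        # only the lognormal normalisations 1/x and 1/y shift, by -2 log 2
        assert lp2 - lp1 == pytest.approx(-2 * math.log(2.0), rel=1e-9)

    def test_forward_failure_gives_minus_infinity(self):
        def broken(d, mbw, mmet):
            raise RuntimeError("boom")

        with pytest.warns(UserWarning, match="forward model failed"):
            lp = log_posterior(0.01, (1.0, 1.0), 10.0, broken, self.config, 0.01)
        assert lp == -math.inf


class TestDiagnostics:
    def test_gelman_rubin_mixed_chains_near_one(self):
        rng = np.random.default_rng(3)
        chains = np.exp(rng.standard_normal((4, 2000)))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_gelman_rubin_detects_disagreement(self):
        rng = np.random.default_rng(3)
        chains = np.exp(rng.standard_normal((4, 500)))
        chains[0] *= 50.0
        assert gelman_rubin(chains) > 1.5

    def test_ess_below_n_for_correlated_chain(self):
        rng = np.random.default_rng(0)
        x = np.empty(4000)
        x[0] = 0.0
        for i in range(1, 4000):
            x[i] = 0.95 * x[i - 1] + rng.standard_normal()
        ess = effective_sample_size(np.exp(x[None, :]))
        assert ess < 1500


class TestReconstructionModel:
    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ReconstructionConfig(prior_gsd=0.9)
        with pytest.raises(ValidationError):
            ReconstructionConfig(uncertainty_cv=-0.1)
        with pytest.raises(ValidationError):
            ReconstructionConfig(sampler="nuts")

    def test_seeded_determinism(self, worker_forward_map, fast_config):
        study = get_study("labat")
        model = ExposureReconstruction.from_study(
            study, "mean", config=fast_config, forward_map=worker_forward_map)
        r1, r2 = model.fit(), model.fit()
        np.testing.assert_array_equal(r1.draws, r2.draws)
        assert model.fit(seed=99).median != r1.median

    def test_posterior_median_monotone_in_observation(self, worker_forward_map,
                                                      fast_config):
        medians = []
        for obs in (100.0, 300.0, 900.0):
            model = ExposureReconstruction(obs, "post_shift_spot",
                                           config=fast_config,
                                           forward_map=worker_forward_map)
            medians.append(model.fit().median)
        assert medians[0] < medians[1] < medians[2]

    def test_noiseless_self_consistency(self, worker_forward_map, fast_config):
        """Observation generated at the prior median is recovered."""
        truth = 0.01
        obs = worker_forward_map(truth) * 1e3  # ug/L
        import dataclasses

        config = dataclasses.replace(fast_config, prior_median=truth)
        model = ExposureReconstruction(obs, "post_shift_spot", config=config,
                                       forward_map=worker_forward_map)
        result = model.fit()
        assert result.median == pytest.approx(truth, rel=0.10)

    def test_worker_reconstruction_below_mass_balance(self, worker_forward_map,
                                                      fast_config):
        """Post-shift samples overshoot steady state, so inverting them with
        the dynamic model must give less intake than the mass balance."""
        study = get_study("labat")
        model = ExposureReconstruction.from_study(
            study, "mean", config=fast_config, forward_map=worker_forward_map)
        result = model.fit()
        assert result.median < result.mass_balance_estimate

    def test_summary_renders(self, worker_forward_map, fast_config):
        model = ExposureReconstruction.from_study(
            get_study("labat"), "mean", config=fast_config,
            forward_map=worker_forward_map)
        text = model.fit().summary()
        assert "posterior median" in text and "R-hat" in text

    def test_missing_statistic_raises(self, fast_config):
        with pytest.raises(KeyError, match="p95"):
            ExposureReconstruction.from_study(get_study("eitaki"), "p95",
                                              config=fast_config)
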