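"""Synthetic cohort generator: determinism, distributional structure, recovery."""

import dataclasses
import math

import numpy as np
import pytest

from otrisk.errors import ValidationError
from otrisk.reconstruct import ReconstructionConfig, cv_to_sigma
from otrisk.synthetic import (SyntheticCohortSpec, generate_cohort,
                              recovery_experiment)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_subjects": 0}, {"true_intake_median": 0.0}, {"intake_gsd": 0.5},
        {"bw_cv": -0.1}, {"generator": "magic"}, {"population": "pets"},
    ])
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValidationError):
            SyntheticCohortSpec(**kwargs)

    def test_sampling_plan_matches_generator(self):
        assert SyntheticCohortSpec(generator="fast").sampling_plan == "steady_state_spot"
        assert SyntheticCohortSpec(generator="pbpk").sampling_plan == "post_shift"
        assert SyntheticCohortSpec(population="general").sampling_plan == "pool"


class TestGeneration:
    def test_noiseless_cohort_reproduces_mass_balance_inverse(self):
        spec = SyntheticCohortSpec(n_subjects=4, true_intake_median=0.014943,
                                   intake_gsd=1.0, bw_cv=0.0, metabolic_cv=0.0,
                                   measurement_gsd=1.0, seed=9)
        frame, summary = generate_cohort(spec)
        np.testing.assert_allclose(frame["observed"], 523.005, rtol=1e-4)
        assert summary.stats["sd"] == 0.0

    def test_same_seed_identical_cohort(self):
        spec = SyntheticCohortSpec(seed=11)
        f1, s1 = generate_cohort(spec)
        f2, s2 = generate_cohort(spec)
        assert f1.equals(f2) and s1 == s2
        f3, _ = generate_cohort(dataclasses.replace(spec, seed=12))
        assert not f1["observed"].equals(f3["observed"])

    def test_positive_and_summary_valid(self):
        _, summary = generate_cohort(SyntheticCohortSpec(seed=4))
        assert all(v >= 0 for v in summary.stats.values())
        assert summary.stats["max"] >= summary.stats["median"]

    def test_composed_gsd_matches_lognormal_closure(self):
        """Concentration GSD composes the intake, body-weight and noise GSDs."""
        spec = SyntheticCohortSpec(n_subjects=20000, intake_gsd=2.0,
                                   measurement_gsd=1.3, seed=21)
        frame, _ = generate_cohort(spec)
        sigma2 = (math.log(2.0) ** 2 + cv_to_sigma(0.30) ** 2
                  + math.log(1.3) ** 2)
        observed_gsd = math.exp(np.std(np.log(frame["observed"]), ddof=1))
        assert observed_gsd == pytest.approx(math.exp(math.sqrt(sigma2)), rel=0.05)

    def test_pbpk_generator_small_cohort(self):
        spec = SyntheticCohortSpec(n_subjects=3, generator="pbpk", seed=2,
                                   measurement_gsd=1.0)
        frame, summary = generate_cohort(spec)
        assert (frame["observed"] > 0).all()
        assert summary.sample_type == "post_shift_spot"

    def test_general_population_units(self):
        spec = SyntheticCohortSpec(population="general", true_intake_median=1.2e-6,
                                   n_subjects=10, seed=3)
        _, summary = generate_cohort(spec)
        assert summary.unit == "ng_per_24h"


class TestRecovery:
    def test_noiseless_linear_case_recovers_truth(self, steady_state_forward_map):
        spec = SyntheticCohortSpec(n_subjects=20, intake_gsd=1.0, bw_cv=0.0,
                                   metabolic_cv=0.0, measurement_gsd=1.0, seed=5)
        config = ReconstructionConfig(n_iterations=3000, burn_in=800, n_chains=2)
        report = recovery_experiment(spec, config, n_replicates=3,
                                     forward_map=steady_state_forward_map)
        assert abs(report.relative_bias) < 0.10
        assert report.coverage == 1.0

    def test_measurement_noise_widens_credible_interval(self, steady_state_forward_map):
        """Matching the error model to the assay GSD, more noise -> wider CI."""
        widths = []
        for gsd in (1.05, 1.5, 2.5):
            spec = SyntheticCohortSpec(n_subjects=30, measurement_gsd=gsd, seed=8)
            config = ReconstructionConfig(n_iterations=4000, burn_in=1000,
                                          n_chains=2, error_gsd=gsd + 1e-9)
            report = recovery_experiment(spec, config, n_replicates=1,
                                         forward_map=steady_state_forward_map)
            widths.append(float((report.ci_upper[0] - report.ci_lower[0])
                                / report.posterior_medians[0]))
        assert widths[0] < widths[1] < widths[2]

    def test_report_summary_text(self, steady_state_forward_map):
        spec = SyntheticCohortSpec(seed=1)
        report = recovery_experiment(
            spec, ReconstructionConfig(n_iterations=1000, burn_in=300, n_chains=2),
            n_replicates=2, forward_map=steady_state_forward_map)
        assert "relative bias" in report.summary()
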