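"""PBPK model: conservation, analytic limits, independent-integrator oracle."""

import dataclasses

import numpy as np
import pytest

from otrisk import massbalance as mb
from otrisk.errors import DomainError, ValidationError
from otrisk.pbpk import (ExposureScenario, PbpkModel, PbpkParameterSet,
                         build_model, dose_response_linearity_check,
                         general_scenario, urinary_concentration_at_sampling,
                         worker_scenario)
from otrisk.physiology import TISSUES, Physiology


def test_parameter_defaults_echo_published_values(default_model):
    p = default_model.params
    assert p.partition["GI"] == 3.8 and p.partition["gonads"] == 0.79
    assert p.partition_met["fat"] == 0.18
    assert p.km == 27.2 and p.vmax == 2835.3
    assert p.cl_kidney_parent == 0.0 and p.cl_kidney_met == 0.17
    assert p.f_plasma_bound == 0.035 and p.f_met_plasma_bound == 0.95
    assert p.f_transform == 1.0 and p.f_abs_gi == 1.0 and p.k_abs_gi == 1.0


@pytest.mark.parametrize("kwargs", [
    {"km": 0.0}, {"vmax": -1.0}, {"f_met_plasma_bound": 1.5},
    {"partition": {t: 1.0 for t in TISSUES[:-1]}},
])
def test_parameter_validation(kwargs):
    with pytest.raises(ValidationError):
        PbpkParameterSet(**kwargs)


def test_physiology_flow_consistency_enforced():
    phys = Physiology()
    bad_flows = dict(phys.tissue_blood_flows)
    bad_flows["muscle"] *= 2.0
    with pytest.raises(ValidationError):
        Physiology(tissue_blood_flows=bad_flows)


def test_null_exposure_everything_zero(default_model):
    res = default_model.simulate(worker_scenario(0.0, n_days=1), output_dt=0.5)
    assert np.all(res.conc_parent_blood == 0)
    assert np.all(res.conc_met_blood == 0)
    assert np.all(res.cumulative_biomarker_mg == 0)
    assert urinary_concentration_at_sampling(res, "post_shift") == 0.0


def test_switched_off_metabolism_gives_no_urinary_biomarker():
    params = PbpkParameterSet(vmax=0.0)
    model = build_model(params)
    res = model.simulate(worker_scenario(1.0, n_days=1), output_dt=0.5)
    assert res.cumulative_biomarker_mg[-1] == pytest.approx(0.0, abs=1e-12)
    assert res.conc_parent_blood[-1] > 0  # parent accumulates instead


def test_mass_conservation_and_nonnegativity(default_model):
    res = default_model.simulate(worker_scenario(0.5, n_days=3))
    assert res.mass_balance_error() < 1e-6
    for series in (res.conc_parent_blood, res.conc_met_blood,
                   res.cumulative_biomarker_mg):
        assert np.all(series >= 0)
    assert np.all(np.diff(res.cumulative_biomarker_mg) >= -1e-12)


def test_steady_state_urinary_recovery_matches_calibration(default_model):
    res = default_model.simulate(general_scenario(0.01, n_days=6), output_dt=0.5)
    daily_dose_mg = 0.01 * default_model.phys.bw
    pool = urinary_concentration_at_sampling(res, "pool")
    assert pool / daily_dose_mg == pytest.approx(
        default_model.params.biomarker_recovery, rel=0.01)


def test_one_compartment_analytic_limit():
    """Single effective compartment: uniform partition, linear renal clearance,
    near-instant perfusion -> C(t) = R/CL * (1 - exp(-CL t / V_eff))."""
    part = {t: 2.0 for t in TISSUES}
    params = PbpkParameterSet(partition=part, partition_met=part, vmax=0.0,
                              cl_kidney_parent=0.1, cl_kidney_met=0.0,
                              f_plasma_bound=0.0, f_rbc_bound=0.0)
    phys = Physiology()
    fast = Physiology(
        cardiac_output=phys.cardiac_output * 1000,
        tissue_blood_flows={t: q * 1000 for t, q in phys.tissue_blood_flows.items()})
    model = PbpkModel(params, fast)
    c_air = 1.0
    scenario = ExposureScenario(route="inhalation", magnitude=c_air,
                                schedule=((0.0, 24.0),), days_per_week=7,
                                n_days=2, sampling="pool")
    res = model.simulate(scenario, output_dt=0.5)
    rate = c_air * fast.ventilation_rate           # mg/h into blood
    cl = 0.1 * 60.0                                # L/h
    v_eff = fast.blood_volume + 2.0 * sum(fast.tissue_volumes.values())
    t = res.t[res.t >= 1.0]
    expected = rate / cl * (1.0 - np.exp(-cl * t / v_eff))
    np.testing.assert_allclose(res.conc_parent_blood[res.t >= 1.0], expected,
                               rtol=1e-3)


def test_doubling_volumes_and_flows_halves_flow_limited_steady_state():
    """With metabolism far above the flow-limited ceiling, hepatic clearance
    equals liver blood flow, so scaling the body doubles clearance."""
    params = dataclasses.replace(PbpkParameterSet(), vmax=2835.3e3)
    phys = Physiology()
    doubled = Physiology(
        bw=phys.bw * 2, cardiac_output=phys.cardiac_output * 2,
        tissue_volumes={t: v * 2 for t, v in phys.tissue_volumes.items()},
        tissue_blood_flows={t: q * 2 for t, q in phys.tissue_blood_flows.items()},
        blood_volume=phys.blood_volume * 2)
    scenario = ExposureScenario(route="inhalation", magnitude=0.5,
                                schedule=((0.0, 24.0),), days_per_week=7,
                                n_days=10, sampling="pool")
    c1 = PbpkModel(params, phys).simulate(scenario, output_dt=1.0).conc_parent_blood[-1]
    c2 = PbpkModel(params, doubled).simulate(scenario, output_dt=1.0).conc_parent_blood[-1]
    assert c2 / c1 == pytest.approx(0.5, rel=0.01)


def test_fixed_step_rk4_equivalence(default_model):
    """Independent explicit integrator at refined step reproduces the stiff
    solver on a small instance."""
    scenario = worker_scenario(0.5, n_days=1)
    res = default_model.simulate(scenario, output_dt=1.0)

    dt = 0.001
    y = np.zeros(31)
    segments = default_model._input_rates(scenario)
    checkpoints = {}
    for t0, t1, r_inh, r_oral in segments:
        n = int(round((t1 - t0) / dt))
        t = t0
        for _ in range(n):
            k1 = default_model._rhs(t, y, r_inh, r_oral)
            k2 = default_model._rhs(t + dt / 2, y + dt / 2 * k1, r_inh, r_oral)
            k3 = default_model._rhs(t + dt / 2, y + dt / 2 * k2, r_inh, r_oral)
            k4 = default_model._rhs(t + dt, y + dt * k3, r_inh, r_oral)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        checkpoints[round(t, 6)] = y.copy()
    y_end = checkpoints[24.0]
    i_end = np.searchsorted(res.t, 24.0)
    p = default_model.params
    conc_ref = y_end[1] / default_model.phys.blood_volume * p.mw_parent / 1e3
    biomarker_ref = y_end[25] * p.mw_parent / 1e3 * p.biomarker_recovery
    assert res.conc_parent_blood[i_end] == pytest.approx(conc_ref, rel=1e-3)
    assert res.cumulative_biomarker_mg[i_end] == pytest.approx(biomarker_ref, rel=1e-3)


def test_post_shift_void_exceeds_next_morning(default_model):
    res = default_model.simulate(worker_scenario(0.5, n_days=2), output_dt=0.5)
    post_shift_day1 = urinary_concentration_at_sampling(res, ("void", 14.0))
    next_morning = urinary_concentration_at_sampling(res, ("void", 30.0))
    assert post_shift_day1 > next_morning


def test_weekly_accumulation_monotone(default_model):
    c_air = 0.5
    res5 = default_model.simulate(worker_scenario(c_air, n_days=5), output_dt=0.5)
    res1 = default_model.simulate(worker_scenario(c_air, n_days=1), output_dt=0.5)
    assert (urinary_concentration_at_sampling(res5, "post_shift")
            >= urinary_concentration_at_sampling(res1, "post_shift"))


class TestLinearity:
    def scenario_factory(self, d):
        return worker_scenario(mb.air_from_intake(d), n_days=3)

    def test_linear_in_biomonitoring_range(self, default_model):
        dev = dose_response_linearity_check(
            default_model, self.scenario_factory, [1e-5, 1e-3, 0.03, 0.05])
        assert dev < 0.01

    def test_identical_doses_zero_deviation(self, default_model):
        dev = dose_response_linearity_check(
            default_model, self.scenario_factory, [0.01, 0.01])
        assert dev == 0.0

    def test_saturation_detected_at_extreme_doses(self, default_model):
        dev = dose_response_linearity_check(
            default_model, self.scenario_factory, [1e-3, 30.0, 100.0])
        assert dev > 0.1

    def test_nonpositive_grid_rejected(self, default_model):
        with pytest.raises(DomainError):
            dose_response_linearity_check(default_model, self.scenario_factory,
                                          [0.0, 1.0])


class TestScenarioAndSampling:
    def test_schedule_validation(self):
        with pytest.raises(ValidationError):
            ExposureScenario(route="inhalation", magnitude=1.0,
                             schedule=((2.0, 10.0), (8.0, 12.0)))
        with pytest.raises(ValidationError):
            ExposureScenario(route="inhalation", magnitude=1.0, schedule=((8.0, 30.0),))
        with pytest.raises(ValidationError):
            ExposureScenario(route="swim", magnitude=1.0)

    def test_unknown_void_raises(self, default_model):
        res = default_model.simulate(worker_scenario(0.1, n_days=1), output_dt=0.5)
        with pytest.raises(DomainError):
            urinary_concentration_at_sampling(res, ("void", 13.0))

    def test_pool_equals_final_day_mass(self, default_model):
        res = default_model.simulate(general_scenario(0.01, n_days=3), output_dt=0.5)
        pool = urinary_concentration_at_sampling(res, "pool")
        m = res.cumulative_biomarker_mg
        day_start = np.searchsorted(res.t, 48.0)
        assert pool == pytest.approx(m[-1] - m[day_start], rel=1e-9)
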