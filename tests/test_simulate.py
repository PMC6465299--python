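"""Synthetic-assay generator contracts: determinism, zero-noise transparency,
Monte-Carlo consistency, and limiting behaviors."""

import numpy as np
import pandas as pd
import pytest

from hergqc import estimators, kinetics
from hergqc.params import NOISELESS, KineticParams, NoiseModel, ParameterError, PHMixtureSpec
from hergqc.simulate import (
    simulate_chx,
    simulate_pulse_chase,
    simulate_surface_pools,
    simulate_vesicle_ph,
)


def test_same_seed_gives_byte_identical_tables(wt_params, default_noise):
    a = simulate_pulse_chase(wt_params, default_noise, n_reps=5, seed=7)
    b = simulate_pulse_chase(wt_params, default_noise, n_reps=5, seed=7)
    pd.testing.assert_frame_equal(a.data, b.data)
    c = simulate_surface_pools(wt_params, (0, 1, 2, 3), "internalization", default_noise, seed=3)
    d = simulate_surface_pools(wt_params, (0, 1, 2, 3), "internalization", default_noise, seed=3)
    pd.testing.assert_frame_equal(c.data, d.data)
    mix = PHMixtureSpec(((1.0, 6.5, 0.2),))
    assert np.array_equal(
        simulate_vesicle_ph(mix, 100, seed=5).ph_values,
        simulate_vesicle_ph(mix, 100, seed=5).ph_values,
    )
    e = simulate_chx(wt_params, 41, (0, 1, 2), default_noise, seed=9)
    f = simulate_chx(wt_params, 41, (0, 1, 2), default_noise, seed=9)
    pd.testing.assert_frame_equal(e.data, f.data)


def test_different_seed_changes_noisy_output(wt_params, default_noise):
    a = simulate_pulse_chase(wt_params, default_noise, n_reps=5, seed=1)
    b = simulate_pulse_chase(wt_params, default_noise, n_reps=5, seed=2)
    assert not a.data.equals(b.data)


def test_noiseless_pulse_chase_reproduces_analytic_maturation(wt_params):
    table = simulate_pulse_chase(wt_params, NOISELESS, n_reps=3, seed=0)
    res = estimators.maturation_from_table(table)
    cg, fg = kinetics.solve_cohort_kinetics(wt_params, [0.0, 3.0])
    analytic = 100.0 * fg[1] / (cg[0] - cg[1])
    assert res.mean_pct == pytest.approx(analytic, rel=1e-6)
    assert res.sem_pct == pytest.approx(0.0, abs=1e-9)


def test_noiseless_fraction_remaining_matches_pool_sum(wt_params):
    table = simulate_pulse_chase(wt_params, NOISELESS, n_reps=3, seed=0)
    res = estimators.fraction_remaining(table)
    cg, fg = kinetics.solve_cohort_kinetics(wt_params, [3.0])
    assert res.mean_pct == pytest.approx(100.0 * (cg[0] + fg[0]), rel=1e-6)


def test_noisy_maturation_estimate_is_monte_carlo_consistent(wt_params):
    table = simulate_pulse_chase(wt_params, NoiseModel(cv_band=0.1), n_reps=200, seed=11)
    res = estimators.maturation_from_table(table)
    cg, fg = kinetics.solve_cohort_kinetics(wt_params, [0.0, 3.0])
    analytic = 100.0 * fg[1] / (cg[0] - cg[1])
    assert res.mean_pct == pytest.approx(analytic, abs=1.0)


def test_frozen_surface_when_internalization_is_zero():
    p = KineticParams("x", 0.5, 0.3, 0.0, 0.02, 0.005, 0.1)
    tc = simulate_surface_pools(p, (0, 2, 4, 7), "internalization", NOISELESS, seed=0)
    sig = tc.data[~tc.data["is_background"]]["signal"]
    assert np.allclose(sig, sig.iloc[0])


def test_no_recycling_limit_decays_at_exactly_k_int():
    p = KineticParams("x", 0.5, 0.3, 0.02, 0.0, 5.0, 0.1)  # k_rec = 0, fast lysosomal exit
    tc = simulate_surface_pools(p, tuple(range(8)), "internalization", NOISELESS, seed=0)
    fit = estimators.surface_decay_fit(tc)
    assert fit.rate == pytest.approx(p.k_int, rel=1e-6)


def test_recycling_assay_zero_when_no_recycling():
    p = KineticParams("x", 0.5, 0.3, 0.05, 0.0, 0.02, 0.1)
    rt = simulate_surface_pools(p, (5.0, 10.0, 20.0), "recycling", NOISELESS, seed=0)
    assert estimators.recycling_percent(rt, 10.0) == 0.0


def test_wt_preset_noiseless_reproduces_calibration_targets(preset_lib, wt_params):
    targets = preset_lib.get("WT").targets
    tc = simulate_surface_pools(wt_params, tuple(range(8)), "internalization", NOISELESS, seed=0)
    assert estimators.percent_internalized(tc, 5.0) == pytest.approx(
        targets.pct_internalized_5min, rel=2e-2
    )
    course = simulate_surface_pools(wt_params, (1.5, 3.0, 4.5, 6.0), "turnover", NOISELESS, seed=0)
    assert estimators.surface_decay_fit(course).half_life == pytest.approx(
        targets.surface_half_life_h, rel=2e-2
    )


def test_vesicle_sampling_law_of_large_numbers():
    mix = PHMixtureSpec(((1.0, 6.69, 0.25),))
    vs = simulate_vesicle_ph(mix, 500, seed=123)
    assert vs.ph_values.mean() == pytest.approx(6.69, abs=3 * 0.25 / np.sqrt(500))
    sym = PHMixtureSpec(((0.5, 5.0, 0.1), (0.5, 7.0, 0.1)))
    vs2 = simulate_vesicle_ph(sym, 4000, seed=5)
    assert vs2.ph_values.mean() == pytest.approx(6.0, abs=0.1)


def test_vesicle_sampling_respects_truncation_and_single_component():
    mix = PHMixtureSpec(((1.0, 4.1, 0.8),))
    vs = simulate_vesicle_ph(mix, 2000, seed=1)
    assert vs.ph_values.min() >= 3.5 and vs.ph_values.max() <= 8.0
    one = PHMixtureSpec(((1.0, 6.0, 0.05), (0.0, 4.5, 0.2)))
    vs2 = simulate_vesicle_ph(one, 300, seed=2)
    assert abs(vs2.ph_values.mean() - 6.0) < 0.05


def test_chx_noiseless_rate_ratio_equals_temp_factor(wt_params):
    t = (0.0, 1.0, 2.0, 4.0, 6.0)
    c37 = simulate_chx(wt_params, 37, t, NOISELESS, seed=0)
    c41 = simulate_chx(wt_params, 41, t, NOISELESS, seed=0)
    f37 = estimators.fit_single_exponential(c37.data["time_h"], c37.data["mature"])
    f41 = estimators.fit_single_exponential(c41.data["time_h"], c41.data["mature"])
    assert estimators.temperature_fold(f41, f37) == pytest.approx(
        wt_params.temp_factor, rel=1e-6
    )


def test_invalid_simulation_requests_rejected(wt_params, default_noise):
    with pytest.raises(ParameterError):
        simulate_surface_pools(wt_params, (), "internalization", default_noise)
    with pytest.raises(ParameterError):
        simulate_surface_pools(wt_params, (0, 1), "sorting", default_noise)
    with pytest.raises(ParameterError):
        simulate_pulse_chase(wt_params, default_noise, n_reps=0)
    with pytest.raises(ParameterError):
        simulate_chx(wt_params, 30, (0, 1), default_noise)
    with pytest.raises(ParameterError):
        simulate_vesicle_ph(PHMixtureSpec(((1.0, 6.5, 0.2),)), 0)
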