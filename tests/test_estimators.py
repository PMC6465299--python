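"""Assay estimator arithmetic, fit recovery, and scale-invariance properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hergqc import estimators
from hergqc.params import ParameterError
from hergqc.simulate import PulseChaseTable, RecyclingTable, SurfaceTimeCourse


def make_pulse_chase(rows):
    return PulseChaseTable(
        pd.DataFrame(rows, columns=["replicate", "chase_time_h", "cg_intensity", "fg_intensity"])
    )


@pytest.mark.parametrize(
    "cg0,cg3,fg3,expected",
    [(100.0, 20.0, 40.0, 50.0), (100.0, 50.0, 0.0, 0.0), (80.0, 30.0, 25.0, 50.0)],
)
def test_maturation_efficiency_formula(cg0, cg3, fg3, expected):
    assert estimators.maturation_efficiency(cg0, cg3, fg3) == pytest.approx(expected)


def test_maturation_efficiency_guards():
    with pytest.raises(ParameterError):
        estimators.maturation_efficiency(100.0, 100.0, 10.0)  # zero denominator
    with pytest.raises(ParameterError):
        estimators.maturation_efficiency(100.0, -1.0, 10.0)


@settings(max_examples=50, deadline=None)
@given(gain=st.floats(0.01, 1e4))
def test_maturation_efficiency_gel_exposure_invariance(gain):
    base = estimators.maturation_efficiency(100.0, 20.0, 40.0)
    scaled = estimators.maturation_efficiency(100.0 * gain, 20.0 * gain, 40.0 * gain)
    assert scaled == pytest.approx(base, rel=1e-9)


def test_fraction_remaining_examples():
    table = make_pulse_chase(
        [(0, 0.0, 100.0, 0.0), (0, 3.0, 30.0, 30.0), (1, 0.0, 100.0, 0.0), (1, 3.0, 60.0, 40.0)]
    )
    res = estimators.fraction_remaining(table)
    assert res.per_replicate_pct == (60.0, 100.0)
    assert res.mean_pct == pytest.approx(80.0)
    missing = make_pulse_chase([(0, 0.0, 100.0, 0.0)])
    with pytest.raises(ParameterError):
        estimators.fraction_remaining(missing)


def test_single_exponential_exact_inversion():
    t = np.array([0.0, 1.5, 3.0, 4.5, 6.0])
    y = 100.0 * np.exp(-0.099 * t)
    fit = estimators.fit_single_exponential(t, y)
    assert fit.half_life == pytest.approx(math.log(2) / 0.099, rel=1e-6)
    assert fit.amplitude == pytest.approx(100.0, rel=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
    assert fit.converged


def test_single_exponential_flat_signal_gives_infinite_half_life():
    t = np.array([0.0, 1.0, 2.0, 3.0])
    fit = estimators.fit_single_exponential(t, np.full(4, 50.0))
    assert math.isinf(fit.half_life)


def test_single_exponential_needs_three_distinct_times():
    with pytest.raises(ParameterError):
        estimators.fit_single_exponential([0.0, 1.0], [10.0, 5.0])


def test_single_exponential_noiseless_recovery_over_random_parameters():
    rng = np.random.default_rng(42)
    t = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0])
    for _ in range(100):
        a, k = rng.uniform(10.0, 500.0), rng.uniform(0.02, 1.5)
        fit = estimators.fit_single_exponential(t, a * np.exp(-k * t))
        assert fit.rate == pytest.approx(k, rel=1e-6)
        assert fit.amplitude == pytest.approx(a, rel=1e-6)


def test_single_exponential_noisy_recovery_median_error():
    # 5 time points x 4 wells, 10% multiplicative noise
    rng = np.random.default_rng(7)
    t_points = np.array([0.0, 1.5, 3.0, 4.5, 6.0])
    errors = []
    for _ in range(100):
        a, k = 100.0, rng.uniform(0.05, 0.5)
        t = np.repeat(t_points, 4)
        sigma = math.sqrt(math.log(1 + 0.1**2))
        y = a * np.exp(-k * t) * rng.lognormal(-sigma**2 / 2, sigma, t.size)
        fit = estimators.fit_single_exponential(t, y)
        errors.append(abs(fit.rate - k) / k)
    assert np.median(errors) < 0.15


def surface_course(times, means, bg=None, unit="min"):
    rows = []
    for t, m in zip(times, means):
        rows.append({"time": t, "well": "s0", "signal": m, "is_background": False})
        if bg is not None:
            rows.append({"time": t, "well": "b0", "signal": bg, "is_background": True})
    return SurfaceTimeCourse(pd.DataFrame(rows), time_unit=unit)


def test_background_subtract_example_and_clamp(caplog):
    df = pd.DataFrame(
        {
            "time": [0.0] * 6,
            "well": ["s0", "s1", "s2", "s3", "b0", "b1"],
            "signal": [10.0, 12.0, 11.0, 9.0, 2.0, 2.0],
            "is_background": [False] * 4 + [True] * 2,
        }
    )
    corrected, n_clamped = estimators.background_subtract(SurfaceTimeCourse(df))
    assert corrected["mean_signal"].iloc[0] == pytest.approx(8.5)
    assert n_clamped == 0
    # background exceeding the signal clamps to zero
    over = surface_course([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], bg=5.0)
    corrected, n_clamped = estimators.background_subtract(over)
    assert (corrected["mean_signal"] == 0.0).all() and n_clamped == 3


def test_background_subtract_without_background_wells_proceeds():
    tc = surface_course([0.0, 1.0], [10.0, 8.0])
    corrected, _ = estimators.background_subtract(tc)
    assert list(corrected["mean_signal"]) == [10.0, 8.0]


def test_percent_internalized_from_fitted_rate():
    k = 0.0103
    t = np.arange(8.0)
    tc = surface_course(t, 100.0 * np.exp(-k * t))
    pct = estimators.percent_internalized(tc, 5.0)
    assert pct == pytest.approx(100.0 * (1.0 - math.exp(-5 * k)), rel=1e-6)
    frozen = surface_course(t, np.full(8, 100.0))
    assert estimators.percent_internalized(frozen, 5.0) == pytest.approx(0.0, abs=1e-9)


def test_percent_internalized_monotone_in_rate():
    t = np.arange(8.0)
    pcts = [
        estimators.percent_internalized(surface_course(t, 100.0 * np.exp(-k * t)), 5.0)
        for k in (0.005, 0.01, 0.05, 0.2)
    ]
    assert all(a < b for a, b in zip(pcts, pcts[1:]))


def test_percent_internalized_rejects_hours_course():
    tc = surface_course([0.0, 1.5, 3.0], [100.0, 90.0, 80.0], unit="h")
    with pytest.raises(ParameterError):
        estimators.percent_internalized(tc)


def test_recycling_percent_examples():
    rt = RecyclingTable(
        pool_signal=200.0,
        data=pd.DataFrame({"time_min": [5.0, 10.0], "recycled_signal": [20.0, 50.0]}),
    )
    assert estimators.recycling_percent(rt, 10.0) == pytest.approx(25.0)
    assert estimators.recycling_percent(rt, 5.0) == pytest.approx(10.0)
    with pytest.raises(ParameterError):
        estimators.recycling_percent(rt, 7.0)


def test_normalize_to_mrna_and_wt():
    out = estimators.normalize_to_mrna_and_wt({"WT": 10.0, "M": 5.0}, {"WT": 1.0, "M": 1.0})
    by = {e.construct: e.pct_of_wt for e in out}
    assert by == {"WT": pytest.approx(100.0), "M": pytest.approx(50.0)}
    out2 = estimators.normalize_to_mrna_and_wt({"WT": 10.0, "M": 10.0}, {"WT": 1.0, "M": 2.0})
    assert {e.construct: e.pct_of_wt for e in out2}["M"] == pytest.approx(50.0)
    with pytest.raises(ParameterError):
        estimators.normalize_to_mrna_and_wt({"M": 5.0}, {"M": 1.0})
    with pytest.raises(ParameterError):
        estimators.normalize_to_mrna_and_wt({"WT": 1.0, "M": 5.0}, {"WT": 1.0, "M": 0.0})


@pytest.mark.parametrize(
    "ct_t,ct_r,cal,expected",
    [(20.0, 18.0, (20.0, 18.0), 1.0), (21.0, 18.0, (20.0, 18.0), 0.5), (18.0, 18.0, (20.0, 18.0), 4.0)],
)
def test_relative_mrna_ddct(ct_t, ct_r, cal, expected):
    assert estimators.relative_mrna(ct_t, ct_r, cal) == pytest.approx(expected)


def test_relative_mrna_requires_finite_ct():
    with pytest.raises(ParameterError):
        estimators.relative_mrna(float("nan"), 18.0, (20.0, 18.0))


def test_temperature_fold():
    f37 = estimators.ExpFitResult(0.10, math.log(2) / 0.10, 100.0, 0.99, True)
    f41 = estimators.ExpFitResult(0.11, math.log(2) / 0.11, 100.0, 0.99, True)
    assert estimators.temperature_fold(f41, f37) == pytest.approx(1.1)
    assert estimators.temperature_fold(f37, f37) == pytest.approx(1.0)
    flat = estimators.ExpFitResult(0.0, math.inf, 100.0, 0.0, True)
    with pytest.raises(ParameterError):
        estimators.temperature_fold(f41, flat)


@settings(max_examples=50, deadline=None)
@given(gain=st.floats(0.01, 100.0))
def test_ubiquitination_index_gain_invariance(gain):
    base = estimators.ubiquitination_index(4.0, 2.0, 3.0, 3.0)
    assert base == pytest.approx(2.0)
    scaled = estimators.ubiquitination_index(4.0 * gain, 2.0 * gain, 3.0 * gain, 3.0 * gain)
    assert scaled == pytest.approx(base, rel=1e-9)


def test_ubiquitination_index_examples():
    assert estimators.ubiquitination_index(3.0, 2.0, 3.0, 2.0) == pytest.approx(1.0)
    assert estimators.ubiquitination_index(6.0, 2.0, 3.0, 2.0) == pytest.approx(2.0)
    with pytest.raises(ParameterError):
        estimators.ubiquitination_index(1.0, 0.0, 1.0, 1.0)


def test_expression_correlation():
    x = np.array([10.0, 40.0, 70.0, 100.0])
    slope, intercept, r2 = estimators.expression_correlation(x, x)
    assert (slope, intercept, r2) == (pytest.approx(1.0), pytest.approx(0.0), pytest.approx(1.0))
    rng = np.random.default_rng(0)
    big = rng.uniform(0, 100, 500)
    _, _, r2_perm = estimators.expression_correlation(big, rng.permutation(big))
    assert r2_perm < 0.05
    with pytest.raises(ParameterError):
        estimators.expression_correlation([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ParameterError):
        estimators.expression_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
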