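"""ER-vs-peripheral loss partition: arithmetic, flags, ordering, end-to-end consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hergqc import estimators
from hergqc.decomposition import (
    ConstructSummary,
    decompose,
    qc_response,
    rank_and_tabulate,
    relative_metrics,
)
from hergqc.params import NoiseModel, ParameterError
from hergqc.simulate import simulate_pulse_chase


def test_decompose_neutral_wild_type():
    row = decompose(ConstructSummary("WT", 1.0, 1.0, 1.0))
    assert (row.er_loss_pct, row.peripheral_loss_pct, row.total_loss_pct) == (0.0, 0.0, 0.0)
    assert row.stability_flag == "neutral"


def test_decompose_mixed_losses():
    row = decompose(ConstructSummary("M", 0.6, 0.3, 2.0))
    assert row.er_loss_pct == pytest.approx(40.0)
    assert row.peripheral_loss_pct == pytest.approx(30.0)
    assert row.total_loss_pct == pytest.approx(70.0)
    assert row.stability_flag == "decreased"


def test_decompose_wt_like_maturation_reduced_surface():
    # WT-like ER processing with halved surface expression: all loss peripheral
    row = decompose(ConstructSummary("R56Q", 1.0, 0.5, 2.0))
    assert row.er_loss_pct == pytest.approx(0.0)
    assert row.peripheral_loss_pct == pytest.approx(50.0)
    assert row.total_loss_pct == pytest.approx(50.0)
    assert row.stability_flag == "decreased"


def test_decompose_super_wt_maturation_is_clamped():
    # maturation above WT clamps the ER loss at zero; the surplus shows up as a
    # negative peripheral loss, and the flag compares surface vs ER fractions
    row = decompose(ConstructSummary("M", 1.2, 1.1, 0.8))
    assert row.er_loss_pct == 0.0
    assert row.peripheral_loss_pct == pytest.approx(-10.0)
    assert row.stability_flag == "decreased"  # pm_rel < me_rel
    above = decompose(ConstructSummary("M", 0.9, 1.05, 0.8))
    assert above.er_loss_pct == pytest.approx(10.0)
    assert above.peripheral_loss_pct == pytest.approx(-15.0)
    assert above.stability_flag == "increased"


@settings(max_examples=200, deadline=None)
@given(
    me=st.floats(0.0, 1.5, allow_nan=False),
    pm=st.floats(0.0, 1.5, allow_nan=False),
)
def test_losses_are_exactly_additive(me, pm):
    row = decompose(ConstructSummary("x", me, pm, 1.0))
    assert row.er_loss_pct + row.peripheral_loss_pct == pytest.approx(
        row.total_loss_pct, abs=1e-9
    )
    assert row.total_loss_pct == pytest.approx(100.0 * (1.0 - pm), abs=1e-9)
    if me <= 1.0:
        assert 0.0 <= row.er_loss_pct <= 100.0


def test_qc_response_folds():
    assert qc_response(ConstructSummary("x", 0.25, 0.2, 4.0)).er_response_fold == pytest.approx(4.0)
    assert qc_response(ConstructSummary("x", 0.5, 0.2, 5.0)).peripheral_response_fold == 5.0
    wt = qc_response(ConstructSummary("WT", 1.0, 1.0, 1.0))
    assert (wt.er_response_fold, wt.peripheral_response_fold) == (1.0, 1.0)
    blocked = qc_response(ConstructSummary("x", 0.0, 0.1, 2.0))
    assert math.isinf(blocked.er_response_fold) and blocked.infinite_er_response


def test_rank_and_tabulate_orders_by_severity_with_alphabetical_ties():
    rows = [
        decompose(ConstructSummary("A", 0.5, 0.3, 1.0)),
        decompose(ConstructSummary("B", 0.9, 0.7, 1.0)),
        decompose(ConstructSummary("WT", 1.0, 1.0, 1.0)),
        decompose(ConstructSummary("C", 0.9, 0.7, 1.0)),
    ]
    ordered = rank_and_tabulate(rows)
    assert [r.construct for r in ordered] == ["WT", "B", "C", "A"]
    with pytest.raises(ParameterError):
        rank_and_tabulate([])


def test_relative_metrics_anchors_wild_type():
    out = relative_metrics(
        {"WT": 50.0, "M": 25.0},
        {"WT": 200.0, "M": 50.0},
        {"WT": 0.1, "M": 0.3},
    )
    by = {s.construct: s for s in out}
    assert (by["WT"].me_rel, by["WT"].pm_rel, by["WT"].turnover_fold) == (1.0, 1.0, 1.0)
    assert by["M"].me_rel == pytest.approx(0.5)
    assert by["M"].pm_rel == pytest.approx(0.25)
    assert by["M"].turnover_fold == pytest.approx(3.0)
    with pytest.raises(ParameterError):
        relative_metrics({"M": 25.0}, {"M": 50.0}, {"M": 0.3})
    with pytest.raises(ParameterError):
        relative_metrics({"WT": 0.0, "M": 25.0}, {"WT": 1.0, "M": 1.0}, {"WT": 1.0, "M": 1.0})


@settings(max_examples=50, deadline=None)
@given(gain_pm=st.floats(0.01, 100.0), gain_me=st.floats(0.01, 100.0))
def test_decomposition_invariant_to_instrument_gain(gain_pm, gain_me):
    raw_me = {"WT": 50.0, "M": 20.0}
    raw_pm = {"WT": 300.0, "M": 90.0}
    base = relative_metrics(raw_me, raw_pm, None)
    scaled = relative_metrics(
        {k: v * gain_me for k, v in raw_me.items()},
        {k: v * gain_pm for k, v in raw_pm.items()},
        None,
    )
    for s_base, s_scaled in zip(base, scaled):
        row_b, row_s = decompose(s_base), decompose(s_scaled)
        assert row_s.er_loss_pct == pytest.approx(row_b.er_loss_pct, rel=1e-9, abs=1e-9)
        assert row_s.total_loss_pct == pytest.approx(row_b.total_loss_pct, rel=1e-9, abs=1e-9)


def test_end_to_end_decomposition_recovers_generating_rates(preset_lib):
    # simulate -> estimate -> decompose for (WT, T65P) at 100 replicates must land
    # within Monte-Carlo error of the decomposition implied by the presets
    noise = NoiseModel(cv_band=0.1)
    me = {}
    for name in ("WT", "T65P"):
        table = simulate_pulse_chase(preset_lib.params(name), noise, n_reps=100, seed=88)
        me[name] = estimators.maturation_from_table(table).mean_pct
    pm = {name: preset_lib.get(name).pm_pct_of_wt for name in ("WT", "T65P")}
    summaries = {s.construct: s for s in relative_metrics(me, pm, None)}
    row = decompose(summaries["T65P"])

    wt_t, mut_t = preset_lib.get("WT").targets, preset_lib.get("T65P").targets
    expected_er = 100.0 * (1.0 - mut_t.maturation_pct / wt_t.maturation_pct)
    expected_total = 100.0 - preset_lib.get("T65P").pm_pct_of_wt
    assert row.er_loss_pct == pytest.approx(expected_er, abs=3.0)
    assert row.total_loss_pct == pytest.approx(expected_total, abs=3.0)
    assert row.peripheral_loss_pct == pytest.approx(expected_total - expected_er, abs=3.0)
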