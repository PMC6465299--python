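"""Quantitative assay readouts.

Implements the calculations applied to raw assay tables: pulse-chase
maturation efficiency FG3/(CG0 - CG3), fraction of labeled channel remaining,
plateau-zero single-exponential decay fits (surface turnover, internalization,
CHX chase), internalization and recycling percentages, isotype-background
subtraction, mRNA/WT normalization of expression, ddCt relative transcript
quantification, temperature fold-change of turnover, ubiquitination index,
and the expression correlation regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import ParameterError
from .simulate import PulseChaseTable, RecyclingTable, SurfaceTimeCourse

__all__ = [
    "MaturationResult",
    "ExpFitResult",
    "NormalizedExpression",
    "maturation_efficiency",
    "maturation_from_table",
    "fraction_remaining",
    "fit_single_exponential",
    "background_subtract",
    "surface_decay_fit",
    "percent_internalized",
    "recycling_percent",
    "normalize_to_mrna_and_wt",
    "relative_mrna",
    "temperature_fold",
    "ubiquitination_index",
    "expression_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaturationResult:
    per_replicate_pct: tuple
    mean_pct: float
    sem_pct: float


@dataclass(frozen=True)
class ExpFitResult:
    """Single-exponential decay fit A*exp(-rate*t) + plateau.

    ``rate`` carries the inverse of ``time_unit``; ``half_life`` is
    ln(2)/rate in the same unit (``inf`` for a flat signal).
    """

    rate: float
    half_life: float
    amplitude: float
    r_squared: float
    converged: bool
    time_unit: str = "h"


@dataclass(frozen=True)
class NormalizedExpression:
    construct: str
    raw_signal: float
    mrna_level: float
    pct_of_wt: float


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, sem


def maturation_efficiency(cg0: float, cg3: float, fg3: float) -> float:
    """Maturation efficiency 100 * FG3 / (CG0 - CG3), in percent.

    CG0 and CG3 are the core-glycosylated band intensities before and after
    the 3-h chase; FG3 is the complex-glycosylated band at 3 h. The
    denominator is the amount of nascent channel that left the ER pool.
    """
    if min(cg0, cg3, fg3) < 0:
        raise ParameterError("band intensities must be >= 0")
    if cg3 >= cg0:
        raise ParameterError(
            "CG3 >= CG0: no net ER-pool consumption (no ER exit or gel loading artifact)"
        )
    return 100.0 * fg3 / (cg0 - cg3)


def _paired_rows(table: PulseChaseTable, t0: float = 0.0, t1: float = 3.0) -> pd.DataFrame:
    df = table.data
    early = df[df["chase_time_h"] == t0].set_index("replicate")
    late = df[df["chase_time_h"] == t1].set_index("replicate")
    if early.empty or late.empty:
        raise ParameterError(f"pulse-chase table must contain t={t0} and t={t1} h rows")
    return early.join(late, lsuffix="_0", rsuffix="_3", how="inner")


def maturation_from_table(table: PulseChaseTable) -> MaturationResult:
    """Replicate-level maturation efficiencies, then mean +/- SEM across replicates."""
    paired = _paired_rows(table)
    per_rep = np.array(
        [
            maturation_efficiency(r.cg_intensity_0, r.cg_intensity_3, r.fg_intensity_3)
            for r in paired.itertuples()
        ]
    )
    mean, sem = _mean_sem(per_rep)
    return MaturationResult(tuple(per_rep), mean, sem)


def fraction_remaining(table: PulseChaseTable) -> MaturationResult:
    """Percent of total (mature + immature) labeled channel remaining after the chase."""
    paired = _paired_rows(table)
    per_rep = np.array(
        [
            100.0
            * (r.cg_intensity_3 + r.fg_intensity_3)
            / (r.cg_intensity_0 + r.fg_intensity_0)
            for r in paired.itertuples()
        ]
    )
    mean, sem = _mean_sem(per_rep)
    return MaturationResult(tuple(per_rep), mean, sem)


# A fitted decay of less than this fraction over the observed time span is
# indistinguishable from a flat signal: the rate snaps to 0 and the half-life
# to the infinite sentinel.
_FLAT_RATE_TOL = 1e-4


def fit_single_exponential(
    times, values, plateau: float = 0.0, time_unit: str = "h"
) -> ExpFitResult:
    """Least-squares fit of A*exp(-k*t) + plateau with k >= 0.

    The initial guess takes A from the earliest point and k from a log-linear
    regression; the nonlinear fit then runs on linear-scale signals. A flat
    signal yields rate ~0 and an infinite half-life sentinel rather than an
    error, and non-convergence is reported via the ``converged`` flag.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(t).size < 3:
        raise ParameterError("exponential fit needs >= 3 distinct time points")
    if y[np.argmin(t)] - plateau <= 0:
        raise ParameterError("signal at the earliest time must exceed the plateau")

    excess = y - plateau
    pos = excess > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, intercept = np.polyfit(t[pos], np.log(excess[pos]), 1)
        k0 = max(-slope, 1e-6)
        a0 = math.exp(intercept)
    else:
        k0, a0 = 1e-6, float(excess[np.argmin(t)])

    def model(tt, a, k):
        return a * np.exp(-k * tt) + plateau

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=(a0, k0), bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
        )
        a_hat, k_hat = popt
    except (RuntimeError, optimize.OptimizeWarning):
        converged = False
        a_hat, k_hat = a0, k0

    resid = y - model(t, a_hat, k_hat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if k_hat * np.ptp(t) < _FLAT_RATE_TOL:
        k_hat, half_life = 0.0, math.inf
    else:
        half_life = math.log(2.0) / k_hat
    return ExpFitResult(
        rate=float(k_hat),
        half_life=float(half_life),
        amplitude=float(a_hat),
        r_squared=r2,
        converged=converged,
        time_unit=time_unit,
    )


def background_subtract(tc: SurfaceTimeCourse) -> tuple[pd.DataFrame, int]:
    """Per-time mean of specific wells minus mean of isotype-control wells.

    Negative corrected means clamp to zero; the count of clamped time points
    is returned alongside the corrected table. With no background wells the
    specific means are returned uncorrected (with a logged warning).
    """
    df = tc.data
    spec = df[~df["is_background"]].groupby("time")["signal"].mean()
    bg = df[df["is_background"]].groupby("time")["signal"].mean()
    if bg.empty:
        logger.warning("no isotype-control wells; proceeding without background correction")
        corrected = spec
    else:
        corrected = spec - bg.reindex(spec.index).fillna(float(bg.mean()))
    n_clamped = int((corrected < 0).sum())
    if n_clamped:
        logger.warning("clamped %d negative background-corrected means to 0", n_clamped)
    corrected = corrected.clip(lower=0.0)
    out = corrected.reset_index().rename(columns={"signal": "mean_signal"})
    return out, n_clamped


def surface_decay_fit(tc: SurfaceTimeCourse, plateau: float = 0.0) -> ExpFitResult:
    """Background-correct a surface time course and fit the plateau-zero decay."""
    corrected, _ = background_subtract(tc)
    return fit_single_exponential(
        corrected["time"], corrected["mean_signal"], plateau=plateau, time_unit=tc.time_unit
    )


def percent_internalized(tc: SurfaceTimeCourse, interval: float = 5.0) -> float:
    """Percent of the initial surface pool lost over ``interval`` minutes.

    Evaluated from the single-exponential fit over the early (0-7 min)
    window: 100 * (1 - exp(-k * interval)).
    """
    if tc.time_unit != "min":
        raise ParameterError("internalization requires a minutes time course")
    if tc.data["time"].max() > 10.0:
        raise ParameterError("internalization window must lie within the first 10 minutes")
    fit = surface_decay_fit(tc)
    return 100.0 * (1.0 - math.exp(-fit.rate * interval))


def recycling_percent(rt: RecyclingTable, at_time: float = 10.0) -> float:
    """Recycled signal at ``at_time`` minutes as percent of the endosomal pool."""
    row = rt.data[rt.data["time_min"] == at_time]
    if row.empty:
        raise ParameterError(f"no recycling measurement at t={at_time} min")
    return 100.0 * float(row["recycled_signal"].iloc[0]) / rt.pool_signal


def normalize_to_mrna_and_wt(
    raw: dict[str, float], mrna: dict[str, float], wt_name: str = "WT"
) -> list[NormalizedExpression]:
    """Express mRNA-normalized signals as percent of the wild-type construct."""
    if wt_name not in raw or wt_name not in mrna:
        raise ParameterError(f"wild-type construct {wt_name!r} missing from inputs")
    for name, level in mrna.items():
        if level <= 0:
            raise ParameterError(f"mRNA level for {name!r} must be > 0")
    wt_ratio = raw[wt_name] / mrna[wt_name]
    if wt_ratio <= 0:
        raise ParameterError("wild-type normalized signal must be > 0")
    return [
        NormalizedExpression(
            construct=name,
            raw_signal=raw[name],
            mrna_level=mrna[name],
            pct_of_wt=100.0 * (raw[name] / mrna[name]) / wt_ratio,
        )
        for name in raw
    ]


def relative_mrna(
    ct_target: float,
    ct_ref: float,
    calibrator: tuple[float, float],
    efficiency: float = 1.0,
) -> float:
    """Relative transcript quantity by the ddCt method.

    ``calibrator`` is the (target, reference) Ct pair of the calibrator
    sample; ``efficiency`` is the amplification efficiency (1.0 = perfect
    doubling per cycle, giving the classic 2^-ddCt).
    """
    for v in (ct_target, ct_ref, *calibrator):
        if not math.isfinite(v):
            raise ParameterError("Ct values must be finite")
    ddct = (ct_target - ct_ref) - (calibrator[0] - calibrator[1])
    return float((1.0 + efficiency) ** (-ddct))


def temperature_fold(fit_41: ExpFitResult, fit_37: ExpFitResult) -> float:
    """Fold increase in turnover rate at 41 degC relative to 37 degC."""
    if not (fit_41.converged and fit_37.converged):
        raise ParameterError("both exponential fits must have converged")
    if fit_37.rate <= 0:
        raise ParameterError("37 degC turnover rate must be > 0")
    return fit_41.rate / fit_37.rate


def ubiquitination_index(
    ub_signal: float, ha_signal: float, control_ub: float, control_ha: float
) -> float:
    """Ubiquitin signal normalized to channel (HA) signal, relative to control."""
    if ha_signal <= 0 or control_ha <= 0:
        raise ParameterError("HA signals must be > 0")
    return (ub_signal / ha_signal) / (control_ub / control_ha)


def expression_correlation(x, y) -> tuple[float, float, float]:
    """OLS regression of two expression readouts; returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ParameterError("correlation needs >= 3 points")
    if np.ptp(x) == 0:
        raise ParameterError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
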