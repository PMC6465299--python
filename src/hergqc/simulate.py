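"""Synthetic-assay generators.

Each simulator produces the tabular readout of one wet-lab assay from the
deterministic compartmental model plus a multiplicative lognormal measurement
noise model: metabolic pulse-chase densitometry, surface-ELISA time courses
(internalization / turnover), sandwich-ELISA recycling, per-vesicle pH sets,
and cycloheximide-chase immunoblots. All randomness flows through a single
integer seed, so identical calls produce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinetics
from .params import KineticParams, NoiseModel, ParameterError, PHMixtureSpec

__all__ = [
    "PulseChaseTable",
    "SurfaceTimeCourse",
    "RecyclingTable",
    "VesicleSet",
    "ChxCourse",
    "simulate_pulse_chase",
    "simulate_surface_pools",
    "simulate_vesicle_ph",
    "simulate_chx",
]

#: Nominal densitometry / plate-reader amplitude for the initial specific signal.
SIGNAL_SCALE = 100.0

#: Isotype-control wells emitted per time point.
N_BACKGROUND_WELLS = 2

#: Duration of the endosomal-loading (antibody uptake) phase in the recycling assay.
RECYCLING_UPTAKE_MIN = 20.0

#: pH range of measurable vesicles; mixture draws are truncated to it.
PH_RANGE = (3.5, 8.0)


@dataclass
class PulseChaseTable:
    """Radiolabel band intensities per replicate and chase time."""

    data: pd.DataFrame  # columns: replicate, chase_time_h, cg_intensity, fg_intensity

    def __post_init__(self) -> None:
        required = {"replicate", "chase_time_h", "cg_intensity", "fg_intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParameterError(f"pulse-chase table missing columns {sorted(missing)}")
        if (self.data[["cg_intensity", "fg_intensity"]] < 0).any().any():
            raise ParameterError("band intensities must be >= 0")


@dataclass
class SurfaceTimeCourse:
    """Surface-ELISA well signals over chase time (specific + isotype-control wells)."""

    data: pd.DataFrame  # columns: time, well, signal, is_background
    time_unit: str = "min"  # "min" or "h"

    def __post_init__(self) -> None:
        if self.time_unit not in ("min", "h"):
            raise ParameterError(f"unknown time unit {self.time_unit!r}")
        required = {"time", "well", "signal", "is_background"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParameterError(f"surface time course missing columns {sorted(missing)}")
        if (self.data["signal"] < 0).any():
            raise ParameterError("well signals must be >= 0")


@dataclass
class RecyclingTable:
    """Sandwich-ELISA recycling readout: endosomal pool and recycled signal over time."""

    pool_signal: float
    data: pd.DataFrame  # columns: time_min, recycled_signal
    block_efficiency: float = 0.99

    def __post_init__(self) -> None:
        if self.pool_signal <= 0:
            raise ParameterError("endosomal pool signal must be > 0")
        missing = {"time_min", "recycled_signal"} - set(self.data.columns)
        if missing:
            raise ParameterError(f"recycling table missing columns {sorted(missing)}")


@dataclass
class VesicleSet:
    """Per-vesicle pH measurements from one chase time."""

    chase_time_h: float
    ph_values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.ph_values, dtype=float)
        object.__setattr__(self, "ph_values", vals)
        if vals.size < 1:
            raise ParameterError("vesicle set must contain at least one vesicle")
        if np.any(vals < PH_RANGE[0]) or np.any(vals > PH_RANGE[1]):
            raise ParameterError(f"vesicle pH outside {PH_RANGE}")

    @property
    def n(self) -> int:
        return int(self.ph_values.size)


@dataclass
class ChxCourse:
    """Cycloheximide-chase band intensities at one temperature."""

    temperature: float
    data: pd.DataFrame  # columns: time_h, mature, immature

    def __post_init__(self) -> None:
        if self.temperature not in (37, 41):
            raise ParameterError("temperature must be 37 or 41 degC")
        missing = {"time_h", "mature", "immature"} - set(self.data.columns)
        if missing:
            raise ParameterError(f"CHX table missing columns {sorted(missing)}")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def simulate_pulse_chase(
    params: KineticParams,
    noise: NoiseModel,
    n_reps: int = 3,
    seed: int = 0,
    chase_times_h: tuple[float, ...] = (0.0, 3.0),
) -> PulseChaseTable:
    """Simulate a metabolic pulse-chase experiment.

    Each replicate carries its own labeling amplitude (lognormal around the
    nominal scale with cv ``cv_band``); every band intensity then receives an
    independent multiplicative densitometry error with the same cv.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    times = np.asarray(chase_times_h, dtype=float)
    cg, fg = kinetics.solve_cohort_kinetics(params, times)
    rng = np.random.default_rng(seed)
    amps = SIGNAL_SCALE * _lognormal_factors(rng, noise.cv_band, n_reps)
    rows = []
    for rep in range(n_reps):
        band_noise = _lognormal_factors(rng, noise.cv_band, (times.size, 2))
        for j, t in enumerate(times):
            rows.append(
                {
                    "replicate": rep,
                    "chase_time_h": t,
                    "cg_intensity": amps[rep] * cg[j] * band_noise[j, 0],
                    "fg_intensity": amps[rep] * fg[j] * band_noise[j, 1],
                }
            )
    return PulseChaseTable(pd.DataFrame(rows))


def _surface_course(
    params: KineticParams,
    schedule: np.ndarray,
    time_unit: str,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> SurfaceTimeCourse:
    t_min = schedule * 60.0 if time_unit == "h" else schedule
    surf, _ = kinetics.surface_solution(params, t_min)
    rows = []
    for j, t in enumerate(schedule):
        # specific wells carry the additive isotype background on top of the
        # specific signal; the estimator removes it via the background wells
        spec = (
            SIGNAL_SCALE
            * (surf[j] + noise.background_frac)
            * _lognormal_factors(rng, noise.cv_well, noise.n_wells)
        )
        for w, sig in enumerate(spec):
            rows.append({"time": t, "well": f"s{w}", "signal": sig, "is_background": False})
        if noise.background_frac > 0:
            bg = (
                SIGNAL_SCALE
                * noise.background_frac
                * _lognormal_factors(rng, noise.cv_well, N_BACKGROUND_WELLS)
            )
            for w, sig in enumerate(bg):
                rows.append({"time": t, "well": f"b{w}", "signal": sig, "is_background": True})
    return SurfaceTimeCourse(pd.DataFrame(rows), time_unit=time_unit)


def simulate_surface_pools(
    params: KineticParams,
    schedule,
    assay_kind: str,
    noise: NoiseModel,
    seed: int = 0,
):
    """Simulate a surface-ELISA assay.

    ``assay_kind`` selects the protocol:

    * ``"internalization"`` -- minutes schedule (0-7 min window), surface
      fraction of an antibody-labeled cohort;
    * ``"turnover"`` -- hours schedule (1.5-6 h), same labeled-cohort system
      followed over the long, slow-eigenvalue-dominated phase;
    * ``"recycling"`` -- minutes schedule; the endosomal pool is pre-loaded by
      a 20-min uptake phase, and the cumulative surface-reappearing signal is
      reported against the pool size (returns a :class:`RecyclingTable`).
    """
    sched = np.asarray(schedule, dtype=float)
    if sched.size == 0:
        raise ParameterError("schedule must be non-empty")
    if np.any(sched < 0):
        raise ParameterError("schedule times must be >= 0")
    rng = np.random.default_rng(seed)

    if assay_kind == "internalization":
        return _surface_course(params, sched, "min", noise, rng)
    if assay_kind == "turnover":
        return _surface_course(params, sched, "h", noise, rng)
    if assay_kind == "recycling":
        _, endo = kinetics.surface_solution(params, np.array([RECYCLING_UPTAKE_MIN]))
        pool_frac = float(endo[0])
        pool = SIGNAL_SCALE * pool_frac * float(_lognormal_factors(rng, noise.cv_well, 1)[0])
        recycled_frac = kinetics.recycling_curve(params, sched)
        sig = (
            SIGNAL_SCALE
            * pool_frac
            * recycled_frac
            * _lognormal_factors(rng, noise.cv_well, sched.size)
        )
        df = pd.DataFrame({"time_min": sched, "recycled_signal": sig})
        return RecyclingTable(pool_signal=pool, data=df)
    raise ParameterError(f"unknown assay_kind {assay_kind!r}")


def simulate_vesicle_ph(
    mixture: PHMixtureSpec, n_vesicles: int, seed: int = 0, chase_time_h: float = 3.0
) -> VesicleSet:
    """Draw per-vesicle pH values from a Gaussian mixture, truncated to [3.5, 8.0]."""
    if n_vesicles < 1:
        raise ParameterError("n_vesicles must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([c[0] for c in mixture.components])
    means = np.array([c[1] for c in mixture.components])
    sds = np.array([c[2] for c in mixture.components])
    out = np.empty(n_vesicles)
    filled = 0
    while filled < n_vesicles:
        need = n_vesicles - filled
        comp = rng.choice(len(weights), size=need, p=weights)
        draw = rng.normal(means[comp], sds[comp])
        ok = draw[(draw >= PH_RANGE[0]) & (draw <= PH_RANGE[1])]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    return VesicleSet(chase_time_h=chase_time_h, ph_values=out)


def simulate_chx(
    params: KineticParams,
    temperature: float,
    times_h,
    noise: NoiseModel,
    seed: int = 0,
) -> ChxCourse:
    """Simulate a cycloheximide-chase immunoblot time course at 37 or 41 degC."""
    t = np.asarray(times_h, dtype=float)
    mature, immature = kinetics.chx_decay(params, temperature, t)
    rng = np.random.default_rng(seed)
    factors = _lognormal_factors(rng, noise.cv_band, (t.size, 2))
    df = pd.DataFrame(
        {
            "time_h": t,
            "mature": SIGNAL_SCALE * mature * factors[:, 0],
            "immature": SIGNAL_SCALE * immature * factors[:, 1],
        }
    )
    return ChxCourse(temperature=temperature, data=df)
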