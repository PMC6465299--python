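"""Closed-form solutions of the compartmental trafficking model.

Two linear subsystems are solved analytically:

* the biosynthetic cascade of a pulse-labeled nascent cohort
  (core-glycosylated ER pool -> mature pool -> degraded, with competing
  ERAD from the ER pool), on an hours time base;
* the surface/endosome exchange of an antibody-labeled surface cohort
  (surface <-> endosome with competing lysosomal sorting), on a minutes
  time base.

All functions return pool sizes as fractions of the initial labeled cohort,
so mass across live and degraded pools sums to one exactly.
"""

from __future__ import annotations

import numpy as np

from .params import KineticParams, ParameterError

__all__ = [
    "solve_cohort_kinetics",
    "cohort_pools",
    "surface_solution",
    "surface_pools",
    "recycling_curve",
    "slow_surface_rate",
    "chx_decay",
]

# Relative eigenvalue gap below which the degenerate (repeated-root) branch is used.
_DEGENERATE_TOL = 1e-12


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ParameterError("time grid must be non-empty")
    if np.any(t < 0):
        raise ParameterError("times must be >= 0")
    return t


def solve_cohort_kinetics(params: KineticParams, times) -> tuple[np.ndarray, np.ndarray]:
    """Core- and complex-glycosylated fractions of a pulse-labeled cohort.

    With total nascent decay K = k_mat + k_erad::

        CG(t) = exp(-K t)
        FG(t) = k_mat / (K - k_pm) * (exp(-k_pm t) - exp(-K t))

    and the removable singularity at ``K == k_pm`` replaced by its limit
    ``FG(t) = k_mat * t * exp(-K t)``.

    Parameters
    ----------
    params
        Rate constants; only k_mat, k_erad and k_pm are used.
    times
        Chase times in hours.

    Returns
    -------
    (cg, fg)
        Fractions of the initial labeled cohort, each in [0, 1].
    """
    t = _check_times(times)
    big_k = params.nascent_decay_rate
    cg = np.exp(-big_k * t)
    delta = big_k - params.k_pm
    scale = max(big_k, params.k_pm, 1.0)
    if abs(delta) < _DEGENERATE_TOL * scale:
        fg = params.k_mat * t * np.exp(-big_k * t)
    else:
        fg = params.k_mat / delta * (np.exp(-params.k_pm * t) - np.exp(-big_k * t))
    return cg, fg


def cohort_pools(params: KineticParams, times) -> dict[str, np.ndarray]:
    """All four biosynthetic pools (live + degraded) over the chase.

    Returns a dict with keys ``cg``, ``fg``, ``erad_degraded``,
    ``mature_degraded``; the four arrays sum to one at every time.
    """
    t = _check_times(times)
    cg, fg = solve_cohort_kinetics(params, t)
    big_k = params.nascent_decay_rate
    if big_k == 0.0:
        consumed = np.zeros_like(t)
    else:
        consumed = (1.0 - np.exp(-big_k * t))
    erad_degraded = (params.k_erad / big_k) * consumed if big_k > 0 else np.zeros_like(t)
    matured_cum = (params.k_mat / big_k) * consumed if big_k > 0 else np.zeros_like(t)
    return {
        "cg": cg,
        "fg": fg,
        "erad_degraded": erad_degraded,
        "mature_degraded": matured_cum - fg,
    }


def _surface_eigen(params: KineticParams) -> tuple[float, float]:
    """Eigenvalues (slow, fast) of the surface/endosome exchange matrix."""
    a, kappa = params.k_int, params.k_rec + params.k_lys
    tr = -(a + kappa)
    disc = np.sqrt(max((a + kappa) ** 2 - 4.0 * a * params.k_lys, 0.0))
    return (tr + disc) / 2.0, (tr - disc) / 2.0


def surface_solution(params: KineticParams, times_min) -> tuple[np.ndarray, np.ndarray]:
    """Surface and endosomal fractions of a surface-labeled cohort.

    Solves dS/dt = -k_int S + k_rec E, dE/dt = k_int S - (k_rec + k_lys) E
    with S(0) = 1, E(0) = 0. Times are in minutes.
    """
    t = _check_times(times_min)
    a, kappa = params.k_int, params.k_rec + params.k_lys
    lam1, lam2 = _surface_eigen(params)
    gap = lam1 - lam2
    scale = max(abs(lam1), abs(lam2), 1.0)
    if gap < _DEGENERATE_TOL * scale:
        lam = lam1
        s = np.exp(lam * t) * (1.0 + (kappa + lam) * t)
        e = a * t * np.exp(lam * t)
    else:
        e1, e2 = np.exp(lam1 * t), np.exp(lam2 * t)
        s = ((kappa + lam1) * e1 - (kappa + lam2) * e2) / gap
        e = a * (e1 - e2) / gap
    return s, e


def surface_pools(params: KineticParams, times_min) -> dict[str, np.ndarray]:
    """Surface, endosomal and lysosome-degraded fractions (sum to one)."""
    s, e = surface_solution(params, times_min)
    return {"surface": s, "endosome": e, "lys_degraded": 1.0 - s - e}


def recycling_curve(params: KineticParams, times_min) -> np.ndarray:
    """Cumulative fraction of a pre-loaded endosomal pool recycled to the surface.

    During the recycling chase the endosomal pool empties at k_rec + k_lys
    and a fraction k_rec / (k_rec + k_lys) of the exits reappear at the
    surface; re-internalization of recycled channels within the short chase
    window is neglected::

        R(t) = f_rec * (1 - exp(-(k_rec + k_lys) t))
    """
    t = _check_times(times_min)
    kappa = params.k_rec + params.k_lys
    if kappa == 0.0:
        return np.zeros_like(t)
    return params.recycling_fraction * (1.0 - np.exp(-kappa * t))


def slow_surface_rate(params: KineticParams) -> float:
    """Magnitude of the slow eigenvalue (per minute): the long-term PM decay rate."""
    lam1, _ = _surface_eigen(params)
    return -lam1


def chx_decay(params: KineticParams, temperature: float, times_h) -> tuple[np.ndarray, np.ndarray]:
    """Mature and immature band fractions during a cycloheximide chase.

    The mature (complex-glycosylated) band decays at k_pm at 37 degC and at
    k_pm * temp_factor at 41 degC; the immature (core-glycosylated) band
    decays at the total nascent rate k_mat + k_erad.
    """
    if temperature not in (37, 41):
        raise ParameterError(f"unsupported chase temperature {temperature}; use 37 or 41")
    t = _check_times(times_h)
    rate_pm = params.k_pm * (params.temp_factor if temperature == 41 else 1.0)
    mature = np.exp(-rate_pm * t)
    immature = np.exp(-params.nascent_decay_rate * t)
    return mature, immature
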