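"""Partition of the surface-expression defect into ER and peripheral QC losses.

Under a constant-turnover null model, a mutant whose only defect is reduced
ER maturation should express at the surface in proportion to its relative
maturation efficiency (pm_rel = me_rel). Any shortfall below that prediction
is attributed to peripheral quality control:

    er_loss         = 100 * (1 - min(me_rel, 1))
    peripheral_loss = 100 * (min(me_rel, 1) - pm_rel)
    total_loss      = 100 * (1 - pm_rel) = er_loss + peripheral_loss

Constructs expressing above the prediction (pm_rel > me_rel) carry an
``increased`` PM-stability flag and a negative peripheral loss. The
compartmental QC responses are the fold decrease in maturation efficiency
(ER) and the fold increase in PM turnover (peripheral).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ParameterError

__all__ = [
    "ConstructSummary",
    "DecompositionRow",
    "QCResponse",
    "relative_metrics",
    "decompose",
    "qc_response",
    "rank_and_tabulate",
    "bootstrap_decomposition",
]

#: |pm_rel - me_rel| below this is reported as neutral PM stability.
NEUTRAL_TOL = 1e-6


@dataclass(frozen=True)
class ConstructSummary:
    """Per-construct metrics as fractions/folds of wild type."""

    construct: str
    me_rel: float  # maturation efficiency relative to WT
    pm_rel: float  # PM expression relative to WT
    turnover_fold: float  # PM turnover rate as fold of WT

    def __post_init__(self) -> None:
        if self.me_rel < 0 or self.pm_rel < 0:
            raise ParameterError("relative metrics must be >= 0")
        if self.turnover_fold <= 0:
            raise ParameterError("turnover_fold must be > 0")


@dataclass(frozen=True)
class DecompositionRow:
    construct: str
    er_loss_pct: float
    peripheral_loss_pct: float
    total_loss_pct: float
    stability_flag: str  # "increased" | "decreased" | "neutral"


@dataclass(frozen=True)
class QCResponse:
    construct: str
    er_response_fold: float  # WT/mutant maturation efficiency
    peripheral_response_fold: float  # mutant/WT PM turnover rate
    infinite_er_response: bool = False


def relative_metrics(
    raw_me: dict[str, float],
    raw_pm,
    turnover_rates: dict[str, float] | None = None,
    wt_name: str = "WT",
) -> list[ConstructSummary]:
    """Express raw per-construct readouts as fractions/folds of wild type.

    ``raw_me`` are maturation efficiencies (%); ``raw_pm`` is either a
    ``{construct: signal}`` dict or a list of
    :class:`~hergqc.estimators.NormalizedExpression`; ``turnover_rates`` are
    fitted PM decay rates (optional -- folds default to 1).
    """
    if not isinstance(raw_pm, dict):
        raw_pm = {e.construct: e.pct_of_wt for e in raw_pm}
    checks = [(raw_me, "maturation"), (raw_pm, "PM expression")]
    if turnover_rates is not None:
        checks.append((turnover_rates, "turnover"))
    for d, label in checks:
        if wt_name not in d:
            raise ParameterError(f"wild type {wt_name!r} missing from {label} inputs")
        if d[wt_name] <= 0:
            raise ParameterError(f"wild-type {label} must be > 0")
    return [
        ConstructSummary(
            construct=name,
            me_rel=raw_me[name] / raw_me[wt_name],
            pm_rel=raw_pm[name] / raw_pm[wt_name],
            turnover_fold=(
                turnover_rates[name] / turnover_rates[wt_name]
                if turnover_rates is not None
                else 1.0
            ),
        )
        for name in raw_me
    ]


def decompose(s: ConstructSummary) -> DecompositionRow:
    """Split the total PM-expression loss into ER and peripheral contributions."""
    me_capped = min(s.me_rel, 1.0)
    er_loss = 100.0 * (1.0 - me_capped)
    total_loss = 100.0 * (1.0 - s.pm_rel)
    peripheral_loss = total_loss - er_loss
    if abs(s.pm_rel - s.me_rel) <= NEUTRAL_TOL:
        flag = "neutral"
    elif s.pm_rel > s.me_rel:
        flag = "increased"
    else:
        flag = "decreased"
    return DecompositionRow(
        construct=s.construct,
        er_loss_pct=er_loss,
        peripheral_loss_pct=peripheral_loss,
        total_loss_pct=total_loss,
        stability_flag=flag,
    )


def qc_response(s: ConstructSummary) -> QCResponse:
    """Compartment-specific QC response folds."""
    if s.me_rel == 0.0:
        return QCResponse(s.construct, math.inf, s.turnover_fold, infinite_er_response=True)
    return QCResponse(s.construct, 1.0 / s.me_rel, s.turnover_fold)


def rank_and_tabulate(rows: list[DecompositionRow]) -> list[DecompositionRow]:
    """Order rows by increasing severity of the PM expression defect.

    Ties break alphabetically by construct name.
    """
    if not rows:
        raise ParameterError("no decomposition rows")
    return sorted(rows, key=lambda r: (r.total_loss_pct, r.construct))


def bootstrap_decomposition(
    me_samples: dict[str, np.ndarray],
    pm_samples: dict[str, np.ndarray],
    wt_name: str = "WT",
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Nonparametric bootstrap confidence intervals for the loss partition.

    Replicate-level maturation efficiencies and PM signals are resampled with
    replacement (jointly with the wild-type replicates); returns per-construct
    ``{metric: (lo, hi)}`` percentile intervals for er/peripheral/total loss.
    """
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    out: dict[str, dict[str, tuple[float, float]]] = {}
    wt_me = np.asarray(me_samples[wt_name], dtype=float)
    wt_pm = np.asarray(pm_samples[wt_name], dtype=float)
    for name in me_samples:
        me = np.asarray(me_samples[name], dtype=float)
        pm = np.asarray(pm_samples[name], dtype=float)
        draws = np.empty((n_boot, 3))
        for b in range(n_boot):
            me_b = rng.choice(me, me.size).mean()
            pm_b = rng.choice(pm, pm.size).mean()
            wt_me_b = rng.choice(wt_me, wt_me.size).mean()
            wt_pm_b = rng.choice(wt_pm, wt_pm.size).mean()
            row = decompose(
                ConstructSummary(name, me_b / wt_me_b, pm_b / wt_pm_b, 1.0)
            )
            draws[b] = (row.er_loss_pct, row.peripheral_loss_pct, row.total_loss_pct)
        out[name] = {
            metric: (
                float(np.quantile(draws[:, i], alpha)),
                float(np.quantile(draws[:, i], 1.0 - alpha)),
            )
            for i, metric in enumerate(("er_loss_pct", "peripheral_loss_pct", "total_loss_pct"))
        }
    return out
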