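"""Vesicular-pH distribution analysis (fluorescence ratiometric imaging).

Per-vesicle pH values are histogrammed, the histogram is fit with a sum of
one to three Gaussian peaks by nonlinear least squares, and the summary
statistic is the area-weighted average of the peak centers (the mean
endocytic pH). Early/recycling endosomes sit around pH 6.5-6.8 and late
endosomes/lysosomes around 4.5-5.5, so the weighted mean tracks how much of
the internalized channel has been sorted toward the degradative branch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .params import ParameterError
from .simulate import VesicleSet

__all__ = [
    "PHHistogram",
    "FRIAResult",
    "CalibrationCurve",
    "build_histogram",
    "fit_multi_gaussian",
    "weighted_mean_ph",
    "ratio_to_ph",
]

logger = logging.getLogger(__name__)

MAX_COMPONENTS = 3
#: Minimum vesicle count before a multi-peak fit is attempted.
MIN_N_MULTI = 20


@dataclass(frozen=True)
class PHHistogram:
    """Uniform-width histogram of per-vesicle pH, half-open bins [edge, edge+w)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if edges.size != counts.size + 1:
            raise ParameterError("need len(bin_edges) == len(counts) + 1")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ParameterError("bin edges must be strictly increasing and uniform")

    @property
    def n_total(self) -> int:
        return int(round(float(self.counts.sum())))

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass(frozen=True)
class FRIAResult:
    """Fitted mixture and its weighted-average mean pH."""

    components: tuple  # ((weight, mean_ph, sd_ph), ...) sorted by mean
    mean_ph: float
    n_vesicles: int
    k: int
    gof: float  # residual sum of squares of the histogram fit
    converged: bool
    degenerate: bool = False


@dataclass(frozen=True)
class CalibrationCurve:
    """Fluorescence-ratio -> pH calibration knots (strictly monotone in ratio)."""

    ratios: np.ndarray
    ph: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        p = np.asarray(self.ph, dtype=float)
        if r.size < 2 or r.size != p.size:
            raise ParameterError("calibration curve needs >= 2 (ratio, pH) pairs")
        order = np.argsort(r)
        r, p = r[order], p[order]
        if np.any(np.diff(r) <= 0):
            raise ParameterError("calibration ratios must be distinct")
        dp = np.diff(p)
        if not (np.all(dp > 0) or np.all(dp < 0)):
            raise ParameterError("calibration curve must be strictly monotone in ratio")
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "ph", p)


def build_histogram(vs: VesicleSet, bin_width: float = 0.1) -> PHHistogram:
    """Histogram the vesicle pH values into bins aligned to multiples of ``bin_width``."""
    if bin_width <= 0:
        raise ParameterError("bin width must be > 0")
    vals = vs.ph_values
    lo = math.floor(vals.min() / bin_width) * bin_width
    n_bins = int(math.floor((vals.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.floor((vals - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guards the float-boundary case at the max
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return PHHistogram(edges, counts)


def _gauss_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of Gaussians; params = (amp1, mean1, sd1, amp2, ...)."""
    y = np.zeros_like(x)
    for amp, mu, sd in params.reshape(-1, 3):
        y = y + amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def _fit_k(h: PHHistogram, k: int) -> tuple[np.ndarray, float, bool]:
    """Least-squares fit of k Gaussian peaks to the histogram counts."""
    x, y = h.centers, h.counts
    data = np.repeat(x, h.counts.astype(int))
    qs = np.quantile(data, (np.arange(k) + 0.5) / k)
    sd0 = max(np.std(data) / k, h.bin_width)
    p0 = []
    for mu in qs:
        p0.extend([max(y.max(), 1.0), mu, sd0])
    p0 = np.array(p0)
    lb = np.tile([0.0, x.min() - 1.0, h.bin_width / 4.0], k)
    ub = np.tile([np.inf, x.max() + 1.0, (x.max() - x.min()) + 1.0], k)
    try:
        sol = optimize.least_squares(
            lambda p: _gauss_sum(x, p) - y, p0, bounds=(lb, ub), max_nfev=5000
        )
        return sol.x, float(2.0 * sol.cost), sol.status > 0
    except Exception:  # pragma: no cover - defensive
        return p0, float(np.sum((_gauss_sum(x, p0) - y) ** 2)), False


#: Significance level for accepting an additional peak in the auto fit.
EXTRA_PEAK_ALPHA = 0.01


def _extra_peak_significant(rss_small: float, rss_big: float, n_bins: int, k_big: int) -> bool:
    """Nested-model F-test: does the (k_big)-peak fit beat the (k_big - 1)-peak fit?"""
    dof_big = n_bins - 3 * k_big
    if dof_big < 1:
        return False
    if rss_big <= 0:
        return rss_small > 0
    f_stat = ((rss_small - rss_big) / 3.0) / (rss_big / dof_big)
    if f_stat <= 0:
        return False
    p_value = stats.f.sf(f_stat, 3, dof_big)
    return p_value < EXTRA_PEAK_ALPHA


def fit_multi_gaussian(h: PHHistogram, k: int | str = "auto") -> FRIAResult:
    """Fit a multi-Gaussian peak model to a pH histogram.

    With ``k="auto"`` peaks are added (up to 3) while each additional peak
    significantly improves the histogram fit under a nested-model F-test.
    Component weights are the Gaussian areas normalized to unity; components
    are reported sorted by mean. A single-bin histogram returns a degenerate
    single component whose sd is floored at half the bin width.
    """
    n_total = h.n_total
    if n_total < 1:
        raise ParameterError("empty histogram")

    if int((h.counts > 0).sum()) == 1:
        center = float(h.centers[np.argmax(h.counts)])
        comp = ((1.0, center, h.bin_width / 2.0),)
        return FRIAResult(comp, center, n_total, 1, 0.0, True, degenerate=True)

    n_bins = h.counts.size
    if isinstance(k, str):
        if k != "auto":
            raise ParameterError(f"k must be an integer or 'auto', got {k!r}")
        kk = 1
        par, rss, ok = _fit_k(h, 1)
        while kk < MAX_COMPONENTS and n_total >= MIN_N_MULTI and n_bins >= 3 * (kk + 1) + 2:
            par_next, rss_next, ok_next = _fit_k(h, kk + 1)
            if not _extra_peak_significant(rss, rss_next, n_bins, kk + 1):
                break
            kk, par, rss, ok = kk + 1, par_next, rss_next, ok_next
    else:
        if not (1 <= k <= MAX_COMPONENTS):
            raise ParameterError(f"k must lie in 1..{MAX_COMPONENTS}")
        kk = int(k)
        if kk > 1 and n_total < MIN_N_MULTI:
            raise ParameterError(f"multi-peak fit needs >= {MIN_N_MULTI} vesicles")
        par, rss, ok = _fit_k(h, kk)

    comps = par.reshape(-1, 3)
    areas = comps[:, 0] * comps[:, 2]  # amplitude * sd, proportional to vesicle counts
    total_area = areas.sum()
    if total_area <= 0:
        raise ParameterError("degenerate mixture fit: zero total area")
    weights = areas / total_area
    order = np.argsort(comps[:, 1])
    components = tuple(
        (float(weights[i]), float(comps[i, 1]), float(comps[i, 2])) for i in order
    )
    return FRIAResult(
        components=components,
        mean_ph=weighted_mean_ph(components),
        n_vesicles=n_total,
        k=kk,
        gof=rss,
        converged=bool(ok),
    )


def weighted_mean_ph(components) -> float:
    """Area-weighted average of the peak centers."""
    comps = list(components)
    if not comps:
        raise ParameterError("no mixture components")
    total = sum(w for w, _, _ in comps)
    if total <= 0:
        raise ParameterError("component weights must sum to a positive value")
    return float(sum(w * m for w, m, _ in comps) / total)


def ratio_to_ph(ratios, curve: CalibrationCurve) -> np.ndarray:
    """Convert fluorescence ratios to pH by monotone piecewise-linear interpolation.

    Ratios outside the calibration range clamp to the endpoint pH values with
    a logged warning.
    """
    r = np.asarray(ratios, dtype=float)
    n_out = int(np.sum((r < curve.ratios[0]) | (r > curve.ratios[-1])))
    if n_out:
        logger.warning("%d ratios outside the calibration range were clamped", n_out)
    return np.interp(r, curve.ratios, curve.ph)
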