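"""Local linear (degree-1) regression with tricube weights and automatic
span selection by the corrected Akaike information criterion.

For each target point the ``ceil(span * n)`` nearest neighbours (by
position) are weighted with the tricube kernel scaled to the farthest
neighbour, and a weighted straight line is fitted; the fitted value and the
diagonal element of the smoother matrix L fall out of the same closed-form
solve. The span is chosen to minimise

    AICc = log(sigma^2) + 1 + 2 (tr(L) + 1) / (n - tr(L) - 2)

where sigma^2 is the mean squared residual (Hurvich, Simonoff & Tsai 1998).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model import DataError

log = logging.getLogger(__name__)

DEFAULT_SPAN_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


@dataclass
class LoessFit:
    span: float
    fitted: np.ndarray
    trace_l: float
    aicc: float


def _nearest_window(x: np.ndarray, i: int, k: int) -> tuple[int, int]:
    """[lo, hi) bounds of the k nearest neighbours of x[i] in sorted x."""
    n = len(x)
    lo, hi = i, i + 1
    while hi - lo < k:
        if lo == 0:
            hi += 1
        elif hi == n:
            lo -= 1
        elif x[i] - x[lo - 1] <= x[hi] - x[i]:
            lo -= 1
        else:
            hi += 1
    return lo, hi


def local_linear_smooth(
    x: np.ndarray, y: np.ndarray, span: float
) -> tuple[np.ndarray, float]:
    """Fitted values and tr(L) of the degree-1 tricube smoother at one span.

    ``x`` must be sorted in increasing order. Windows of fewer than 3 points
    raise ValueError (the span is unusable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    k = int(math.ceil(span * n))
    if k < 3:
        raise ValueError(f"span {span} gives window of {k} < 3 points")
    k = min(k, n)

    fitted = np.empty(n)
    trace = 0.0
    for i in range(n):
        lo, hi = _nearest_window(x, i, k)
        dx = x[lo:hi] - x[i]
        dmax = max(abs(dx[0]), abs(dx[-1]))
        if dmax == 0.0:
            w = np.ones(hi - lo)
        else:
            u = np.abs(dx) / dmax
            w = np.clip(1.0 - u**3, 0.0, None) ** 3
        sw = w.sum()
        swx = (w * dx).sum()
        swxx = (w * dx * dx).sum()
        denom = sw * swxx - swx * swx
        # equivalent row of the smoother matrix: fitted_i = l . y_window
        if denom <= 1e-12 * max(sw * swxx, 1e-300):
            l = w / sw  # degenerate design -> weighted mean
        else:
            l = w * (swxx - swx * dx) / denom
        fitted[i] = float(l @ y[lo:hi])
        trace += float(l[i - lo])
    return fitted, trace


def aicc_score(y: np.ndarray, fitted: np.ndarray, trace_l: float) -> float:
    """AICc of a linear smoother; +inf when the penalty denominator vanishes."""
    n = len(y)
    resid = np.asarray(y, dtype=float) - fitted
    sigma2 = float(resid @ resid) / n
    denom = n - trace_l - 2.0
    if denom <= 0:
        return math.inf
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny  # perfect fit; keep the score finite
    return math.log(sigma2) + 1.0 + 2.0 * (trace_l + 1.0) / denom


def loess_fit_aicc(
    x: np.ndarray,
    y: np.ndarray,
    span_grid: tuple[float, ...] | None = None,
) -> LoessFit:
    """Fit at every candidate span and return the AICc-minimising fit.

    Spans whose local windows hold fewer than 3 points are skipped; if no
    span is usable a DataError is raised. Requires >= 10 points with
    strictly increasing x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise DataError(f"loess requires >= 10 points, got {len(x)}")
    if np.any(np.diff(x) <= 0):
        raise DataError("x must be strictly increasing")
    grid = DEFAULT_SPAN_GRID if span_grid is None else tuple(span_grid)

    best: LoessFit | None = None
    for span in grid:
        try:
            fitted, trace = local_linear_smooth(x, y, span)
        except ValueError:
            continue
        score = aicc_score(y, fitted, trace)
        if best is None or score < best.aicc:
            best = LoessFit(span=float(span), fitted=fitted, trace_l=trace, aicc=score)
    if best is None:
        raise DataError("no usable span in the grid (all windows < 3 points)")
    return best
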