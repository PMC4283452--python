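"""Mamdani min-max inference, Karnik-Mendel type reduction and
defuzzification on a fixed output grid.

The engine is written for interval bounds throughout: a type-1 system is
the degenerate case lower == upper, and a zSlices general type-2 system
runs one interval inference per slice and combines the per-slice
centroids weighted by their z levels.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "firing_interval",
    "aggregate",
    "km_type_reduce",
    "centroid",
    "defuzzify_interval",
    "defuzzify_zslices",
    "output_grid",
]

#: Number of points used to discretize output universes (<0.1% centroid error).
GRID_POINTS = 1001


def output_grid(universe: tuple[float, float], n: int = GRID_POINTS) -> np.ndarray:
    return np.linspace(universe[0], universe[1], n)


def firing_interval(
    m1: tuple[float, float], m2: tuple[float, float]
) -> tuple[float, float]:
    """Rule firing interval under the minimum t-norm.

    ``m1``/``m2`` are (lower, upper) membership bounds of the two
    antecedents; type-1 memberships are passed as degenerate intervals.
    """
    return min(m1[0], m2[0]), min(m1[1], m2[1])


def aggregate(
    consequents: list[tuple[np.ndarray, np.ndarray]],
    firings: list[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Truncate each fired consequent at its firing interval and take the
    pointwise maximum across rules, per bound.

    ``consequents`` holds (lower_grid, upper_grid) membership arrays of
    each fired rule's output set.
    """
    if not consequents:
        raise ValueError("no fired rules to aggregate")
    lo = np.zeros_like(consequents[0][0])
    hi = np.zeros_like(consequents[0][1])
    for (c_lo, c_hi), (f_lo, f_hi) in zip(consequents, firings):
        np.maximum(lo, np.minimum(c_lo, f_lo), out=lo)
        np.maximum(hi, np.minimum(c_hi, f_hi), out=hi)
    return lo, hi


def centroid(x: np.ndarray, mu: np.ndarray) -> float:
    """Discrete weighted-mean centroid of a type-1 set sampled on ``x``."""
    total = mu.sum()
    if total <= 0:
        raise ValueError("cannot take the centroid of an identically zero set")
    return float((x * mu).sum() / total)


def _km_bound(
    x: np.ndarray,
    c_lo: np.ndarray,
    c_hi: np.ndarray,
    cx_lo: np.ndarray,
    cx_hi: np.ndarray,
    y0: float,
    left: bool,
) -> float:
    """One Karnik-Mendel switch-point iteration (classic KM).

    ``left=True`` computes y_l (upper memberships left of the switch
    point, lower to the right); ``left=False`` computes y_r with the
    roles swapped.  ``c_*``/``cx_*`` are zero-prefixed cumulative sums
    of the membership bounds and their first moments, which make each
    iteration O(1): the switch point is just an index into the sorted
    grid.
    """
    n = len(x)
    tot_lo, tot_hi = c_lo[n], c_hi[n]
    totx_lo, totx_hi = cx_lo[n], cx_hi[n]
    y = y0
    split = -1
    for _ in range(100):
        k = int(np.searchsorted(x, y, side="right"))
        if k == split:
            break
        split = k
        if left:
            num = cx_hi[k] + (totx_lo - cx_lo[k])
            den = c_hi[k] + (tot_lo - c_lo[k])
        else:
            num = cx_lo[k] + (totx_hi - cx_hi[k])
            den = c_lo[k] + (tot_hi - c_hi[k])
        if den <= 0:
            num, den = totx_hi, tot_hi
        y = num / den
    return float(y)


def km_type_reduce(
    x: np.ndarray, lower: np.ndarray, upper: np.ndarray
) -> tuple[float, float]:
    """Interval centroid [y_l, y_r] of an aggregated interval type-2 set.

    For a degenerate set (lower == upper) both bounds collapse to the
    type-1 centroid.  Raises on an identically zero upper envelope.
    """
    if len(x) == 0:
        raise ValueError("empty grid")
    if not np.any(upper > 0):
        raise ValueError("cannot type-reduce an identically zero set")
    if np.array_equal(lower, upper):
        c = centroid(x, upper)
        return c, c
    zero = np.zeros(1)
    c_lo = np.concatenate((zero, np.cumsum(lower)))
    c_hi = np.concatenate((zero, np.cumsum(upper)))
    cx_lo = np.concatenate((zero, np.cumsum(x * lower)))
    cx_hi = np.concatenate((zero, np.cumsum(x * upper)))
    mid = (c_lo[-1] + c_hi[-1])
    y0 = (cx_lo[-1] + cx_hi[-1]) / mid if mid > 0 else float(x[0])
    y_l = _km_bound(x, c_lo, c_hi, cx_lo, cx_hi, y0, left=True)
    y_r = _km_bound(x, c_lo, c_hi, cx_lo, cx_hi, y0, left=False)
    if y_l > y_r:  # numerically impossible for valid FOUs; keep ordered
        y_l, y_r = y_r, y_l
    return y_l, y_r


def defuzzify_interval(reduced: tuple[float, float]) -> float:
    """Midpoint of the type-reduced interval."""
    y_l, y_r = reduced
    return 0.5 * (y_l + y_r)


def defuzzify_zslices(
    z_levels: list[float] | tuple[float, ...],
    intervals: list[tuple[float, float]],
) -> float:
    """z-weighted mean of the per-slice interval midpoints."""
    if not intervals:
        raise ValueError("empty type reduction")
    num = sum(z * defuzzify_interval(iv) for z, iv in zip(z_levels, intervals))
    den = sum(z_levels[: len(intervals)])
    return num / den
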