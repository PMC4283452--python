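"""Fuzzy set representations: type-1 triangles, interval type-2 FOUs and
zSlices-based general type-2 stacks.

A type-1 set assigns each point a crisp grade in [0,1].  An interval
type-2 set is described entirely by its footprint of uncertainty (FOU),
the band between a lower and an upper membership function.  A zSlices
general type-2 set is a finite stack of interval type-2 sets at
increasing secondary levels z, with the FOU at a higher z nested inside
every lower one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "INPUT_LABELS",
    "OUTPUT_LABELS",
    "TriangularMF",
    "IntervalType2Set",
    "ZSliceSet",
    "LinguisticVariable",
    "membership",
    "build_partition",
    "build_fou_from_stats",
    "as_slices",
]

#: Linguistic labels for controller inputs, in their total order.
INPUT_LABELS = ("NB", "NM", "NS", "ZE", "PS", "PM", "PB")
#: Linguistic labels for controller outputs (drug-adjustment magnitudes).
OUTPUT_LABELS = ("ZE", "PS", "PM", "PB")


@dataclass(frozen=True)
class TriangularMF:
    """Triangular type-1 membership function (left foot, peak, right foot)."""

    left: float
    peak: float
    right: float

    def __post_init__(self) -> None:
        if not (self.left <= self.peak <= self.right):
            raise ValueError("triangle requires left <= peak <= right")

    def __call__(self, x):
        if isinstance(x, (int, float)):  # scalar fast path
            if x < self.left or x > self.right:
                return 0.0
            up = (
                (x - self.left) / (self.peak - self.left)
                if self.peak > self.left
                else (1.0 if x >= self.peak else 0.0)
            )
            down = (
                (self.right - x) / (self.right - self.peak)
                if self.right > self.peak
                else (1.0 if x <= self.peak else 0.0)
            )
            return max(0.0, min(up, down, 1.0))
        x = np.asarray(x, dtype=float)
        if self.peak > self.left:
            up = (x - self.left) / (self.peak - self.left)
        else:
            up = np.where(x >= self.peak, 1.0, 0.0)
        if self.right > self.peak:
            down = (self.right - x) / (self.right - self.peak)
        else:
            down = np.where(x <= self.peak, 1.0, 0.0)
        mu = np.clip(np.minimum(up, down), 0.0, 1.0)
        return float(mu) if mu.ndim == 0 else mu


@dataclass(frozen=True)
class IntervalType2Set:
    """Interval type-2 set given by its lower and upper membership functions."""

    lower: TriangularMF
    upper: TriangularMF

    def __post_init__(self) -> None:
        # Same-peak triangles: the FOU is non-degenerate iff the lower
        # triangle's support is contained in the upper one's.
        if not (
            self.upper.left <= self.lower.left
            and self.lower.right <= self.upper.right
        ):
            raise ValueError("lower MF must lie inside the upper MF (FOU)")

    def membership(self, x) -> tuple:
        return self.lower(x), self.upper(x)


@dataclass(frozen=True)
class ZSliceSet:
    """Stack of interval type-2 sets at strictly increasing z levels."""

    z_levels: tuple[float, ...]
    slices: tuple[IntervalType2Set, ...]

    def __post_init__(self) -> None:
        if len(self.z_levels) != len(self.slices) or not self.slices:
            raise ValueError("need one slice per z level")
        if any(not (0 < z <= 1) for z in self.z_levels):
            raise ValueError("z levels must lie in (0, 1]")
        if any(b <= a for a, b in zip(self.z_levels, self.z_levels[1:])):
            raise ValueError("z levels must be strictly increasing")
        for lo, hi in zip(self.slices[1:], self.slices):
            # Slice at higher z must be nested in every lower-z slice.
            if not (
                hi.upper.left <= lo.upper.left
                and lo.upper.right <= hi.upper.right
                and lo.lower.left <= hi.lower.left + 1e-12
                and hi.lower.right <= lo.lower.right + 1e-12
            ):
                raise ValueError("zSlice FOUs must be nested with increasing z")

    def membership(self, x) -> list:
        return [s.membership(x) for s in self.slices]


FuzzySet = TriangularMF | IntervalType2Set | ZSliceSet


def membership(fset: FuzzySet, x):
    """Grade (type-1), interval (interval type-2) or per-slice intervals (zSlices)."""
    if isinstance(fset, TriangularMF):
        return fset(x)
    return fset.membership(x)


def as_slices(fset: FuzzySet) -> tuple[tuple[float, ...], tuple[IntervalType2Set, ...]]:
    """Normalize any set kind to a (z_levels, interval-slices) stack.

    A type-1 set becomes a single degenerate interval slice at z=1; an
    interval type-2 set a single slice at z=1.  This is the degeneracy
    chain the inference engine relies on.
    """
    if isinstance(fset, TriangularMF):
        return (1.0,), (IntervalType2Set(fset, fset),)
    if isinstance(fset, IntervalType2Set):
        return (1.0,), (fset,)
    return fset.z_levels, fset.slices


@dataclass(frozen=True)
class LinguisticVariable:
    """A named universe with an ordered family of labelled fuzzy sets."""

    name: str
    universe: tuple[float, float]
    sets: Mapping[str, FuzzySet]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.universe[0] >= self.universe[1]:
            raise ValueError("universe must be a nonempty interval")
        if tuple(self.sets.keys()) != self.labels:
            raise ValueError("sets must be keyed by the ordered labels")

    def clamp(self, x: float) -> float:
        """Out-of-universe inputs saturate at the universe edge."""
        return min(max(x, self.universe[0]), self.universe[1])

    def fuzzify(self, x: float) -> dict[str, object]:
        xc = self.clamp(x)
        return {lab: membership(s, xc) for lab, s in self.sets.items()}

    @property
    def n_zslices(self) -> int:
        return max(len(as_slices(s)[0]) for s in self.sets.values())


def _blurred_triangle(
    left: float, peak: float, right: float, w: float
) -> IntervalType2Set:
    if w < 0:
        raise ValueError("FOU width must be >= 0")
    # Degenerate sides (shoulders at the universe edge) keep their foot at
    # the peak; everywhere else the lower MF must remain a true triangle.
    if (peak > left and peak - left <= w) or (right > peak and right - peak <= w):
        raise ValueError("fou_width too large: lower MF would cross the peak")
    lo_left = peak if peak == left else left + w
    lo_right = peak if peak == right else right - w
    up_left = peak if peak == left else left - w
    up_right = peak if peak == right else right + w
    return IntervalType2Set(
        TriangularMF(lo_left, peak, lo_right), TriangularMF(up_left, peak, up_right)
    )


def build_partition(
    universe: tuple[float, float],
    labels: Sequence[str] = INPUT_LABELS,
    fou_width: float = 0.0,
    n_zslices: int | None = None,
    name: str = "",
) -> LinguisticVariable:
    """Evenly spaced triangular partition with 50% overlap.

    ``fou_width`` (absolute units of the universe) blurs every
    triangle's feet outward (upper MF) and inward (lower MF); zero gives
    a plain type-1 partition.  With ``n_zslices`` each label becomes a
    zSlices stack of ``n`` nested FOUs whose widths shrink linearly with
    z: slice k of n has width ``fou_width * (1 - (k-1)/n)``, so a single
    slice reproduces the interval type-2 set exactly.
    """
    lo, hi = universe
    if lo >= hi:
        raise ValueError("universe must be a nonempty interval")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two labels")
    spacing = (hi - lo) / (n - 1)
    sets: dict[str, FuzzySet] = {}
    for i, lab in enumerate(labels):
        peak = lo + i * spacing
        left = max(peak - spacing, lo) if i > 0 else lo
        right = min(peak + spacing, hi) if i < n - 1 else hi
        if fou_width == 0:
            sets[lab] = TriangularMF(left, peak, right)
        elif not n_zslices:
            sets[lab] = _blurred_triangle(left, peak, right, fou_width)
        else:
            z_levels = tuple((k + 1) / n_zslices for k in range(n_zslices))
            widths = [fou_width * (1 - k / n_zslices) for k in range(n_zslices)]
            slices = tuple(
                _blurred_triangle(left, peak, right, w) for w in widths
            )
            sets[lab] = ZSliceSet(z_levels, slices)
    return LinguisticVariable(
        name=name or "x", universe=(lo, hi), sets=sets, labels=tuple(labels)
    )


def build_fou_from_stats(
    mean: float,
    sd: float,
    scale: float = 1.0,
    halfwidth: float | None = None,
    group_stats: Sequence[tuple[float, float]] | None = None,
) -> FuzzySet:
    """Heuristic FOU construction from signal statistics.

    The principal triangle is centered on ``mean`` with base half-width
    ``halfwidth`` (default ``3*sd``); the FOU half-width is
    ``scale*sd``, spreading the upper MF's feet out and the lower MF's
    feet in by that amount.  ``sd == 0`` degenerates to a type-1
    triangle.  With per-group ``(mean, sd)`` statistics (up to five
    groups, emulating patient subgroups), one FOU is built per group and
    the FOUs are stacked as zSlices ordered by decreasing dispersion;
    groups whose FOUs cannot be nested even after sorting by width raise
    an error.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if group_stats is not None:
        if not 1 <= len(group_stats) <= 5:
            raise ValueError("between 1 and 5 groups are supported")
        ordered = sorted(group_stats, key=lambda ms: -ms[1])
        n = len(ordered)
        z_levels = tuple((k + 1) / n for k in range(n))
        slices = []
        for gmean, gsd in ordered:
            s = build_fou_from_stats(gmean, gsd, scale, halfwidth)
            if isinstance(s, TriangularMF):
                s = IntervalType2Set(s, s)
            slices.append(s)
        try:
            return ZSliceSet(z_levels, tuple(slices))
        except ValueError as err:
            raise ValueError(f"group FOUs are not nestable: {err}") from err
    h = 3.0 * sd if halfwidth is None else halfwidth
    if sd == 0 or scale == 0:
        return TriangularMF(mean - h, mean, mean + h)
    w = scale * sd
    if w > h:
        raise ValueError("FOU half-width scale*sd exceeds the triangle base")
    return IntervalType2Set(
        TriangularMF(mean - h + w, mean, mean + h - w),
        TriangularMF(mean - h - w, mean, mean + h + w),
    )
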