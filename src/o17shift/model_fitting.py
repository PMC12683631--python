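"""Fixed-exponent power-law fits and linear calibration fits.

These are the fits that produced the model constants: shift-vs-distance
scans are fitted to ``slope / r^n`` with n fixed at 4 (water-water) or
6 (DMSO / CH contacts), through the origin because the shift must
vanish at infinite separation; predicted-vs-target pairs are fitted by
ordinary least squares, optionally constrained through the origin and
partitioned into dangling / no-dangling sites.

For through-origin fits, R^2 is computed against the uncentered sum of
squares (sum of y^2), the convention consistent with a model that has
no intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ScanPoint",
    "PowerLawFit",
    "LinearCalibration",
    "PredictorCalibration",
    "fit_power_law",
    "fit_linear",
    "calibrate_predictor",
]


class ScanPoint(NamedTuple):
    """One (distance, shift) point of a scan; r in Angstrom, delta in ppm."""

    r: float
    delta: float


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting delta = slope / r^exponent (+ intercept)."""

    exponent: int
    slope: float
    r_squared: float
    intercept: float = 0.0

    def __call__(self, r: float) -> float:
        return self.slope * r ** -self.exponent + self.intercept


@dataclass(frozen=True)
class LinearCalibration:
    """Result of an ordinary least-squares line fit."""

    slope: float
    intercept: float
    r_squared: float

    def __call__(self, x: float) -> float:
        return self.slope * x + self.intercept


class PredictorCalibration(NamedTuple):
    no_dangling: LinearCalibration
    dangling: LinearCalibration


def _r_squared(y: np.ndarray, pred: np.ndarray, centered: bool) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2) if centered else np.sum(y ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_power_law(points: Sequence[ScanPoint | tuple[float, float]],
                  exponent: int, through_origin: bool = True) -> PowerLawFit:
    """Least-squares slope of delta against r^-exponent.

    ``through_origin=True`` (the default, matching the asymptotic
    rationale that the shift vanishes at infinite separation) fixes a
    zero intercept and needs at least one point; the free-intercept
    variant needs at least two distinct distances.
    """
    pts = [ScanPoint(float(r), float(d)) for r, d in points]
    if any(p.r <= 0 for p in pts):
        raise ValueError("scan distances must be positive")
    min_pts = 1 if through_origin else 2
    if len(pts) < min_pts:
        raise ValueError(f"need at least {min_pts} point(s)")
    r = np.array([p.r for p in pts])
    y = np.array([p.delta for p in pts])
    x = r ** -float(exponent)
    if not through_origin and len(np.unique(r)) < 2:
        raise ValueError("free-intercept fit needs at least two distinct distances")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        (slope, intercept), *_ = np.linalg.lstsq(
            np.column_stack([x, np.ones_like(x)]), y, rcond=None)
        slope, intercept = float(slope), float(intercept)
    pred = slope * x + intercept
    return PowerLawFit(exponent=int(exponent), slope=slope,
                       r_squared=_r_squared(y, pred, centered=not through_origin),
                       intercept=intercept)


def fit_linear(x: Sequence[float], y: Sequence[float],
               with_intercept: bool = True) -> LinearCalibration:
    """Ordinary least squares line, optionally constrained through 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0.0 and with_intercept:
        raise ValueError("degenerate fit: all x values are equal")
    if with_intercept:
        design = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    else:
        if np.all(x == 0.0):
            raise ValueError("degenerate fit: all x values are zero")
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    pred = slope * x + intercept
    return LinearCalibration(float(slope), float(intercept),
                             _r_squared(y, pred, centered=with_intercept))


def calibrate_predictor(pairs: Sequence[tuple[float, float]],
                        dangling: Sequence[bool],
                        with_intercept: bool = True) -> PredictorCalibration:
    """Independent calibration fits for dangling and no-dangling sites.

    ``pairs`` holds (predicted, target) shifts in ppm; ``dangling``
    flags each pair.  Each partition needs at least two pairs.
    """
    if len(pairs) != len(dangling):
        raise ValueError("pairs and dangling flags must have equal length")
    fits = {}
    for name, flag in (("no_dangling", False), ("dangling", True)):
        sel = [(p, t) for (p, t), d in zip(pairs, dangling) if bool(d) == flag]
        if len(sel) < 2:
            raise ValueError(f"partition {name!r} has {len(sel)} pair(s); need >= 2")
        xs, ys = zip(*sel)
        fits[name] = fit_linear(xs, ys, with_intercept=with_intercept)
    return PredictorCalibration(**fits)
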