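"""Shape-preserving piecewise cubic Hermite interpolation (pchip) onto a 1-minute grid.

The interpolant is the monotone Hermite scheme of Fritsch and Carlson:
knot derivatives are weighted harmonic means of adjacent secant slopes,
zeroed at local extrema, with shape-preserving one-sided three-point end
conditions. On any knot interval whose endpoints are monotone the
interpolant is monotone (no overshoot), which keeps interpolated
concentration curves physiologically plausible between sparse samples.

Implemented directly (derivative rule + Hermite basis evaluation) so the
interpolant can be validated against an independent reference
implementation; no extrapolation beyond the knot span is permitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import BicarbSeries, ValidationError


class ExtrapolationError(ValueError):
    """Requested grid extends beyond the observed knot span."""


@dataclass(frozen=True)
class InterpolatedProfile:
    """The 1-minute-grid concentration curve for one subject-visit.

    grid runs from grid_start to grid_end inclusive (integer minutes);
    values[i] is the interpolated [HCO3-] at grid[i]. Values at knot
    minutes equal the observed knot values to numerical tolerance.
    """

    subject_id: str
    visit: int
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.values):
            raise ValidationError("grid and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("interpolated values must be finite")


def _pchip_derivatives(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fritsch-Carlson knot derivatives.

    Interior: zero where the secant slope changes sign (local extremum),
    otherwise the interval-length-weighted harmonic mean of the two secants.
    Ends: the non-centred three-point formula, clipped so the end interval
    stays monotone (d set to 0 if it opposes the secant, capped at 3x the
    secant when the data turn).
    """
    h = np.diff(x)
    delta = np.diff(y) / h
    n = len(x)
    d = np.zeros(n)

    if n == 2:
        d[:] = delta[0]
        return d

    # interior knots
    for k in range(1, n - 1):
        if delta[k - 1] == 0.0 or delta[k] == 0.0 or np.sign(delta[k - 1]) != np.sign(delta[k]):
            d[k] = 0.0
        else:
            w1 = 2.0 * h[k] + h[k - 1]
            w2 = h[k] + 2.0 * h[k - 1]
            d[k] = (w1 + w2) / (w1 / delta[k - 1] + w2 / delta[k])

    def edge(h0, h1, d0, d1):
        v = ((2.0 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
        if np.sign(v) != np.sign(d0):
            return 0.0
        if np.sign(d0) != np.sign(d1) and abs(v) > 3.0 * abs(d0):
            return 3.0 * d0
        return v

    d[0] = edge(h[0], h[1], delta[0], delta[1])
    d[-1] = edge(h[-1], h[-2], delta[-1], delta[-2])
    return d


def _hermite_eval(x: np.ndarray, y: np.ndarray, d: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate the cubic Hermite interpolant with knot values y and derivatives d."""
    idx = np.clip(np.searchsorted(x, t, side="right") - 1, 0, len(x) - 2)
    h = x[idx + 1] - x[idx]
    s = (t - x[idx]) / h
    # incremental form: exact at knots and for constant data
    h01 = s**2 * (3 - 2 * s)
    h10 = s * (1 - s) ** 2
    h11 = s**2 * (s - 1)
    return y[idx] + h01 * (y[idx + 1] - y[idx]) + h * (h10 * d[idx] + h11 * d[idx + 1])


def pchip_values(times, concentrations, query) -> np.ndarray:
    """Monotone pchip interpolation of (times, concentrations) at query points."""
    x = np.asarray(times, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    t = np.asarray(query, dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least 2 knots to interpolate")
    d = _pchip_derivatives(x, y)
    return _hermite_eval(x, y, d, t)


def pchip_interpolate(
    series: BicarbSeries, grid_start: int = 0, grid_end: int = 240
) -> InterpolatedProfile:
    """Interpolate one subject-visit's knots onto the integer-minute grid.

    The grid must lie within the observed knot span; values are computed once
    and cached in the returned profile, which all downstream metrics read.
    """
    x = np.asarray(series.times, dtype=float)
    if len(x) < 2:
        raise ValidationError(
            f"{series.subject_id} visit {series.visit}: need >= 2 knots"
        )
    if grid_start < x[0] or grid_end > x[-1]:
        raise ExtrapolationError(
            f"grid [{grid_start}, {grid_end}] exceeds knot span [{x[0]:g}, {x[-1]:g}]; "
            "extrapolation is not performed"
        )
    grid = np.arange(grid_start, grid_end + 1)
    values = pchip_values(series.times, series.concentrations, grid)
    return InterpolatedProfile(
        subject_id=series.subject_id, visit=series.visit, grid=grid, values=values
    )


def value_at(profile: InterpolatedProfile, t: int) -> float:
    """Return the cached grid value at integer minute t."""
    t0, t1 = int(profile.grid[0]), int(profile.grid[-1])
    if not t0 <= t <= t1:
        raise ValueError(f"t={t} outside grid [{t0}, {t1}]")
    return float(profile.values[int(t) - t0])
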