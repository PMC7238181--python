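"""Surface roughness and three-point-bend mechanics of filaments.

Roughness statistics from a profilometry height trace over the sampling
length: Rav, the arithmetic mean absolute deviation of heights from their
mean, and Rz, the peak-to-valley height (both in micrometres; Rz is taken
over the full sampling length, not per ISO sub-lengths).

From a three-point-bend force-travel record: the bending modulus as the
least-squares gradient of the initial linear section (N/mm, reported in the
N mm convention of texture-analyser software), and toughness as the total
trapezoidal area under the force-travel curve (N mm).  The "initial linear
section" is found by greedy prefix growth: starting from a minimum fraction
of the travel range, the fitted prefix is extended point by point for as long
as its linear fit keeps R^2 at or above a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RoughnessProfile",
    "ForceCurve",
    "average_roughness",
    "max_height",
    "bending_modulus",
    "toughness",
]


@dataclass
class RoughnessProfile:
    """Profilometry trace: positions (mm) along the sampling length, heights (um)."""

    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.positions.shape != self.heights.shape or self.positions.ndim != 1:
            raise ValueError("positions and heights must be equal-length 1-D arrays")
        if self.positions.size < 10:
            raise ValueError("need at least 10 measurement points")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class ForceCurve:
    """Three-point-bend record: travel (mm, from 0, non-decreasing), force (N)."""

    travel: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.travel = np.asarray(self.travel, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.travel.shape != self.force.shape or self.travel.ndim != 1:
            raise ValueError("travel and force must be equal-length 1-D arrays")
        if self.travel[0] != 0:
            raise ValueError("travel must start at 0")
        if np.any(np.diff(self.travel) < 0):
            raise ValueError("travel must be non-decreasing")


def average_roughness(p: RoughnessProfile) -> float:
    """Arithmetic average roughness Rav (um): mean |Z_n - mean(Z)|."""
    z = p.heights
    if z.size < 2:
        raise ValueError("need at least 2 height points")
    return float(np.mean(np.abs(z - z.mean())))


def max_height(p: RoughnessProfile) -> float:
    """Peak-to-valley height Rz (um): max(Z) - min(Z) over the sampling length."""
    if p.heights.size < 2:
        raise ValueError("need at least 2 height points")
    return float(np.ptp(p.heights))


def bending_modulus(
    fc: ForceCurve,
    linear_fraction: float = 0.15,
    r2_threshold: float = 0.99,
    deviation_tol: float = 0.01,
) -> float:
    """Gradient of the initial linear section of the force-travel curve (N/mm).

    The elastic region is grown greedily from the start: an OLS line is fitted
    to the minimum prefix (at least ``linear_fraction`` of the maximum travel,
    never fewer than 5 points) and extended one point at a time for as long as
    the next point stays inside a residual band around the running fit — the
    larger of 3x the fit's RMS residual (tracks measurement noise) and
    ``deviation_tol`` relative to the predicted force (catches a noise-free
    yield kink within about one sample).  The returned gradient is the OLS
    slope over the accepted prefix.  If even the minimum prefix fails the
    ``r2_threshold`` linearity check, its slope is returned with a warning.
    """
    x, y = fc.travel, fc.force
    if x.size < 5:
        raise ValueError("need at least 5 points")
    min_travel = linear_fraction * x[-1]
    n_min = max(5, int(np.searchsorted(x, min_travel, side="right")))
    n_min = min(n_min, x.size)

    def fit(n):
        res = stats.linregress(x[:n], y[:n])
        resid = y[:n] - (res.slope * x[:n] + res.intercept)
        ss = np.sum((y[:n] - y[:n].mean()) ** 2)
        r2 = 1.0 if ss == 0 and np.allclose(y[:n], y[0]) else float(res.rvalue**2)
        return float(res.slope), float(res.intercept), float(np.sqrt(np.mean(resid**2))), r2

    slope, intercept, rms, r2 = fit(n_min)
    if r2 < r2_threshold:
        warnings.warn(
            "initial prefix is not linear at the configured R^2 threshold; "
            f"falling back to the first {linear_fraction:.0%} of travel",
            stacklevel=2,
        )
        return slope
    n = n_min
    while n < x.size:
        pred = slope * x[n] + intercept
        band = max(3.0 * rms, deviation_tol * abs(pred))
        if abs(y[n] - pred) > band:
            break
        n += 1
        slope, intercept, rms, r2 = fit(n)
    return slope


def toughness(fc: ForceCurve) -> float:
    """Total area under the force-travel curve (N mm), by the trapezoidal rule."""
    return float(np.trapezoid(fc.force, fc.travel))
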