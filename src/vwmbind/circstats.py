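"""Circular statistics on the interval [-pi, pi).

All angles in this package live on the full circle in radians, stored in the
half-open interval [-pi, pi).  Bar orientations, whose native space only covers
180 degrees, are doubled on load so that the three feature dimensions
(location, color, orientation) share a single circular metric; reporting
utilities may halve them again for display.

The dispersion measure used throughout is Fisher's circular standard
deviation, ``sqrt(-2 ln R)`` with ``R`` the mean resultant length.  It is 0
for coincident angles and diverges to +inf as the sample approaches perfect
uniformity (R -> 0); callers must be prepared for the infinite value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "wrap",
    "circ_dist",
    "mean_resultant",
    "circ_summary",
    "CircSummary",
    "circular_sd",
    "circular_mad",
    "v_test",
    "abs_error_correlation",
]

TWO_PI = 2.0 * np.pi


def wrap(angle):
    """Wrap angles into [-pi, pi).  pi maps to -pi (half-open convention)."""
    angle = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(angle)):
        raise ValueError("wrap: non-finite angle")
    out = np.mod(angle + np.pi, TWO_PI) - np.pi
    # mod may return 2*pi - eps rounded to 2*pi for inputs just below -pi
    out = np.where(out >= np.pi, out - TWO_PI, out)
    if out.ndim == 0:
        return float(out)
    return out


def circ_dist(a, b):
    """Signed shortest angular distance a - b, in [-pi, pi)."""
    return wrap(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class CircSummary:
    """First-order summary of a circular sample."""

    n: int
    mean_dir: float
    R: float
    circ_sd: float


def mean_resultant(angles) -> tuple[float, float]:
    """Mean direction and mean resultant length R of a sample of angles."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("mean_resultant: empty sample")
    z = np.exp(1j * angles).mean()
    return float(np.angle(z)), float(np.abs(z))


def circ_summary(angles) -> CircSummary:
    angles = np.asarray(angles, dtype=float)
    mu, R = mean_resultant(angles)
    # resultants at rounding-noise level are treated as exactly zero
    with np.errstate(divide="ignore"):
        sd = float(np.sqrt(-2.0 * np.log(R))) if R > 1e-12 else float("inf")
    return CircSummary(n=angles.size, mean_dir=mu, R=R, circ_sd=sd)


def circular_sd(angles) -> float:
    """Fisher circular standard deviation sqrt(-2 ln R).

    Returns +inf when the mean resultant length is exactly zero (e.g. two
    antipodal angles); this is a documented value, not an error.
    """
    return circ_summary(angles).circ_sd


def circular_mad(deviations) -> float:
    """Mean absolute circular deviation.  pi/2 for uniform responses."""
    d = wrap(np.asarray(deviations, dtype=float))
    if d.size == 0:
        raise ValueError("circular_mad: empty sample")
    return float(np.mean(np.abs(d)))


def v_test(angles, hypothesized_mean: float) -> tuple[float, float]:
    """V-test for nonuniformity toward a hypothesized mean direction.

    V = n * R * cos(mean_dir - mu0); the p-value uses the one-sided
    large-sample normal approximation of u = V * sqrt(2 / n).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise ValueError("v_test: need at least 2 angles")
    n = angles.size
    mu, R = mean_resultant(angles)
    V = n * R * np.cos(mu - hypothesized_mean)
    u = V * np.sqrt(2.0 / n)
    p = float(_sstats.norm.sf(u))
    return float(V), p


def abs_error_correlation(err1, err2) -> float:
    """Pearson correlation between absolute response errors of two reports."""
    a = np.abs(np.asarray(err1, dtype=float))
    b = np.abs(np.asarray(err2, dtype=float))
    if a.shape != b.shape:
        raise ValueError("abs_error_correlation: length mismatch")
    if a.size < 3:
        raise ValueError("abs_error_correlation: need at least 3 trials")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("abs_error_correlation: zero variance")
    return float(_sstats.pearsonr(a, b)[0])
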