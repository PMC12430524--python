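"""Circular (directional) statistics for torsion angles in degrees.

Backbone dihedrals live on the circle: the arithmetic mean of {170, -170}
is 0 but the two conformations are 20 degrees apart across the wrap.  All
averaging and differencing in this package goes through these helpers.
Angles are stored in degrees on the half-open interval (-180, 180].
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np

__all__ = [
    "wrap_angle",
    "wrap_difference",
    "circular_mean",
    "circular_stats",
    "CircularStats",
]

#: Resultant lengths below this are treated as directionless (mean undefined).
RESULTANT_EPS = 1e-9


def wrap_angle(angle):
    """Wrap angle(s) in degrees onto (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = np.mod(a + 180.0, 360.0) - 180.0
    # mod maps onto [-180, 180); fold the closed end to +180
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def wrap_difference(a, b):
    """Signed circular difference a - b in degrees, in (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


class CircularStats(NamedTuple):
    mean: float          # circular mean, degrees in (-180, 180]; NaN if undefined
    sd: float            # circular standard deviation, degrees
    resultant: float     # mean resultant length in [0, 1]


def circular_mean(values, axis=None):
    """Circular mean in degrees along ``axis`` (NaN where undefined)."""
    rad = np.deg2rad(np.asarray(values, dtype=float))
    s = np.mean(np.sin(rad), axis=axis)
    c = np.mean(np.cos(rad), axis=axis)
    r = np.hypot(s, c)
    mean = wrap_angle(np.rad2deg(np.arctan2(s, c)))
    return np.where(r < RESULTANT_EPS, np.nan, mean) if np.ndim(mean) else (
        float("nan") if r < RESULTANT_EPS else mean
    )


def circular_sd_from_resultant(r):
    """Circular standard deviation (degrees) from resultant length."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        sd = np.sqrt(np.maximum(-2.0 * np.log(np.clip(r, 1e-300, 1.0)), 0.0))
    return np.rad2deg(sd)


def circular_stats(values) -> CircularStats:
    """Mean direction, circular SD and resultant length of a 1-D sample.

    If the sample is (numerically) balanced around the circle the resultant
    length vanishes and no mean direction exists; the mean is returned as
    NaN with a warning rather than an arbitrary direction.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("circular_stats requires a nonempty sample")
    rad = np.deg2rad(values)
    s = float(np.mean(np.sin(rad)))
    c = float(np.mean(np.cos(rad)))
    r = float(np.hypot(s, c))
    if r < RESULTANT_EPS:
        warnings.warn(
            "resultant length ~ 0: circular mean is undefined for this sample",
            RuntimeWarning,
            stacklevel=2,
        )
        mean = float("nan")
    else:
        mean = wrap_angle(np.rad2deg(np.arctan2(s, c)))
    sd = float(circular_sd_from_resultant(r))
    return CircularStats(mean=mean, sd=sd, resultant=r)


def unwrap_about(values, center):
    """Represent angles as real numbers center + signed offset.

    Used before applying linear statistics (e.g. a t-test) to angular data:
    each value is mapped to the representative of its wrap class nearest to
    ``center``, so ordinary moments are meaningful as long as the sample is
    concentrated (well within a half-circle of the center).
    """
    return np.asarray(center, dtype=float) + wrap_difference(values, center)
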