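"""Shared numeric helpers: circular arithmetic in degrees and LOESS smoothing.

All angles in this package are degrees in [0, 360), counter-clockwise
positive, with movement direction defined as ``atan2(fb, rl)`` (forward
speed over rightward speed).
"""

from __future__ import annotations

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess


def wrap_deg(angle):
    """Wrap angle(s) to [0, 360)."""
    return np.mod(angle, 360.0)


def wrap_signed_deg(angle):
    """Wrap angle difference(s) to (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    out = np.where(a > 180.0, a - 360.0, a)
    # map -180 exactly to +180 so the interval is (-180, 180]
    out = np.where(np.isclose(out, -180.0), 180.0, out)
    return out if np.ndim(angle) else float(out)


def circ_dist_deg(a, b):
    """Unsigned circular distance between angles, in [0, 180]."""
    return np.abs(wrap_signed_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def circ_mean_deg(angles, weights=None):
    """Circular mean of angles in degrees, result in [0, 360)."""
    ang = np.deg2rad(np.asarray(angles, dtype=float))
    if weights is None:
        s, c = np.sin(ang).sum(), np.cos(ang).sum()
    else:
        w = np.asarray(weights, dtype=float)
        s, c = (w * np.sin(ang)).sum(), (w * np.cos(ang)).sum()
    return float(wrap_deg(np.rad2deg(np.arctan2(s, c))))


def loess_smooth(y: np.ndarray, span: int, x: np.ndarray | None = None) -> np.ndarray:
    """Locally linear (tricube-weighted) smoother with a fixed window length.

    Parameters
    ----------
    y : 1-D array of samples.
    span : window width in samples; near the edges the effective window
        shrinks as the fraction-of-data neighbourhood is clipped.
    x : optional abscissa; defaults to the sample index.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("empty trace")
    if n <= 2 or span <= 1:
        return y.copy()
    frac = min(1.0, span / n)
    if x is None:
        x = np.arange(n, dtype=float)
    # delta skips redundant local fits; keeps long traces fast without
    # visibly changing the smooth at our spans
    delta = 0.0 if n < 5000 else 0.002 * (x[-1] - x[0])
    sm = lowess(y, x, frac=frac, it=0, delta=delta, return_sorted=False)
    return np.asarray(sm, dtype=float)
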