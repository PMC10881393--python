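"""Circular arithmetic, circular statistics and the smoothing filters used
throughout the pipeline.

All azimuthal quantities (heading, goal, bar position, bump phase, wind
direction) are angles in degrees wrapped to the half-open interval
``(-180, 180]``, measured positive anticlockwise.  The closed-loop bar on the
arena is the *inverse* of the fly's heading, so a single helper,
:func:`heading_from_bar`, performs the sign flip; nothing else in the package
touches that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "wrap_angle",
    "circ_dist",
    "circ_mean",
    "circ_std",
    "circ_corr",
    "heading_from_bar",
    "heading_vector_length",
    "boxcar_filter",
    "gaussian_filter",
    "StabilitySeries",
]


def wrap_angle(x):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180].

    Accepts scalars or arrays; NaN is propagated but infinities are rejected.
    """
    x = np.asarray(x, dtype=float)
    if np.isinf(x).any():
        raise ValueError("non-finite angle")
    wrapped = -np.mod(-x + 180.0, 360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def circ_dist(a, b):
    """Signed shortest rotation from ``b`` to ``a`` in degrees, in (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def circ_mean(angles, weights=None, axis=None):
    """Weighted circular mean and resultant length.

    Parameters
    ----------
    angles : array-like of degrees
    weights : optional non-negative weights, same shape
    axis : axis along which to reduce (default: all)

    Returns
    -------
    mean : degrees in (-180, 180]; NaN where the resultant vanishes
    resultant_length : in [0, 1]
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circ_mean of empty input")
    rad = np.radians(angles)
    if weights is None:
        z = np.exp(1j * rad)
        total = np.sum(np.isfinite(rad), axis=axis)
        resultant = np.nansum(np.where(np.isfinite(rad), z, 0), axis=axis)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("negative weights")
        total = np.sum(weights, axis=axis)
        if np.all(total == 0):
            raise ValueError("weights sum to zero")
        resultant = np.sum(weights * np.exp(1j * rad), axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.abs(resultant) / total
    mean = wrap_angle(np.degrees(np.angle(resultant)))
    # a vanishing resultant leaves the mean undefined
    tiny = R < 1e-12
    if np.ndim(mean):
        mean = np.where(tiny, np.nan, mean)
    elif tiny:
        mean = float("nan")
    return mean, R


def circ_std(angles=None, weights=None, *, R=None):
    """Circular standard deviation sqrt(-2 ln R), in degrees.

    Either pass samples (and optional weights) or a precomputed resultant
    length ``R``.  For tight distributions this converges to the linear
    standard deviation of the wrapped residuals.
    """
    if R is None:
        _, R = circ_mean(angles, weights)
    R = np.clip(R, 1e-300, 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(R))))


def circ_corr(a, b):
    """Circular-circular correlation coefficient (Fisher & Lee / Jammalamadaka).

    Used to relate a decoded bump phase to the bar position over a recording.
    """
    a = np.radians(np.asarray(a, dtype=float))
    b = np.radians(np.asarray(b, dtype=float))
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    abar = np.angle(np.exp(1j * a).mean())
    bbar = np.angle(np.exp(1j * b).mean())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return float("nan")
    return float((sa * sb).sum() / denom)


def heading_from_bar(bar):
    """Heading angle from closed-loop bar position (the bar is the inverse
    of the fly's heading)."""
    return wrap_angle(-np.asarray(bar, dtype=float))


@dataclass
class StabilitySeries:
    """Mean heading-vector length R over a centred sliding window.

    ``t`` are the timestamps of the *retained* (moving) samples; standstill
    samples are removed and the record concatenated before windowing, so a
    window may span a gap in real time.
    """

    t: np.ndarray
    R: np.ndarray
    window: float


def heading_vector_length(t, heading, standstill=None, window=60.0, fs=None):
    """Continuous heading-stability estimate R in [0, 1].

    Each retained heading sample is a unit vector; R at a sample is the
    resultant length over the centred window of ``window`` seconds counted in
    retained samples (standstill samples removed, record concatenated).

    Returns a :class:`StabilitySeries`; R is NaN everywhere if the retained
    record is shorter than the window.
    """
    t = np.asarray(t, dtype=float)
    heading = np.asarray(heading, dtype=float)
    if standstill is not None:
        keep = ~np.asarray(standstill, dtype=bool)
        t, heading = t[keep], heading[keep]
    if fs is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate")
        fs = 1.0 / np.median(np.diff(t))
    n_win = int(round(window * fs))
    n_win = max(n_win, 1)
    if n_win > len(t):
        return StabilitySeries(t=t, R=np.full(len(t), np.nan), window=window)
    z = np.exp(1j * np.radians(heading))
    # centred moving resultant via uniform filter on real/imag parts
    re = ndimage.uniform_filter1d(z.real, n_win, mode="nearest")
    im = ndimage.uniform_filter1d(z.imag, n_win, mode="nearest")
    R = np.hypot(re, im)
    return StabilitySeries(t=t, R=np.clip(R, 0.0, 1.0), window=window)


def _width_to_samples(width, fs):
    n = int(round(width * fs))
    return n


def boxcar_filter(x, width=0.5, fs=50.0):
    """Centred moving average of ``width`` seconds (default 500 ms).

    Edges shrink the window (the average runs over the samples available).
    A width below one sample interval returns the input unchanged with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    n = _width_to_samples(width, fs)
    if n <= 1:
        warnings.warn("boxcar width below one sample interval; returning input")
        return x.copy()
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def gaussian_filter(x, sigma=0.2, fs=50.0):
    """Gaussian smoothing with ``sigma`` seconds (default 200 ms), reflected
    padding at the edges."""
    x = np.asarray(x, dtype=float)
    sigma_samples = sigma * fs
    if sigma_samples <= 0:
        raise ValueError("sigma must be positive")
    return ndimage.gaussian_filter1d(x, sigma_samples, mode="reflect")
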