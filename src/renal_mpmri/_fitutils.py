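"""Vectorised least-squares helpers shared by the mapping modules."""

from __future__ import annotations

import numpy as np

from .core import FIT_FAIL, FIT_OK


def loglinear_decay_fit(
    signals: np.ndarray,
    x: np.ndarray,
    min_points: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``log(S) = log(S0) - rate * x`` per voxel by ordinary least squares.

    Non-positive samples are dropped voxel-wise before taking the log; a
    voxel is flagged as failed when fewer than ``min_points`` usable samples
    remain.  Used for both T2* (x = TE) and ADC (x = b) mapping, where the
    decay rate is 1/T2* or the ADC respectively.

    Parameters
    ----------
    signals : (V, n) array
        Signal samples per voxel.
    x : (n,) array
        Abscissa (echo time in ms or b-value in s/mm²).

    Returns
    -------
    rate, s0, r_squared, status : (V,) arrays
        Decay rate (slope of -log S vs x), intercept amplitude, coefficient
        of determination of the log-domain fit, and FIT_* status codes.
    """
    signals = np.asarray(signals, dtype=float)
    x = np.asarray(x, dtype=float)
    V, n = signals.shape
    usable = signals > 0
    n_use = usable.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(usable, np.log(np.where(usable, signals, 1.0)), 0.0)
    w = usable.astype(float)

    # Weighted (0/1) normal equations per voxel.
    sw = w.sum(axis=1)
    sx = (w * x).sum(axis=1)
    sy = (w * logs).sum(axis=1)
    sxx = (w * x * x).sum(axis=1)
    sxy = (w * x * logs).sum(axis=1)
    denom = sw * sxx - sx * sx
    good = (n_use >= min_points) & (denom > 0)
    denom_safe = np.where(good, denom, 1.0)
    slope = (sw * sxy - sx * sy) / denom_safe
    intercept = (sy - slope * sx) / np.where(good, sw, 1.0)

    # R² in the log domain over the usable points.
    ybar = sy / np.where(sw > 0, sw, 1.0)
    ss_tot = (w * (logs - ybar[:, None]) ** 2).sum(axis=1)
    resid = logs - (intercept[:, None] + slope[:, None] * x[None, :])
    ss_res = (w * resid**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)

    rate = -slope
    status = np.where(good, FIT_OK, FIT_FAIL)
    rate = np.where(good, rate, np.nan)
    s0 = np.where(good, np.exp(intercept), np.nan)
    r2 = np.where(good, r2, np.nan)
    return rate, s0, r2, status
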