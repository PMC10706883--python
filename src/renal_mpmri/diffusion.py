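"""ADC mapping from multi-b, multi-direction diffusion-weighted series.

The acquisition samples each b-value along three orthogonal diffusion
directions to reduce the influence of anisotropy.  Directions are combined
by the geometric mean per b-value — the arithmetic mean in the log domain,
so combination and the subsequent log-linear fit commute, and for an
anisotropic voxel the fitted ADC is exactly the mean of the per-direction
ADCs.  The combined decay is then fit by ordinary least squares of log(S)
on b over all b-values (mono-exponential; no intravoxel-incoherent-motion
separation, so perfusion contamination at low b biases ADC upward — a
documented property of the protocol, not corrected here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fitutils import loglinear_decay_fit
from .core import FIT_FAIL, FIT_OK, AcquisitionSeries, ParameterMap

__all__ = ["ADCFitResult", "combine_directions", "fit_adc", "PAPER_B_VALUES"]

# Default acquisition protocol: 11 b-values in s/mm².
PAPER_B_VALUES = (0.0, 5.0, 10.0, 20.0, 30.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0)


@dataclass
class ADCFitResult:
    adc: ParameterMap  # mm²/s
    s0: ParameterMap
    r_squared: np.ndarray
    status: np.ndarray


def combine_directions(series: AcquisitionSeries) -> AcquisitionSeries:
    """Geometric-mean combination of diffusion directions per b-value.

    Volumes sharing a b-value are combined as ``(prod S_d)^(1/D)``.  If a
    voxel has a non-positive sample in any direction at some b, the
    geometric mean is taken over its positive directions only (and over
    none, the output is 0, which the ADC fit then drops or flags).
    """
    b = np.asarray(series.params["b_s_mm2"], dtype=float)
    ub = np.unique(b)
    out = np.empty(series.shape + (ub.size,))
    for i, bv in enumerate(ub):
        vols = series.data[..., b == bv]
        pos = vols > 0
        npos = pos.sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logsum = np.where(pos, np.log(np.where(pos, vols, 1.0)), 0.0).sum(axis=-1)
            gm = np.exp(logsum / np.where(npos > 0, npos, 1))
        out[..., i] = np.where(npos > 0, gm, 0.0)
    return AcquisitionSeries(
        data=out,
        params={"b_s_mm2": ub},
        voxel_size_mm=series.voxel_size_mm,
        meta={**series.meta, "directions_combined": True},
    )


def fit_adc(
    series: AcquisitionSeries,
    mask: np.ndarray | None = None,
    min_points: int = 3,
) -> ADCFitResult:
    """Fit the apparent diffusion coefficient voxel-wise.

    Multi-direction input is first geometric-mean combined.  Requires at
    least 3 b-values including one below 50 s/mm² (an S0 anchor).  The ADC
    is the negative slope of log(S) vs b; voxels with an increasing signal
    (negative slope estimate) are flagged rather than returned negative.
    """
    b_all = np.asarray(series.params["b_s_mm2"], dtype=float)
    if np.unique(b_all).size != b_all.size:
        series = combine_directions(series)
    b = np.asarray(series.params["b_s_mm2"], dtype=float)
    if b.size < min_points or b.min() >= 50.0:
        raise ValueError("ADC fit requires >= 3 b-values including one < 50 s/mm²")

    shape = series.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    Y = series.data[mask]
    rate, s0, r2, status_v = loglinear_decay_fit(Y, b, min_points=min_points)
    negative = (status_v == FIT_OK) & (rate < 0)
    status_v = np.where(negative, FIT_FAIL, status_v)
    adc = np.where(status_v == FIT_OK, rate, np.nan)
    s0 = np.where(status_v == FIT_OK, s0, np.nan)
    r2 = np.where(status_v == FIT_OK, r2, np.nan)

    def to_map(vec: np.ndarray) -> np.ndarray:
        vol = np.full(shape, np.nan)
        vol[mask] = vec
        return vol

    status = np.full(shape, FIT_FAIL, dtype=int)
    status[mask] = status_v
    r2_map = to_map(r2)
    vx = series.voxel_size_mm
    return ADCFitResult(
        adc=ParameterMap(to_map(adc), "mm^2/s", "ADC", gof=r2_map, status=status,
                         voxel_size_mm=vx),
        s0=ParameterMap(to_map(s0), "a.u.", "S0", status=status, voxel_size_mm=vx),
        r_squared=r2_map,
        status=status,
    )
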