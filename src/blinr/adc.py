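"""Apparent diffusion coefficient quantitation.

ADC maps come from the mono-exponential diffusion model S(b) = S0·exp(−b·ADC),
fitted voxel-wise by ordinary least squares on ln S versus b: the slope is
−ADC and the intercept ln S0.  Non-positive signals are excluded from the log
domain per voxel; voxels with fewer than two usable samples are marked invalid
(adc = 0, mask False).  Negative fitted ADCs are retained and simply reflect
noise; clamping is left to reporting code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import GridSpec, Volume3D

__all__ = ["ADCMap", "fit_adc", "tube_adc_mae", "TubeMAE"]


@dataclass
class ADCMap:
    """Voxel-wise ADC (mm²·s⁻¹), fitted S0, and validity mask."""

    grid: GridSpec
    adc: np.ndarray
    s0: np.ndarray
    valid_mask: np.ndarray


def fit_adc(volumes: list[tuple[float, Volume3D]]) -> ADCMap:
    """Log-linear least-squares ADC fit across b-values.

    Needs at least two distinct b-values on a common grid.  A two-point fit
    reduces to the closed form ADC = ln(S1/S2)/(b2 − b1).
    """
    if len(volumes) < 2:
        raise ValueError("fit_adc needs at least 2 b-values")
    bs = np.array([float(b) for b, _ in volumes])
    if len(set(bs.tolist())) != len(bs):
        raise ValueError("b-values must be distinct")
    grid = volumes[0][1].grid
    for _, v in volumes:
        if v.grid != grid:
            raise ValueError("all volumes must share one grid")

    S = np.stack([v.data for _, v in volumes], axis=0)  # (B, nx, ny, nz)
    w = S > 0
    logS = np.where(w, np.log(np.where(w, S, 1.0)), 0.0)
    b = bs[:, None, None, None]

    n = w.sum(axis=0)
    sx = (w * b).sum(axis=0)
    sy = logS.sum(axis=0)
    sxx = (w * b * b).sum(axis=0)
    sxy = (b * logS).sum(axis=0)

    denom = n * sxx - sx * sx
    valid = (n >= 2) & (denom > 0)
    safe = np.where(valid, denom, 1.0)
    slope = np.where(valid, (n * sxy - sx * sy) / safe, 0.0)
    nn = np.where(n > 0, n, 1)
    intercept = np.where(valid, (sy - slope * sx) / nn, 0.0)

    adc = np.where(valid, -slope, 0.0)
    s0 = np.where(valid, np.exp(intercept), 0.0)
    return ADCMap(grid=grid, adc=adc, s0=s0, valid_mask=valid)


@dataclass
class TubeMAE:
    """Per-tube and aggregate absolute ADC errors (mm²·s⁻¹).

    ``mean`` averages the per-tube MAEs (tubes weighted equally); ``pooled``
    averages over all tube voxels at once.
    """

    per_tube: np.ndarray
    mean: float
    pooled: float


def tube_adc_mae(adc_map: ADCMap, truth: Volume3D,
                 masks: list[np.ndarray]) -> TubeMAE:
    """Mean absolute ADC error inside each tube mask, against ground truth.

    Only voxels valid in the fitted map contribute; an empty mask (or one with
    no valid voxels) is an error.
    """
    if not masks:
        raise ValueError("need at least one tube mask")
    err = np.abs(adc_map.adc - truth.data)
    per_tube = []
    pooled_num = 0.0
    pooled_n = 0
    for m in masks:
        mm = np.asarray(m, dtype=bool) & adc_map.valid_mask
        if not np.any(mm):
            raise ValueError("tube mask has no valid voxels")
        per_tube.append(float(err[mm].mean()))
        pooled_num += float(err[mm].sum())
        pooled_n += int(mm.sum())
    per_tube = np.array(per_tube)
    return TubeMAE(per_tube=per_tube, mean=float(per_tube.mean()),
                   pooled=pooled_num / pooled_n)
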