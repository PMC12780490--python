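"""Image-quality metrics and parameter-sweep runners.

Full-reference metrics (for synthetic data with a clean reference):

* PSNR = 10·log10(data_range² / MSE), in dB; identical volumes give +inf.
* SSIM with the standard constants k1 = 0.01, k2 = 0.03 and uniform 7-wide
  local windows, computed slice-wise in 2-D (the common MRI convention) and
  averaged across slices; a full 3-D windowed variant is available.  Local
  variances/covariances use the n−1 normalisation and the border half-window
  is cropped before averaging, so values match the conventional reference
  implementation.

Reference-free assessment uses ROI statistics: effective denoising reduces the
standard deviation in a uniform region while preserving its mean.

``run_sweep`` reruns the full pipeline on a synthetic fixture across values of
one parameter (omega_max, patch_size, or a rigid y-shift injected into the
priors) and aggregates the chosen metric over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter

from .encoding import EncodingConfig
from .descriptor import PriorStack
from .phantom import (RicianNoiseSpec, add_rician_noise, apply_shift,
                      diffusion_series, make_brainlike_maps)
from .train import TrainingConfig, fit
from .volume import GridSpec, Volume3D

__all__ = ["ROIStats", "SweepConfig", "SweepResult", "psnr", "ssim",
           "roi_stats", "run_sweep", "wilcoxon_signed_rank"]


def _data(vol) -> np.ndarray:
    return vol.data if isinstance(vol, Volume3D) else np.asarray(vol, dtype=float)


def _check_pair(reference, test):
    a, b = _data(reference), _data(test)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(reference, test, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical inputs.

    ``data_range`` defaults to the maximum of the reference.
    """
    ref, tst = _check_pair(reference, test)
    if data_range is None:
        data_range = float(ref.max())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def _ssim_map(x: np.ndarray, y: np.ndarray, data_range: float, win: int) -> float:
    """Mean local SSIM over the valid (border-cropped) region of one array."""
    x = x.astype(np.float64)
    y = y.astype(np.float64)
    ndim = x.ndim
    npix = win**ndim
    cov_norm = npix / (npix - 1)
    ux = uniform_filter(x, win)
    uy = uniform_filter(y, win)
    uxx = uniform_filter(x * x, win)
    uyy = uniform_filter(y * y, win)
    uxy = uniform_filter(x * y, win)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    sl = tuple(slice(pad, dim - pad) for dim in s.shape)
    return float(s[sl].mean())


def ssim(reference, test, data_range: float | None = None, win: int = 7,
         mode: Literal["2d", "3d"] = "2d") -> float:
    """Structural similarity index in [−1, 1].

    ``2d`` (default) computes SSIM on each axial (z) slice with a win×win
    uniform window and averages across slices; ``3d`` uses a single cubic
    window.  In-plane dimensions must be at least ``win`` wide.
    """
    ref, tst = _check_pair(reference, test)
    if data_range is None:
        data_range = float(ref.max() - ref.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if mode == "2d":
        if ref.shape[0] < win or ref.shape[1] < win:
            raise ValueError(f"in-plane dimensions must be >= window size {win}")
        vals = [_ssim_map(ref[:, :, k], tst[:, :, k], data_range, win)
                for k in range(ref.shape[2])]
        return float(np.mean(vals))
    if mode == "3d":
        if min(ref.shape) < win:
            raise ValueError(f"all dimensions must be >= window size {win}")
        return _ssim_map(ref, tst, data_range, win)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class ROIStats:
    """Mean, sample standard deviation (n−1) and voxel count of an ROI."""

    mean: float
    std: float
    n: int


def roi_stats(vol, mask) -> ROIStats:
    """Statistics of the voxels selected by a boolean mask."""
    data = _data(vol)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError("mask shape must match volume shape")
    vals = data[mask]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ROIStats(mean=float(vals.mean()), std=std, n=int(vals.size))


def wilcoxon_signed_rank(x, y):
    """Paired Wilcoxon signed-rank test (two-sided); thin statistical utility."""
    from scipy.stats import wilcoxon

    res = wilcoxon(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class SweepConfig:
    """Fixture and pipeline settings shared across a sweep.

    The fixture is a brain-like synthetic volume with b-value companions; the
    lowest b-value volume is denoised with the others as priors at the given
    SNR.  ``metric`` selects what is aggregated (PSNR in dB or SSIM).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    b_values: tuple[float, ...] = (0.0, 500.0, 1000.0)
    snr: float = 3.0
    target_b: float = 0.0
    metric: Literal["psnr", "ssim"] = "psnr"
    enc: EncodingConfig = field(default_factory=lambda: EncodingConfig(omega_max=20.0, count=8))
    train: TrainingConfig = field(default_factory=lambda: TrainingConfig(hidden_dim=64, depth=4))


@dataclass
class SweepResult:
    """Aggregated metric per parameter value, ordered by value."""

    parameter: str
    rows: list[tuple[float, float, float]]  # (value, mean metric, spread)
    seeds: list[int]
    metric: str


def _sweep_case(cfg: SweepConfig, seed: int, omega_max=None, patch_size=None,
                shift_pixels=None) -> float:
    grid = GridSpec(cfg.grid_shape)
    s0, adcmap = make_brainlike_maps(grid, seed=seed)
    clean = diffusion_series(s0.data, adcmap.data, cfg.b_values, grid)
    clean_by_b = dict(clean)
    target_clean = clean_by_b[cfg.target_b]
    nspec = RicianNoiseSpec.from_volume(target_clean, cfg.snr, seed=seed)
    noisy = {b: add_rician_noise(v, RicianNoiseSpec(cfg.snr, seed + 17 * i + 1,
                                                    nspec.reference_level))
             for i, (b, v) in enumerate(clean)}
    if omega_max is None:
        enc = cfg.enc
    else:
        count = 1 if float(omega_max) == 1.0 else cfg.enc.resolved_count()
        enc = replace(cfg.enc, omega_max=float(omega_max), count=count)
    tcfg = replace(cfg.train, seed=seed)
    if patch_size is not None:
        tcfg = replace(tcfg, patch_size=int(patch_size))
    dwi_priors = []
    for b, v in noisy.items():
        if b == cfg.target_b:
            continue
        if shift_pixels:
            v = apply_shift(v, "y", int(shift_pixels))
        dwi_priors.append((b, v))
    priors = PriorStack(dwi=dwi_priors, target_b=cfg.target_b)
    _, res = fit(noisy[cfg.target_b], priors, enc, tcfg)
    rng = float(target_clean.data.max())
    if cfg.metric == "psnr":
        return psnr(target_clean, res.denoised, data_range=rng)
    return ssim(target_clean, res.denoised, data_range=rng)


def run_sweep(parameter: Literal["omega_max", "patch_size", "shift_pixels"],
              values, base: SweepConfig | None = None,
              seeds=(0,)) -> SweepResult:
    """Train/evaluate the pipeline per (value, seed) and aggregate the metric.

    ``shift_pixels`` injects a rigid y-translation into every prior volume
    before training, emulating a registration error between modalities.
    """
    if parameter not in ("omega_max", "patch_size", "shift_pixels"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    values = list(values)
    seeds = list(seeds)
    if not values or not seeds:
        raise ValueError("need at least one value and one seed")
    base = base or SweepConfig()
    rows = []
    for v in sorted(values):
        metrics = [
            _sweep_case(base, s, **{parameter: v})
            for s in seeds
        ]
        spread = float(np.std(metrics, ddof=1)) if len(metrics) > 1 else 0.0
        rows.append((float(v), float(np.mean(metrics)), spread))
    return SweepResult(parameter=parameter, rows=rows, seeds=seeds, metric=base.metric)
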