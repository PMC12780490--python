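"""Synthetic ground truth: diffusion phantoms, Rician noise, shifts.

The tube phantom mimics a quantitative diffusion phantom: z-aligned cylindrical
"tubes" with known ADC and proton-density (S0) values inside a uniform
background.  Multi-b-value trace-weighted volumes follow the mono-exponential
model S(b) = S0·exp(−b·ADC) voxel-wise, so the ADC ground truth is known
exactly and quantitation can be validated end to end.

Magnitude-MRI noise is Rician: the clean signal A is perturbed by two
independent zero-mean Gaussians of standard deviation σ in the complex plane,
M = √((A + n₁)² + n₂²).  SNR is defined as the mean clean foreground intensity
divided by σ, the standard magnitude-MRI convention, so requesting SNR s fixes
σ = reference_level / s.  The noise-floor correction defaults to the classic
mean-based formula Â = √(max(M² − σ², 0)), which keeps the corrected mean
close to A down to moderate SNR; the second-moment variant
√(max(M² − 2σ², 0)) (unbiased in E[M²]) is selectable.

A brain-like volume (piecewise-smooth blobs with sharp interfaces, from seeded
smoothed-noise thresholding) is provided as a richer fixture for encoding and
patch-size studies; it makes no claim to real anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import GridSpec, Volume3D

__all__ = [
    "Tube", "PhantomSpec", "RicianNoiseSpec",
    "make_diffusion_phantom", "diffusion_series", "tube_masks", "background_mask",
    "make_brainlike_maps", "make_anatomical_companion",
    "add_rician_noise", "rician_bias_correct", "apply_shift",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class Tube:
    """A z-aligned cylinder: centre (voxel units), in-plane radius (voxels),
    ADC (mm²·s⁻¹) and S0 (signal units).  ``half_length`` bounds the z extent;
    None spans the whole volume."""

    center: tuple[float, float, float]
    radius: float
    adc: float
    s0: float
    half_length: float | None = None


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and diffusion description of the synthetic tube phantom."""

    grid: GridSpec
    tubes: tuple[Tube, ...]
    background_s0: float = 0.0
    background_adc: float = 0.0
    b_values: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        object.__setattr__(self, "tubes", tuple(self.tubes))
        bvals = tuple(float(b) for b in self.b_values)
        object.__setattr__(self, "b_values", bvals)
        if any(t.radius <= 0 for t in self.tubes):
            raise ValueError("tube radii must be positive")
        if any(t.adc < 0 for t in self.tubes) or self.background_adc < 0:
            raise ValueError("ADC values must be nonnegative")
        if len(set(bvals)) != len(bvals) or any(b < 0 for b in bvals):
            raise ValueError("b-values must be unique and nonnegative")
        if 0.0 not in bvals:
            raise ValueError("b-values must include 0")
        self._check_overlap()

    def _check_overlap(self):
        nz = self.grid.shape[2]
        for i in range(len(self.tubes)):
            for j in range(i + 1, len(self.tubes)):
                a, b = self.tubes[i], self.tubes[j]
                za = _z_range(a, nz)
                zb = _z_range(b, nz)
                if za[0] > zb[1] or zb[0] > za[1]:
                    continue
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError(f"tubes {i} and {j} overlap")


def _z_range(t: Tube, nz: int) -> tuple[float, float]:
    if t.half_length is None:
        return (0.0, nz - 1.0)
    return (t.center[2] - t.half_length, t.center[2] + t.half_length)


def _tube_mask(t: Tube, grid: GridSpec) -> np.ndarray:
    nx, ny, nz = grid.shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    inplane = (ix - t.center[0]) ** 2 + (iy - t.center[1]) ** 2 <= t.radius**2
    z0, z1 = _z_range(t, nz)
    return inplane & (iz >= z0) & (iz <= z1)


def tube_masks(spec: PhantomSpec) -> list[np.ndarray]:
    """Boolean mask per tube, in spec order."""
    return [_tube_mask(t, spec.grid) for t in spec.tubes]


def background_mask(spec: PhantomSpec) -> np.ndarray:
    """Voxels belonging to no tube."""
    m = np.ones(spec.grid.shape, dtype=bool)
    for tm in tube_masks(spec):
        m &= ~tm
    return m


def diffusion_series(s0_map: np.ndarray, adc_map: np.ndarray, b_values,
                     grid: GridSpec) -> list[tuple[float, Volume3D]]:
    """Noise-free S(b) = S0·exp(−b·ADC) volumes for each b-value."""
    out = []
    for b in b_values:
        data = s0_map * np.exp(-float(b) * adc_map)
        out.append((float(b), Volume3D(grid, data, role="clean_reference")))
    return out


def make_diffusion_phantom(spec: PhantomSpec):
    """Clean multi-b volumes plus the ADC ground-truth volume.

    Returns ``(volumes, adc_truth)`` where ``volumes`` is a list of
    (b_value, clean Volume3D) in spec b order; the b = 0 volume equals the S0
    map exactly.
    """
    s0 = np.full(spec.grid.shape, float(spec.background_s0))
    adc = np.full(spec.grid.shape, float(spec.background_adc))
    for t, mask in zip(spec.tubes, tube_masks(spec)):
        s0[mask] = t.s0
        adc[mask] = t.adc
    volumes = diffusion_series(s0, adc, spec.b_values, spec.grid)
    adc_truth = Volume3D(spec.grid, adc, role="clean_reference")
    return volumes, adc_truth


def make_brainlike_maps(grid: GridSpec, seed: int = 0, n_tissues: int = 3,
                        smooth_voxels: float = 3.0):
    """Piecewise-smooth S0 and ADC maps with sharp interfaces.

    Seeded Gaussian-smoothed noise is thresholded at quantiles into
    ``n_tissues`` classes plus background; each class gets a distinct S0 and
    ADC.  Purely a synthetic fixture with brain-like frequency content.
    """
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal(grid.shape), smooth_voxels)
    qs = np.quantile(f, np.linspace(0.15, 0.9, n_tissues))
    labels = np.zeros(grid.shape, dtype=int)
    for i, q in enumerate(qs):
        labels[f >= q] = i + 1
    s0_levels = np.linspace(200.0, 1000.0, n_tissues + 1)
    s0_levels[0] = 0.0  # background
    adc_levels = np.linspace(0.4e-3, 2.5e-3, n_tissues + 1)
    adc_levels[0] = 0.0
    s0 = s0_levels[labels]
    adc = adc_levels[labels]
    return Volume3D(grid, s0, role="clean_reference"), Volume3D(grid, adc, role="clean_reference")


def make_anatomical_companion(structure: Volume3D, contrast_map) -> Volume3D:
    """A co-registered anatomical contrast: same geometry, remapped intensity.

    ``contrast_map`` is applied voxel-wise (vectorised over the array); the
    output must be finite.
    """
    data = np.asarray(contrast_map(structure.data), dtype=float)
    if data.shape != structure.data.shape:
        raise ValueError("contrast_map must preserve shape")
    if not np.all(np.isfinite(data)):
        raise ValueError("contrast_map produced non-finite values")
    return Volume3D(structure.grid, data, role="prior_anatomical")


@dataclass(frozen=True)
class RicianNoiseSpec:
    """Noise level for magnitude MRI: σ = reference_level / snr."""

    snr: float
    seed: int
    reference_level: float

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.reference_level <= 0:
            raise ValueError("reference_level must be positive")

    @property
    def sigma(self) -> float:
        return self.reference_level / self.snr

    @classmethod
    def from_volume(cls, clean: Volume3D, snr: float, seed: int,
                    foreground: np.ndarray | None = None) -> "RicianNoiseSpec":
        """Derive σ from a clean volume: reference = mean foreground intensity
        (foreground defaults to strictly positive voxels)."""
        if foreground is None:
            foreground = clean.data > 0
        if not np.any(foreground):
            raise ValueError("empty foreground; cannot derive reference level")
        return cls(snr=float(snr), seed=int(seed),
                   reference_level=float(clean.data[foreground].mean()))


def add_rician_noise(clean: Volume3D, spec: RicianNoiseSpec) -> Volume3D:
    """Rician magnitude noise: M = √((A + n₁)² + n₂²), n ~ N(0, σ²), seeded."""
    if np.any(clean.data < 0):
        raise ValueError("clean volume must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    sigma = spec.sigma
    n1 = rng.normal(0.0, sigma, size=clean.data.shape)
    n2 = rng.normal(0.0, sigma, size=clean.data.shape)
    noisy = np.hypot(clean.data + n1, n2)
    return Volume3D(clean.grid, noisy, role="target_noisy", meta=clean.meta)


def rician_bias_correct(vol, sigma: float, method: str = "mean"):
    """Remove the Rician noise floor from magnitudes.

    ``mean`` (default): Â = √(max(M² − σ², 0)), the classic correction whose
    expectation tracks A closely; ``second_moment``: Â = √(max(M² − 2σ², 0)),
    unbiased in E[M²] but biased low in the mean at moderate SNR.  Accepts a
    Volume3D or a plain array and returns the same kind.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if method == "second_moment":
        k = 2.0
    elif method == "mean":
        k = 1.0
    else:
        raise ValueError(f"unknown correction method {method!r}")
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol, dtype=float)
    corrected = np.sqrt(np.maximum(data**2 - k * sigma**2, 0.0))
    if isinstance(vol, Volume3D):
        return vol.with_data(corrected)
    return corrected


def apply_shift(vol: Volume3D, axis: str, pixels: int) -> Volume3D:
    """Integer-voxel translation along one axis, vacated edges replicated.

    Content moves by +pixels along the axis: out[i] = in[clip(i − pixels)].
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    ax = _AXES[axis]
    n = vol.grid.shape[ax]
    pixels = int(pixels)
    if abs(pixels) >= n:
        raise ValueError(f"shift {pixels} exceeds extent {n} along {axis}")
    idx = np.clip(np.arange(n) - pixels, 0, n - 1)
    return vol.with_data(np.take(vol.data, idx, axis=ax))
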