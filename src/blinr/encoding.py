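"""Band-limited positional encoding.

A coordinate MLP needs sinusoidal features to express fine spatial detail, but a
plain Fourier encoding lets the network fit high-frequency noise just as easily
as high-frequency anatomy.  The band-limited (BL) encoding keeps the same
sinusoids sin(ω_k·p_i), cos(ω_k·p_i) and multiplies each by the normalized sinc
window sinc(ω_k·σ) with σ = 1/ω_max.  Because sinc is exactly zero at nonzero
integers, the component at the cutoff frequency ω_max is nulled exactly and the
attenuation decreases monotonically towards it — the encoding behaves like the
impulse response of an ideal low-pass filter applied to the feature spectrum.

Frequencies ω_1..ω_K are equally spaced on [1, ω_max].  The encoding vector is
laid out axis-major: for each axis (x, y, z), for each frequency in ascending
order, the (sin, cos) pair — 6·K entries in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FrequencySet",
    "EncodingConfig",
    "normalized_sinc",
    "build_frequency_set",
    "encode_bandlimited",
    "encode_fourier",
    "encode_identity",
    "encode",
    "encoding_length",
]


def normalized_sinc(x):
    """Normalized sinc, sin(πx)/(πx), with exact zeros at nonzero integers.

    ``np.sinc`` evaluates the same function but returns ~1e-16 at integer
    arguments; the ideal low-pass cutoff requires an exact zero there, so
    integer inputs are special-cased.

    Parameters
    ----------
    x : float or array-like
        Finite real argument(s).

    Returns
    -------
    float or ndarray
        1.0 at x = 0, exactly 0.0 at nonzero integers, sin(πx)/(πx) elsewhere.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("normalized_sinc requires finite input")
    out = np.sinc(arr)
    integral = arr == np.round(arr)
    out = np.where(integral, np.where(arr == 0.0, 1.0, 0.0), out)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class FrequencySet:
    """The encoding frequencies {ω_k}, their cutoff ω_max and window scale σ.

    ``sigma`` is always 1/ω_max so that the sinc window hits its first zero at
    the maximum frequency.
    """

    omega_max: float
    count: int
    omegas: np.ndarray
    sigma: float

    def attenuations(self) -> np.ndarray:
        """sinc(ω_k·σ) for every frequency.

        Evaluated as sinc(ω_k/ω_max), which is the same quantity but keeps the
        cutoff argument exactly 1 in floating point, so the attenuation at
        ω_max is exactly 0.
        """
        return normalized_sinc(self.omegas / self.omega_max)


def build_frequency_set(omega_max: float, count: int) -> FrequencySet:
    """Equally spaced frequencies on [1, ω_max] with σ = 1/ω_max.

    ω_k = 1 + (k−1)·(ω_max − 1)/(K − 1) for k = 1..K; a single-frequency set
    degenerates to [ω_max].

    Raises
    ------
    ValueError
        If omega_max < 1, count < 1, or count ≥ 2 with omega_max = 1
        (degenerate spacing).
    """
    omega_max = float(omega_max)
    count = int(count)
    if not np.isfinite(omega_max) or omega_max < 1.0:
        raise ValueError(f"omega_max must be >= 1, got {omega_max}")
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    if count >= 2 and omega_max == 1.0:
        raise ValueError("count >= 2 requires omega_max > 1 (degenerate spacing)")
    if count == 1:
        omegas = np.array([omega_max], dtype=float)
    else:
        omegas = 1.0 + np.arange(count, dtype=float) * (omega_max - 1.0) / (count - 1)
        omegas[-1] = omega_max
    omegas.setflags(write=False)
    return FrequencySet(omega_max=omega_max, count=count, omegas=omegas, sigma=1.0 / omega_max)


def _check_coords(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError(f"coordinates must have 3 components, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(p) > 1.0):
        raise ValueError("normalized coordinates must lie in [-1, 1]")
    return p


def _encode_sinusoids(p, freqs: FrequencySet, attenuation: np.ndarray) -> np.ndarray:
    """Axis-major (sin, cos) features, each scaled by the given per-frequency factor."""
    p = _check_coords(p)
    ang = p[..., :, None] * freqs.omegas  # (..., 3, K)
    feats = np.stack(
        [np.sin(ang) * attenuation, np.cos(ang) * attenuation], axis=-1
    )  # (..., 3, K, 2)
    return feats.reshape(p.shape[:-1] + (6 * freqs.count,))


def encode_bandlimited(p, freqs: FrequencySet) -> np.ndarray:
    """Band-limited encoding: sin/cos features attenuated by sinc(ω_k·σ).

    Accepts a single coordinate triple or an (..., 3) array; returns an
    (..., 6·K) array.  All entries at ω_max are exactly zero.
    """
    return _encode_sinusoids(p, freqs, freqs.attenuations())


def encode_fourier(p, freqs: FrequencySet) -> np.ndarray:
    """Plain Fourier encoding: the same sinusoids without the sinc window."""
    return _encode_sinusoids(p, freqs, np.ones(freqs.count))


def encode_identity(p) -> np.ndarray:
    """Raw normalized coordinates as a length-3 feature vector."""
    return _check_coords(p).copy()


@dataclass(frozen=True)
class EncodingConfig:
    """Which positional encoding to use and its frequency grid.

    ``count=None`` defaults to round(omega_max), i.e. integer frequencies
    1..ω_max at unit spacing.
    """

    type: Literal["bandlimited", "fourier", "identity"] = "bandlimited"
    omega_max: float = 20.0
    count: int | None = None

    def resolved_count(self) -> int:
        if self.count is not None:
            return int(self.count)
        return max(1, int(round(self.omega_max)))

    def frequency_set(self) -> FrequencySet:
        return build_frequency_set(self.omega_max, self.resolved_count())


def encoding_length(cfg: EncodingConfig) -> int:
    """Length of the encoding vector produced under ``cfg``."""
    if cfg.type == "identity":
        return 3
    return 6 * cfg.resolved_count()


def encode(p, cfg: EncodingConfig) -> np.ndarray:
    """Dispatch to the configured encoding."""
    if cfg.type == "identity":
        return encode_identity(p)
    freqs = cfg.frequency_set()
    if cfg.type == "bandlimited":
        return encode_bandlimited(p, freqs)
    if cfg.type == "fourier":
        return encode_fourier(p, freqs)
    raise ValueError(f"unknown encoding type: {cfg.type!r}")
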