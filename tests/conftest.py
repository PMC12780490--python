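import numpy as np
import pytest

from blinr import (EncodingConfig, GridSpec, PhantomSpec, PriorStack,
                   RicianNoiseSpec, TrainingConfig, Tube, add_rician_noise,
                   diffusion_series, make_brainlike_maps, make_diffusion_phantom)


def four_tube_spec(size=24, background_s0=100.0, background_adc=0.2e-3,
                   b_values=(0.0, 500.0, 1000.0)):
    """Standard four-tube quantitative phantom used across tests."""
    c, r, off = size / 2.0, size / 8.0, size / 4.0
    tubes = (
        Tube((c - off, c - off, c), r, 0.5e-3, 1000.0),
        Tube((c + off, c - off, c), r, 1.0e-3, 1000.0),
        Tube((c - off, c + off, c), r, 1.5e-3, 1000.0),
        Tube((c + off, c + off, c), r, 2.0e-3, 1000.0),
    )
    return PhantomSpec(GridSpec((size, size, size)), tubes,
                       background_s0=background_s0, background_adc=background_adc,
                       b_values=b_values)


def noisy_study(clean, target_b, snr, seed, prior_snr=10.0):
    """Emulate the simulation protocol: the target volume is degraded to the
    requested SNR while companion b-value volumes keep native acquisition
    quality (SNR 10 relative to the same reference level).

    Returns (noisy_target, prior_stack, sigma) with sigma the target noise std.
    """
    clean_by_b = dict(clean)
    ref = RicianNoiseSpec.from_volume(clean_by_b[target_b], snr, seed)
    noisy_target = add_rician_noise(
        clean_by_b[target_b], RicianNoiseSpec(snr, seed * 1000 + 1, ref.reference_level))
    dwi = [
        (b, add_rician_noise(v, RicianNoiseSpec(prior_snr, seed * 1000 + 17 * i + 2,
                                                ref.reference_level)))
        for i, (b, v) in enumerate(clean) if b != target_b
    ]
    return noisy_target, PriorStack(dwi=dwi, target_b=target_b), ref.sigma


def small_enc():
    return EncodingConfig(omega_max=20.0, count=8)


def small_train(**kw):
    defaults = dict(hidden_dim=64, depth=4, seed=0, epochs=60)
    defaults.update(kw)
    return TrainingConfig(**defaults)


@pytest.fixture(scope="session")
def tube_phantom_24():
    spec = four_tube_spec(24)
    volumes, adc_truth = make_diffusion_phantom(spec)
    return spec, volumes, adc_truth


@pytest.fixture(scope="session")
def brainlike_24():
    grid = GridSpec((24, 24, 24))
    s0, adc = make_brainlike_maps(grid, seed=0)
    volumes = diffusion_series(s0.data, adc.data, (0.0, 500.0, 1000.0), grid)
    return grid, volumes
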