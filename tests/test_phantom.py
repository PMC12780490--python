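"""Synthetic phantoms, Rician noise statistics, bias correction, shifts."""

import numpy as np
import pytest

from blinr import (GridSpec, PhantomSpec, RicianNoiseSpec, Tube, Volume3D,
                   add_rician_noise, apply_shift, fit_adc,
                   make_anatomical_companion, make_brainlike_maps,
                   make_diffusion_phantom, rician_bias_correct, tube_masks)

from conftest import four_tube_spec


class TestDiffusionPhantom:
    def test_b0_equals_s0_map(self):
        spec = four_tube_spec(16)
        volumes, _ = make_diffusion_phantom(spec)
        b0 = dict(volumes)[0.0]
        masks = tube_masks(spec)
        for t, m in zip(spec.tubes, masks):
            assert np.all(b0.data[m] == t.s0)
        bg = ~np.any(masks, axis=0)
        assert np.all(b0.data[bg] == spec.background_s0)

    def test_mono_exponential_closed_form(self):
        g = GridSpec((8, 8, 8))
        spec = PhantomSpec(g, (Tube((4, 4, 4), 2.0, 1.0e-3, 1000.0),),
                           background_s0=0.0, b_values=(0.0, 1000.0))
        volumes, _ = make_diffusion_phantom(spec)
        m = tube_masks(spec)[0]
        s = dict(volumes)[1000.0].data[m]
        assert np.allclose(s, 1000.0 * np.exp(-1.0), rtol=1e-12)

    def test_signal_monotone_in_b(self):
        spec = four_tube_spec(12, b_values=(0.0, 200.0, 500.0, 1000.0))
        volumes, _ = make_diffusion_phantom(spec)
        stack = np.stack([v.data for _, v in volumes])
        assert np.all(np.diff(stack, axis=0) <= 0)

    def test_adc_roundtrip_exact(self):
        spec = four_tube_spec(16, b_values=(0.0, 250.0, 500.0, 1000.0))
        volumes, adc_truth = make_diffusion_phantom(spec)
        fitted = fit_adc(volumes)
        m = adc_truth.data > 0
        rel = np.abs(fitted.adc[m] - adc_truth.data[m]) / adc_truth.data[m]
        assert np.max(rel) <= 1e-12

    def test_overlapping_tubes_rejected(self):
        g = GridSpec((16, 16, 16))
        with pytest.raises(ValueError):
            PhantomSpec(g, (Tube((8, 8, 8), 3.0, 1e-3, 1000.0),
                            Tube((9, 8, 8), 3.0, 1e-3, 1000.0)),
                        b_values=(0.0,))

    def test_b_values_validated(self):
        g = GridSpec((8, 8, 8))
        with pytest.raises(ValueError):
            PhantomSpec(g, (), b_values=(500.0,))  # missing b=0


class TestAnatomicalCompanion:
    def test_identity_remap(self):
        spec = four_tube_spec(12)
        volumes, _ = make_diffusion_phantom(spec)
        s0 = volumes[0][1]
        out = make_anatomical_companion(s0, lambda x: x)
        assert np.array_equal(out.data, s0.data)

    def test_affine_remap(self):
        spec = four_tube_spec(12)
        volumes, _ = make_diffusion_phantom(spec)
        s0 = volumes[0][1]
        out = make_anatomical_companion(s0, lambda x: 2 * x + 5)
        assert np.allclose(out.data, 2 * s0.data + 5)

    def test_contrast_inversion_preserves_edges(self):
        spec = four_tube_spec(12)
        volumes, _ = make_diffusion_phantom(spec)
        s0 = volumes[0][1]
        inv = make_anatomical_companion(s0, lambda x: s0.data.max() - x)

        def edge_mask(d):
            return (np.abs(np.diff(d, axis=0, prepend=d[:1])) > 0) \
                 | (np.abs(np.diff(d, axis=1, prepend=d[:, :1])) > 0) \
                 | (np.abs(np.diff(d, axis=2, prepend=d[:, :, :1])) > 0)

        assert np.array_equal(edge_mask(s0.data), edge_mask(inv.data))

    def test_nonfinite_remap_rejected(self):
        spec = four_tube_spec(8)
        volumes, _ = make_diffusion_phantom(spec)
        with pytest.raises(ValueError):
            make_anatomical_companion(volumes[0][1], lambda x: np.log(x - x.max()))


class TestRicianNoise:
    def test_seed_reproducibility(self):
        spec = four_tube_spec(10)
        volumes, _ = make_diffusion_phantom(spec)
        ns = RicianNoiseSpec.from_volume(volumes[0][1], 3.0, seed=5)
        a = add_rician_noise(volumes[0][1], ns)
        b = add_rician_noise(volumes[0][1], ns)
        assert np.array_equal(a.data, b.data)

    def test_snr_calibration(self):
        spec = four_tube_spec(10)
        volumes, _ = make_diffusion_phantom(spec)
        clean = volumes[0][1]
        ns = RicianNoiseSpec.from_volume(clean, 3.0, seed=5)
        fg = clean.data > 0
        assert clean.data[fg].mean() / ns.sigma == pytest.approx(3.0, rel=1e-12)

    def test_high_snr_limit(self):
        spec = four_tube_spec(10)
        volumes, _ = make_diffusion_phantom(spec)
        ns = RicianNoiseSpec.from_volume(volumes[0][1], 1e7, seed=1)
        noisy = add_rician_noise(volumes[0][1], ns)
        assert np.max(np.abs(noisy.data - volumes[0][1].data)) < 1e-3

    def test_rayleigh_mean_at_zero_signal(self):
        n = 100_000
        sigma = 2.0
        g = GridSpec((n, 1, 1))
        clean = Volume3D(g, np.zeros(g.shape))
        noisy = add_rician_noise(clean, RicianNoiseSpec(1.0, seed=3, reference_level=sigma))
        samples = noisy.data.ravel()
        expected = sigma * np.sqrt(np.pi / 2)
        se = np.sqrt((2 - np.pi / 2) * sigma**2 / n)
        assert abs(samples.mean() - expected) < 3 * se

    def test_rayleigh_variance_at_zero_signal(self):
        n = 100_000
        sigma = 1.5
        g = GridSpec((n, 1, 1))
        noisy = add_rician_noise(Volume3D(g, np.zeros(g.shape)),
                                 RicianNoiseSpec(1.0, seed=9, reference_level=sigma))
        var = noisy.data.var()
        expected = (2 - np.pi / 2) * sigma**2
        # MC standard error of the variance estimate (4th-moment based, approx)
        se = expected * np.sqrt(2.0 / n) * 2
        assert abs(var - expected) < 3 * se

    def test_high_signal_moment(self):
        n = 100_000
        sigma, A = 1.0, 10.0
        g = GridSpec((n, 1, 1))
        noisy = add_rician_noise(Volume3D(g, np.full(g.shape, A)),
                                 RicianNoiseSpec(1.0, seed=4, reference_level=sigma))
        expected = np.sqrt(A**2 + sigma**2)
        se = sigma / np.sqrt(n)
        assert abs(noisy.data.mean() - expected) < 3 * se

    def test_invalid_snr(self):
        with pytest.raises(ValueError):
            RicianNoiseSpec(0.0, seed=0, reference_level=1.0)


class TestBiasCorrection:
    def test_sigma_zero_identity(self):
        rng = np.random.default_rng(0)
        x = np.abs(rng.normal(size=(4, 4, 4))) + 1
        vol = Volume3D(GridSpec((4, 4, 4)), x)
        assert np.array_equal(rician_bias_correct(vol, 0.0).data, x)

    def test_clamped_below_noise_floor(self):
        vol = Volume3D(GridSpec((1, 1, 1)), np.array([[[1.0]]]))
        out = rician_bias_correct(vol, sigma=1.0)  # M^2 < 2 sigma^2
        assert out.data[0, 0, 0] == 0.0

    def test_correction_reduces_bias_at_moderate_snr(self):
        n = 100_000
        sigma, A = 1.0, 3.0
        g = GridSpec((n, 1, 1))
        noisy = add_rician_noise(Volume3D(g, np.full(g.shape, A)),
                                 RicianNoiseSpec(1.0, seed=6, reference_level=sigma))
        corrected = rician_bias_correct(noisy.data, sigma)
        assert abs(corrected.mean() - A) < abs(noisy.data.mean() - A)

    def test_negative_sigma_rejected(self):
        vol = Volume3D(GridSpec((2, 2, 2)), np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            rician_bias_correct(vol, -1.0)


class TestApplyShift:
    def _ramp(self):
        g = GridSpec((6, 7, 5))
        i, j, k = np.meshgrid(np.arange(6), np.arange(7), np.arange(5), indexing="ij")
        return Volume3D(g, i + 10.0 * j + 100.0 * k)

    def test_zero_shift_identity(self):
        vol = self._ramp()
        assert np.array_equal(apply_shift(vol, "y", 0).data, vol.data)

    def test_matches_reindexing_oracle(self):
        vol = self._ramp()
        out = apply_shift(vol, "y", 2)
        expected = np.empty_like(vol.data)
        for j in range(7):
            expected[:, j, :] = vol.data[:, max(j - 2, 0), :]
        assert np.array_equal(out.data, expected)

    def test_roundtrip_restores_interior(self):
        vol = self._ramp()
        back = apply_shift(apply_shift(vol, "y", 2), "y", -2)
        assert np.array_equal(back.data[:, 2:-2, :], vol.data[:, 2:-2, :])

    def test_shift_beyond_extent_rejected(self):
        with pytest.raises(ValueError):
            apply_shift(self._ramp(), "y", 7)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError):
            apply_shift(self._ramp(), "w", 1)


def test_brainlike_maps_are_piecewise_with_sharp_interfaces():
    g = GridSpec((16, 16, 16))
    s0, adc = make_brainlike_maps(g, seed=1)
    # small set of discrete tissue levels, not a continuum
    assert 2 <= np.unique(s0.data).size <= 5
    assert np.unique(adc.data).size == np.unique(s0.data).size
    # deterministic given the seed
    s0b, _ = make_brainlike_maps(g, seed=1)
    assert np.array_equal(s0.data, s0b.data)
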