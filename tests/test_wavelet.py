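import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync import (MorletParams, cwt_morlet, fisher_z, make_scale_grid,
                      smooth_field, wtc)
from dyadsync.wavelet import fourier_factor


class TestScaleGrid:
    def test_default_grid_endpoints_and_ratio(self):
        """106 geometric scales from 0.3 to 128 s with a constant ratio."""
        grid = make_scale_grid(0.3, 128.0, 106)
        assert grid.scales[0] == pytest.approx(0.3, abs=1e-12)
        assert grid.scales[-1] == pytest.approx(128.0, abs=1e-12)
        ratios = grid.scales[1:] / grid.scales[:-1]
        np.testing.assert_allclose(ratios, ratios[0], atol=1e-12)

    def test_powers_of_two(self):
        grid = make_scale_grid(1.0, 4.0, 3)
        np.testing.assert_allclose(grid.scales, [1.0, 2.0, 4.0], atol=1e-12)

    def test_fourier_factor_closed_form(self):
        # 4*pi / (6 + sqrt(38)), the Morlet period per unit scale
        assert fourier_factor(6.0) == pytest.approx(1.0330436477492537,
                                                    abs=1e-12)
        grid = make_scale_grid(1.0, 4.0, 3)
        np.testing.assert_allclose(grid.periods / grid.scales,
                                   1.0330436477492537, atol=1e-12)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            make_scale_grid(-1.0, 4.0, 3)
        with pytest.raises(ValueError):
            make_scale_grid(4.0, 4.0, 3)


class TestCWT:
    def test_linearity(self, rng, small_grid):
        x = rng.standard_normal(600)
        w1 = cwt_morlet(x, 10.0, small_grid)
        w2 = cwt_morlet(2.0 * x, 10.0, small_grid)
        np.testing.assert_allclose(w2, 2.0 * w1, atol=1e-10)

    def test_zero_signal(self, small_grid):
        w = cwt_morlet(np.zeros(256), 10.0, small_grid)
        assert np.all(w == 0)

    def test_sinusoid_power_peaks_at_matching_scale(self, default_grid):
        """|W| at mid-record is maximal at the grid scale whose period is
        nearest the sinusoid's 20 s period (brute-force argmax)."""
        t = np.arange(4800) / 10.0
        x = np.sin(2 * np.pi * t / 20.0)
        w = cwt_morlet(x, 10.0, default_grid)
        mid = np.abs(w[:, 2400])
        expected = np.argmin(np.abs(default_grid.periods - 20.0))
        assert np.argmax(mid) == expected

    def test_non_finite_rejected(self, small_grid):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            cwt_morlet(x, 10.0, small_grid)


class TestSmoothField:
    def test_constant_preserved_away_from_edges(self, small_grid):
        field = np.ones((small_grid.n_scales, 8000))
        out = smooth_field(field, small_grid, 10.0)
        # interior: beyond the widest kernel's reach (~6.5 sigma = 2950
        # samples at scale 64 s) from either edge
        assert np.abs(out[:, 3000:-3000] - 1.0).max() < 1e-9

    def test_impulse_matches_direct_convolution(self, rng):
        """Time smoothing of an impulse equals direct convolution with a
        per-scale Gaussian of std = scale/sqrt(2) seconds."""
        grid = make_scale_grid(1.0, 4.0, 3)
        rate = 10.0
        n = 400
        field = np.zeros((3, n))
        field[:, n // 2] = 1.0
        params = MorletParams(scale_smooth_decades=0.0)  # isolate time axis
        out = smooth_field(field, grid, rate, params)
        t = np.arange(n)
        for i, s in enumerate(grid.scales):
            sigma = s * rate / np.sqrt(2.0)
            kernel = np.exp(-0.5 * ((t - n // 2) / sigma) ** 2)
            kernel /= kernel.sum()
            np.testing.assert_allclose(out[i], kernel, atol=1e-7)

    def test_repeated_smoothing_blurs_more(self, small_grid):
        field = np.zeros((small_grid.n_scales, 1000))
        field[:, 500] = 1.0
        once = smooth_field(field, small_grid, 10.0)
        twice = smooth_field(once, small_grid, 10.0)

        def impulse_var(f):
            t = np.arange(f.shape[1])
            w = np.maximum(f, 0)
            w = w / w.sum(axis=1, keepdims=True)
            mu = (w * t).sum(axis=1)
            return (w * (t[None, :] - mu[:, None]) ** 2).sum(axis=1)

        assert np.all(impulse_var(twice) > impulse_var(once))


class TestWTC:
    def test_self_coherence_is_one(self, rng, small_grid):
        x = rng.standard_normal(1500)
        m = wtc(x, x, 10.0, small_grid)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-6)

    def test_symmetry(self, rng, small_grid):
        x = rng.standard_normal(1500)
        y = rng.standard_normal(1500)
        mxy = wtc(x, y, 10.0, small_grid)
        myx = wtc(y, x, 10.0, small_grid)
        np.testing.assert_allclose(mxy.values, myx.values, atol=1e-10)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(gain=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, gain, offset):
        rng = np.random.default_rng(7)
        grid = make_scale_grid(2.0, 32.0, 12)
        x = rng.standard_normal(800)
        y = rng.standard_normal(800)
        base = wtc(x, y, 10.0, grid)
        scaled = wtc(gain * x + offset, y, 10.0, grid)
        np.testing.assert_allclose(scaled.values, base.values, atol=1e-6)

    def test_independent_noise_has_low_coherence(self, default_grid):
        """Mean coherence of independent white noise over the 12-50 s
        period band stays well below coupling levels (Monte Carlo)."""
        rate = 10.0
        mask = (default_grid.periods >= 12) & (default_grid.periods <= 50)
        means = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            m = wtc(r.standard_normal(1500), r.standard_normal(1500),
                    rate, default_grid)
            means.append(m.values[mask].mean())
        assert np.mean(means) < 0.5

    def test_delayed_band_limited_signal_coherent_at_band(self, rng,
                                                          default_grid):
        """y = x delayed by 10 s, band-limited at 0.025 Hz, is near-
        perfectly coherent at the scale nearest the 40 s period."""
        from dyadsync.simulate import band_limited_noise

        n, rate, lag = 4800, 10.0, 100
        s = band_limited_noise(rng, n + lag, rate, 0.025, 0.004)
        m = wtc(s[lag:], s[:n], rate, default_grid)
        k = np.argmin(np.abs(default_grid.periods - 40.0))
        assert m.values[k, n // 2] > 0.9

    def test_without_smoothing_coherence_degenerates_to_one(self, rng,
                                                            small_grid):
        x = rng.standard_normal(800)
        y = rng.standard_normal(800)
        m = wtc(x, y, 10.0, small_grid, smooth=False)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-9)

    def test_length_mismatch_rejected(self, rng, small_grid):
        with pytest.raises(ValueError, match="equal length"):
            wtc(rng.standard_normal(100), rng.standard_normal(101),
                10.0, small_grid)


class TestFisherZ:
    def test_reference_values(self):
        assert fisher_z(0.0) == 0.0
        # R^2 = 0.25 -> r = 0.5 -> atanh(0.5)
        assert fisher_z(0.25) == pytest.approx(0.5493061443340548, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.0, 0.999), st.floats(0.0, 0.999))
    def test_strictly_increasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert fisher_z(lo) < fisher_z(hi)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)
        with pytest.raises(ValueError):
            fisher_z(-0.2)
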