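import numpy as np
import pytest

from dyadsync import (ArtifactSpec, CouplingSpec, NoiseSpec,
                      SimulationConfig, generate_cohort, generate_dyad,
                      inject_motion_artifacts, make_scale_grid, wtc)
from dyadsync.simulate import band_limited_noise, one_over_f_noise

from conftest import make_recording


def _config(**kw):
    base = dict(n_dyads=2, n_channels=2, sampling_rate=10.0, duration_s=120.0,
                conditions=("CI", "SI"), seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = _config()
        a1, c1, _ = generate_dyad(cfg, 0, "CI")
        a2, c2, _ = generate_dyad(cfg, 0, "CI")
        np.testing.assert_array_equal(a1.data, a2.data)
        np.testing.assert_array_equal(c1.data, c2.data)

    def test_cohort_reproducible(self):
        cfg = _config()
        co1 = generate_cohort(cfg)
        co2 = generate_cohort(cfg)
        for d in co1.dyad_ids:
            for cond in co1.recordings[d]:
                np.testing.assert_array_equal(
                    co1.recordings[d][cond][0].data,
                    co2.recordings[d][cond][0].data)

    def test_different_dyads_differ(self):
        cfg = _config()
        a1, _, _ = generate_dyad(cfg, 0, "CI")
        a2, _, _ = generate_dyad(cfg, 1, "CI")
        assert not np.array_equal(a1.data, a2.data)


class TestCoupling:
    def test_uncoupled_channels_have_low_coherence(self):
        """With no coupling, A and C are independent: mean mid-scale
        coherence stays below 0.5 over many seeds."""
        grid = make_scale_grid(4.0, 32.0, 12)
        mask = (grid.periods >= 8) & (grid.periods <= 32)
        means = []
        for seed in range(50):
            cfg = _config(seed=seed, duration_s=120.0)
            ra, rc, _ = generate_dyad(cfg, 0, "SI")
            m = wtc(ra.data[0], rc.data[0], 10.0, grid)
            means.append(m.values[mask].mean())
        assert np.mean(means) < 0.5

    def test_injected_lag_recovered_by_wtc(self):
        """A strong 0.025 Hz coupling at 17 s lag shows up in lagged
        coherence: the lag maximizing band coherence lies within +/-2 s
        of 17, at scales containing the 40 s period."""
        cfg = _config(
            n_channels=2, duration_s=480.0, seed=5,
            couplings=[CouplingSpec(channel_pair=("CH1", "CH2"),
                                    center_freq=0.025, lag_s=17.0,
                                    strength=0.8, conditions=("SI",))])
        ra, rc, truth = generate_dyad(cfg, 0, "SI")
        assert truth.couplings[0].strength == 0.8
        grid = make_scale_grid(20.0, 60.0, 12)
        band = grid.band_mask(0.020, 0.032)
        rate = 10.0
        scores = {}
        for lag in range(10, 25):
            L = int(lag * rate)
            m = wtc(ra.data[0][:-L], rc.data[1][L:], rate, grid)
            scores[lag] = m.values[band].mean()
        best = max(scores, key=scores.get)
        assert abs(best - 17) <= 2

    def test_variance_fraction_matches_strength(self):
        """Regressing C's coupled channel on the lag-shifted shared
        component recovers the injected variance fraction to +/-0.05."""
        cfg = _config(
            duration_s=600.0, seed=9,
            couplings=[CouplingSpec(channel_pair=("CH1", "CH2"),
                                    center_freq=0.025, lag_s=10.0,
                                    strength=0.5, conditions=("SI",))])
        ra, rc, truth = generate_dyad(cfg, 0, "SI")
        shared = truth.shared_components[("CH1", "CH2")]
        n = rc.n_samples
        shared_c = shared[:n]
        y = rc.data[1]
        beta = np.dot(shared_c - shared_c.mean(), y - y.mean()) / np.dot(
            shared_c - shared_c.mean(), shared_c - shared_c.mean())
        explained = beta**2 * shared_c.var() / y.var()
        assert explained == pytest.approx(0.5, abs=0.05)

    def test_non_integer_lag_rejected(self):
        cfg = _config(couplings=[CouplingSpec(channel_pair=("CH1", "CH2"),
                                              lag_s=0.05, strength=0.5)])
        with pytest.raises(ValueError, match="integer"):
            generate_dyad(cfg, 0, "CI")

    def test_rest_conditions_never_coupled(self):
        cfg = _config(couplings=[CouplingSpec(channel_pair=("CH1", "CH2"),
                                              strength=0.9)])
        _, _, truth = generate_dyad(cfg, 0, "rest")
        assert truth.couplings == []

    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError, match="strength"):
            _config(couplings=[CouplingSpec(channel_pair=("CH1", "CH2"),
                                            strength=1.4)])


class TestNoiseModel:
    def test_one_over_f_slope_recovered(self):
        """Log-log PSD fit over 0.01-1 Hz returns the configured slope
        to +/-0.3 for noise-only channels."""
        from scipy import signal as ssig

        cfg = _config(
            duration_s=1200.0, seed=21,
            noise=NoiseSpec(one_over_f_exponent=1.0, cardiac_amplitude=0.0,
                            respiratory_amplitude=0.0, mayer_amplitude=0.0,
                            white_sd=0.0))
        ra, _, _ = generate_dyad(cfg, 0, "SI")
        f, pxx = ssig.welch(ra.data[0], fs=10.0, nperseg=4096)
        keep = (f >= 0.01) & (f <= 1.0)
        slope = np.polyfit(np.log10(f[keep]), np.log10(pxx[keep]), 1)[0]
        assert -slope == pytest.approx(1.0, abs=0.3)

    def test_band_limited_noise_is_narrowband(self, rng):
        x = band_limited_noise(rng, 6000, 10.0, 0.1, 0.01)
        spec = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(6000, 0.1)
        centroid = (f * spec).sum() / spec.sum()
        assert centroid == pytest.approx(0.1, abs=0.02)

    def test_unit_variance(self, rng):
        assert one_over_f_noise(rng, 4000, 10.0, 1.0).std() == pytest.approx(
            1.0, abs=1e-9)


class TestArtifacts:
    def test_zero_rates_identity(self, noise_recording):
        out, events = inject_motion_artifacts(
            noise_recording, ArtifactSpec(), seed=0)
        assert events == []
        np.testing.assert_array_equal(out.data, noise_recording.data)

    def test_events_match_reported_ground_truth(self, noise_recording):
        spec = ArtifactSpec(spike_rate=2.0, spike_amplitude_sd=20.0)
        out, events = inject_motion_artifacts(noise_recording, spec, seed=4)
        assert len(events) > 0
        diff = out.data - noise_recording.data
        changed = {(rec_ch, s) for rec_ch, s in zip(*np.nonzero(diff))}
        reported = {(noise_recording.channel_labels.index(e.channel), e.sample)
                    for e in events}
        assert changed == reported

    def test_poisson_event_counts(self):
        """Spike counts across seeds match the configured rate."""
        rec = make_recording(np.random.default_rng(0).standard_normal((1, 3000)))
        rate_pm = 1.5  # events/minute over 5 minutes
        counts = []
        for seed in range(100):
            _, events = inject_motion_artifacts(
                rec, ArtifactSpec(spike_rate=rate_pm), seed=seed)
            counts.append(len(events))
        lam = rate_pm * 5.0
        mean = np.mean(counts)
        se = np.sqrt(lam / len(counts))
        assert abs(mean - lam) < 3 * se


class TestCohort:
    def test_matched_rests_generated(self):
        cfg = _config()
        cohort = generate_cohort(cfg)
        conds = set(cohort.recordings[0])
        assert {"CI", "SI", "rest", "rest_rain"} == conds

    def test_too_few_dyads_rejected(self):
        with pytest.raises(ValueError, match="dyads"):
            generate_cohort(_config(n_dyads=1))

    def test_ci_layout_has_45s_phases(self):
        cfg = _config(duration_s=450.0)
        cohort = generate_cohort(cfg)
        ci = cohort.layouts["CI"]
        assert ci.n_phases == 10
        assert all(p.duration_s == 45.0 for p in ci.turns)
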