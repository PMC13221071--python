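"""Filtering, spectra, PLV, n:m coupling, modulation index, theta cycles, SWR."""

import numpy as np
import pytest

from cheeseboard import oscillations as osc
from cheeseboard.core import LfpSignal

FS = 1000.0


def _sine(freq, duration=10.0, amp=1.0, phase=0.0):
    t = np.arange(0, duration, 1 / FS)
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        out = osc.bandpass(_sine(8.0), "theta")
        assert np.abs(out[2000:-2000]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        out = osc.bandpass(_sine(50.0), "theta")
        assert np.abs(out[2000:-2000]).max() < 0.05

    def test_refiltering_attenuates_monotonically(self):
        x = _sine(5.0)  # near the band edge
        once = osc.bandpass(x, "theta")
        twice = osc.bandpass(once, "theta")
        assert np.abs(twice[2000:-2000]).max() <= np.abs(once[2000:-2000]).max() + 1e-9

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            osc.bandpass(_sine(8.0), (100.0, 600.0))


class TestWelch:
    def test_peak_at_tone_frequency(self):
        freqs, psd = osc.welch_power(_sine(8.0))
        assert freqs[np.argmax(psd)] == pytest.approx(8.0, abs=1.0)

    def test_white_noise_flat(self, rng):
        freqs, psd = osc.welch_power(rng.normal(0, 1, 60_000))
        sel = (freqs > 10) & (freqs < 400)
        slope = np.polyfit(freqs[sel], psd[sel] / psd[sel].mean(), 1)[0]
        assert abs(slope) < 1e-3

    def test_parseval(self, rng):
        x = rng.normal(0, 1, 30_000)
        freqs, psd = osc.welch_power(x)
        total = np.trapezoid(psd, freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            osc.welch_power(np.zeros(1500))


class TestPlv:
    def test_constant_offset_gives_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 10_000)
        assert osc.plv(phi, phi + 1.234) == pytest.approx(1.0, abs=1e-12)

    def test_independent_phases_near_zero(self, rng):
        vals = [
            osc.plv(
                rng.uniform(-np.pi, np.pi, 10_000), rng.uniform(-np.pi, np.pi, 10_000)
            )
            for _ in range(40)
        ]
        # E[PLV] ~ sqrt(pi)/(2 sqrt(N)) ~ 0.009 at N = 10,000
        assert np.quantile(vals, 0.95) < 0.03

    def test_bounded_for_arbitrary_input(self, rng):
        v = osc.plv(rng.normal(0, 10, 500), rng.normal(0, 10, 500))
        assert 0.0 <= v <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            osc.plv(np.zeros(10), np.zeros(11))

    def test_plv_jitter_knob_monotone(self):
        """Lower inter-regional lag jitter in the generator -> higher theta PLV."""
        from cheeseboard.synthetic import SynthConfig, generate_lfp

        rng = np.random.default_rng(7)
        plvs = []
        for jitter in (0.0, 0.4, 1.2):
            cfg = SynthConfig(seed=7, plv_lag_jitter=jitter)
            lfp, _ = generate_lfp(cfg, 60.0, np.random.default_rng(7))
            p1 = osc.phase_series(lfp["dCA1"].samples, "theta")
            p2 = osc.phase_series(lfp["mOFC"].samples, "theta")
            plvs.append(osc.plv(p1.phase, p2.phase))
        assert plvs[0] > 0.99
        assert plvs[0] > plvs[1] > plvs[2]


class TestNmPlv:
    def test_perfect_harmonic_locking(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 5000)
        gamma = np.angle(np.exp(1j * 5 * theta))
        assert osc.nm_plv(theta, gamma, 1, 5) == pytest.approx(1.0, abs=1e-12)

    def test_wrong_ratio_is_null_level(self, rng):
        theta = np.angle(np.exp(1j * np.cumsum(np.full(20_000, 0.05))))
        gamma = np.angle(np.exp(1j * 5 * theta + 1j * rng.normal(0, 0.01, 20_000)))
        assert osc.nm_plv(theta, gamma, 1, 4) < 0.1

    def test_identity_ratio(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 1000)
        assert osc.nm_plv(phi, phi, 1, 1) == pytest.approx(1.0)

    def test_ratio_scan_peaks_at_generating_ratio(self):
        """r_{1:m} over m in 1..10 is maximal at the true harmonic stack ratio."""
        t = np.arange(0, 20, 1 / FS)
        theta_phase = np.angle(np.exp(1j * 2 * np.pi * 8 * t))
        gamma_phase = np.angle(np.exp(1j * 2 * np.pi * 40 * t))  # 1:5
        r = [osc.nm_plv(theta_phase, gamma_phase, 1, m) for m in range(1, 11)]
        assert int(np.argmax(r)) + 1 == 5

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            osc.nm_plv(np.zeros(10), np.zeros(10), 0, 3)


class TestModulationIndex:
    def test_uniform_envelope_gives_zero(self):
        phase = np.linspace(-np.pi, np.pi, 18 * 500, endpoint=False)
        res = osc.pac_mi(phase, np.ones_like(phase))
        assert res.mi == pytest.approx(0.0, abs=1e-15)
        assert res.hmax == pytest.approx(np.log(18))
        assert res.p_j.sum() == pytest.approx(1.0)

    def test_concentrated_envelope_approaches_one(self):
        phase = np.linspace(-np.pi, np.pi, 18 * 100, endpoint=False)
        amp = np.zeros_like(phase)
        # all amplitude mass strictly inside one 20-degree bin
        amp[(phase >= 0) & (phase < 2 * np.pi / 18 - 1e-9)] = 1.0
        res = osc.pac_mi(phase, amp)
        assert res.mi == pytest.approx(1.0, abs=1e-12)

    def test_cosine_envelope_matches_closed_form(self):
        """MI of 1 + 0.5 cos(phi) equals the entropy formula on analytic bin means."""
        n = 18 * 2000
        phase = np.linspace(-np.pi, np.pi, n, endpoint=False)
        amp = 1.0 + 0.5 * np.cos(phase)
        res = osc.pac_mi(phase, amp)
        edges = np.linspace(-np.pi, np.pi, 19)
        # mean of 1 + 0.5 cos over [a, b) = 1 + 0.5 (sin b - sin a)/(b - a)
        means = 1.0 + 0.5 * np.diff(np.sin(edges)) / np.diff(edges)
        p = means / means.sum()
        h = -np.sum(p * np.log(p))
        expected = (np.log(18) - h) / np.log(18)
        # discrete sampling vs continuous integral: agreement to ~1e-3 relative
        assert res.mi == pytest.approx(expected, rel=1e-3)

    def test_mi_amplitude_scale_invariant(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20_000)
        amp = 1.0 + 0.4 * np.cos(phase) + 0.01 * rng.random(20_000)
        a = osc.pac_mi(phase, amp).mi
        b = osc.pac_mi(phase, 13.7 * amp).mi
        assert a == pytest.approx(b, rel=1e-12)

    def test_pac_depth_knob_monotone(self):
        """Generator pac_depth 0.8 beats 0.2 in MI across replicate seeds."""
        from cheeseboard.synthetic import SynthConfig, generate_lfp

        wins = 0
        for seed in range(10):
            mis = []
            for depth in (0.2, 0.8):
                cfg = SynthConfig(seed=seed, pac_depth=depth)
                lfp, _ = generate_lfp(cfg, 40.0, np.random.default_rng(seed))
                theta = osc.phase_series(lfp["dCA1"].samples, "theta")
                gamma = osc.phase_series(lfp["mOFC"].samples, "low_gamma")
                mis.append(osc.pac_mi(theta.phase, gamma.amplitude).mi)
            wins += mis[1] > mis[0]
        assert wins >= 9


class TestThetaCyclesAndSwr:
    def _session_pieces(self, speed_cms, with_burst=False, duration=20.0):
        rng = np.random.default_rng(3)
        n = int(duration * FS)
        t = np.arange(n) / FS
        sig = 3.0 * np.cos(2 * np.pi * 8.0 * t) + rng.normal(0, 0.5, n)
        if with_burst:
            i0 = n // 2
            w = np.hanning(60)
            sig[i0 : i0 + 60] += 6.0 * w * np.cos(2 * np.pi * 180 * t[:60])
        lfp = LfpSignal(sig, FS, "dCA1")
        track_t = np.arange(0, duration, 0.02)
        speed = np.full(track_t.size, float(speed_cms))
        return lfp, track_t, speed

    def test_clean_theta_cycle_length(self):
        lfp, tt, speed = self._session_pieces(10.0)
        cycles = osc.detect_theta_cycles(lfp, tt, speed)
        assert len(cycles) > 100
        lengths = np.array([b - a for a, b in cycles])
        assert np.allclose(lengths, 0.125, atol=0.005)

    def test_slow_speed_blocks_cycles(self):
        lfp, tt, speed = self._session_pieces(2.0)
        assert osc.detect_theta_cycles(lfp, tt, speed) == []

    def test_delta_dominance_blocks_cycles(self):
        rng = np.random.default_rng(0)
        n = int(20 * FS)
        t = np.arange(n) / FS
        sig = 5.0 * np.cos(2 * np.pi * 2.0 * t) + 0.3 * np.cos(2 * np.pi * 8.0 * t)
        lfp = LfpSignal(sig + rng.normal(0, 0.1, n), FS, "dCA1")
        tt = np.arange(0, 20, 0.02)
        assert osc.detect_theta_cycles(lfp, tt, np.full(tt.size, 10.0)) == []

    def test_swr_detected_at_rest_with_padded_mask(self):
        lfp, tt, speed = self._session_pieces(1.0, with_burst=True)
        events = osc.detect_swr(lfp, tt, speed)
        assert len(events.intervals) >= 1
        a, b = events.intervals[0]
        assert abs(a - 10.0) < 0.05
        # mask extends ~100 ms past the event end
        end_idx = int(b * FS)
        assert events.exclusion_mask[end_idx + 50]
        assert not events.exclusion_mask[end_idx + 150]

    def test_swr_suppressed_while_running(self):
        lfp, tt, speed = self._session_pieces(10.0, with_burst=True)
        assert osc.detect_swr(lfp, tt, speed).intervals == []

    def test_no_burst_no_events(self):
        lfp, tt, speed = self._session_pieces(1.0, with_burst=False)
        assert osc.detect_swr(lfp, tt, speed).intervals == []


class TestSpeedPowerCorrelation:
    def test_power_proportional_to_speed(self):
        rng = np.random.default_rng(1)
        n = int(60 * FS)
        t = np.arange(n) / FS
        speed_slow = 10.0 + 8.0 * np.sin(2 * np.pi * 0.05 * t)
        sig = (speed_slow / 10.0) * np.cos(2 * np.pi * 8 * t) + rng.normal(0, 0.05, n)
        lfp = LfpSignal(sig, FS, "dCA1")
        tt = np.arange(0, 60, 0.02)
        r, p = osc.speed_power_correlation(
            lfp, tt, np.interp(tt, t, speed_slow), "theta"
        )
        assert r > 0.9 and p < 1e-6

    def test_independent_power_speed_null(self, rng):
        n = int(60 * FS)
        lfp = LfpSignal(rng.normal(0, 1, n), FS, "dCA1")
        tt = np.arange(0, 60, 0.02)
        r, _ = osc.speed_power_correlation(lfp, tt, rng.uniform(0, 30, tt.size), "theta")
        assert abs(r) < 0.2

    def test_too_few_windows(self):
        lfp = LfpSignal(np.zeros(1000), FS, "dCA1")
        with pytest.raises(ValueError):
            osc.speed_power_correlation(lfp, np.arange(0, 1, 0.02), np.zeros(50), "theta")
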