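"""Simulator: flight kinematics, Doppler/PM structure, receiver chain, scenes."""

import math

import numpy as np
import pytest
from scipy.special import jv

from beeradar import sim

C = sim.SPEED_OF_LIGHT


def _speed(profile, n=20000):
    t = np.linspace(0, profile.duration, n)
    r = profile.range_fn(t)
    return t, np.gradient(r, t)


class TestRadarConfig:
    def test_wavelength_from_carrier(self):
        cfg = sim.RadarConfig()
        assert cfg.wavelength == pytest.approx(C / 5.8e9, rel=1e-12)
        assert cfg.wavelength == pytest.approx(0.0517, rel=1e-3)

    def test_sample_rate_must_exceed_twice_cutoff(self):
        with pytest.raises(ValueError):
            sim.RadarConfig(sample_rate=500.0, if_cutoff=408.0)

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            sim.RadarConfig(noise_rms=-0.1)


class TestFlightProfiles:
    def test_outward_seed1_speed_ramp(self):
        p = sim.make_flight_profile("outward", np.random.default_rng(1))
        _, dr = _speed(p)
        peak = np.abs(dr).max()
        assert 1.0 <= peak <= 2.0
        assert abs(dr[-1]) > abs(dr[0])

    def test_hover_seed2_low_mean_speed(self):
        p = sim.make_flight_profile("hover", np.random.default_rng(2))
        _, dr = _speed(p)
        assert np.abs(dr).mean() < 0.5

    def test_inward_seed3_comes_to_rest(self):
        p = sim.make_flight_profile("inward", np.random.default_rng(3))
        _, dr = _speed(p)
        n = len(dr)
        assert np.abs(dr[int(0.9 * n) :]).max() < 0.1

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class label"):
            sim.make_flight_profile("sideways", np.random.default_rng(0))

    @pytest.mark.parametrize("label", sim.FLIGHT_CLASSES)
    @pytest.mark.parametrize("seed", range(8))
    def test_kinematic_invariants(self, label, seed):
        p = sim.make_flight_profile(label, np.random.default_rng(seed))
        t = np.linspace(0, p.duration, 20000)
        r = p.range_fn(t)
        dr = np.gradient(r, t)
        assert r.min() >= 0.05 - 1e-9
        assert r.max() <= 3.0 + 1e-9
        assert np.abs(dr).max() <= 3.0


class TestSynthesizeEvent:
    def _constant_speed_event(self, v, lam, a1=1.0, a2=0.0, duration=1.0):
        cfg = sim.RadarConfig(carrier_frequency=C / lam)
        prof = sim.MotionProfile(
            "outward", lambda t: 2.5 - v * np.asarray(t), duration
        )
        ev = sim.Event(
            "outward",
            0.0,
            duration,
            prof,
            sim.ScattererSpec(a1, a2),
            sim.WingbeatSpec(0.0, 0.0),
        )
        return sim.synthesize_event(ev, cfg), cfg

    def test_constant_speed_single_line_at_2v_over_lambda(self):
        rec, _ = self._constant_speed_event(1.0, 0.05)
        spec = np.abs(np.fft.fft(rec.samples))
        freqs = np.fft.fftfreq(len(rec), 1 / rec.sample_rate)
        peak = freqs[np.argmax(spec)]
        bin_width = rec.sample_rate / len(rec)
        assert abs(peak - 2 * 1.0 / 0.05) <= bin_width

    def test_pm_sidebands_match_independent_oracle(self):
        # oracle: direct FFT of the closed-form phase-modulated exponential,
        # built here without the simulator
        cfg = sim.RadarConfig()
        lam, fs = cfg.wavelength, cfg.sample_rate
        ah, fh, r0 = 0.01, 200.0, 1.0
        n = int(fs)
        t = np.arange(n) / fs
        k = 4 * math.pi / lam
        oracle = np.exp(-1j * k * (r0 + ah * np.cos(2 * math.pi * fh * t)))
        oracle_lines = np.abs(np.fft.fft(oracle) / n)

        prof = sim.MotionProfile("hover", lambda tt: np.full_like(np.asarray(tt, float), r0), 1.0)
        ev = sim.Event(
            "hover", 0.0, 1.0, prof, sim.ScattererSpec(0.0, 1.0),
            sim.WingbeatSpec(ah, 2 * math.pi * fh),
        )
        rec = sim.synthesize_event(ev, cfg)
        lines = np.abs(np.fft.fft(rec.samples) / n)
        beta = k * ah
        for order in range(5):
            idx = int(round(order * fh * n / fs))
            assert lines[idx] == pytest.approx(oracle_lines[idx], rel=1e-9)
            # and both match the Bessel series within 2%
            assert lines[idx] == pytest.approx(abs(jv(order, beta)), rel=0.02)

    def test_static_body_only_is_constant(self):
        rec, _ = self._constant_speed_event(0.0, 0.05, a1=1.0, a2=0.0)
        assert np.allclose(rec.samples, rec.samples[0])
        assert np.abs(rec.samples[0]) == pytest.approx(1.0)

    def test_iq_sign_discrimination(self):
        # approaching -> positive complex frequencies; receding -> negative;
        # the real channel alone is mirror-symmetric and cannot distinguish
        rec_app, _ = self._constant_speed_event(1.0, 0.05)
        cfg = sim.RadarConfig(carrier_frequency=C / 0.05)
        prof = sim.MotionProfile("inward", lambda t: 0.5 + 1.0 * np.asarray(t), 1.0)
        ev = sim.Event("inward", 0.0, 1.0, prof, sim.ScattererSpec(1.0, 0.0), sim.WingbeatSpec(0, 0))
        rec_rec = sim.synthesize_event(ev, cfg)
        for rec, sign in ((rec_app, 1), (rec_rec, -1)):
            spec = np.abs(np.fft.fft(rec.samples))
            freqs = np.fft.fftfreq(len(rec), 1 / rec.sample_rate)
            band = np.abs(np.abs(freqs) - 40.0) < 5.0
            pos = spec[band & (freqs > 0)].sum()
            neg = spec[band & (freqs < 0)].sum()
            assert (pos > 10 * neg) if sign > 0 else (neg > 10 * pos)
            # real channel: mirror-symmetric spectrum
            ispec = np.abs(np.fft.fft(rec.samples.real))
            np.testing.assert_allclose(
                ispec[1:], ispec[1:][::-1], rtol=1e-6, atol=1e-9 * ispec.max()
            )


class TestSynthesizeClutter:
    def test_vibration_lines_at_multiples_of_50(self):
        cfg = sim.RadarConfig()
        spec = sim.ClutterSpec("vibration", 0.002, 2 * math.pi * 50.0)
        rec = sim.synthesize_clutter(spec, cfg, 1.0)
        x = rec.samples - 0  # complex
        lines = np.abs(np.fft.fft(x) / len(x))
        freqs = np.fft.fftfreq(len(x), 1 / cfg.sample_rate)
        on_grid = np.abs(np.round(freqs / 50.0) * 50.0 - freqs) < 0.5
        assert lines[~on_grid].max() < 1e-6 * max(lines.max(), 1e-30) + 1e-12

    def test_wind_power_below_50hz(self):
        # numerical power-fraction oracle on the generated signal
        cfg = sim.RadarConfig()
        spec = sim.ClutterSpec("wind", 0.002, 2 * math.pi * 2.0)
        rec = sim.synthesize_clutter(spec, cfg, 2.0)
        x = rec.samples - np.mean(rec.samples)
        p = np.abs(np.fft.fft(x)) ** 2
        freqs = np.fft.fftfreq(len(x), 1 / cfg.sample_rate)
        frac = p[np.abs(freqs) < 50.0].sum() / p.sum()
        assert frac > 0.9

    def test_zero_amplitude_is_constant(self):
        cfg = sim.RadarConfig()
        rec = sim.synthesize_clutter(sim.ClutterSpec("wind", 0.0, 2 * math.pi), cfg, 0.5)
        assert np.allclose(rec.samples, rec.samples[0])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sim.ClutterSpec("wind", 0.01, 2 * math.pi * 10.0)  # > 5 Hz
        with pytest.raises(ValueError):
            sim.ClutterSpec("vibration", 0.01, 2 * math.pi * 60.0)
        with pytest.raises(ValueError):
            sim.ClutterSpec("rain", 0.01, 2 * math.pi)


class TestReceiverChain:
    def _tone_response(self, f, cfg):
        fs = cfg.sample_rate
        t = np.arange(int(2 * fs)) / fs
        x = np.exp(1j * 2 * math.pi * f * t)
        out = sim.apply_receiver_chain(sim.IQRecording(x, fs), cfg)
        return np.abs(out.samples[len(t) // 2 :]).mean()

    def test_minus_3db_at_cutoff(self, radar):
        amp = self._tone_response(408.0, radar)
        assert amp == pytest.approx(1 / math.sqrt(2), rel=0.05)

    def test_passband_tone_barely_reduced(self, radar):
        amp = self._tone_response(40.8, radar)
        # closed-form first-order magnitude: 1/sqrt(1 + (f/fc)^2)
        assert amp > 0.99
        assert amp == pytest.approx(1 / math.sqrt(1 + (40.8 / 408) ** 2), abs=0.01)

    def test_first_order_magnitude_curve(self):
        cfg = sim.RadarConfig(ac_coupling_hz=0.0)
        for f in np.logspace(math.log10(20), math.log10(2000), 10):
            expected = 1 / math.sqrt(1 + (f / 408.0) ** 2)
            amp = self._tone_response(float(f), cfg)
            assert amp == pytest.approx(expected, rel=0.01)

    def test_zero_noise_consumes_no_randomness(self, radar):
        fs = radar.sample_rate
        rng = np.random.default_rng(0)
        state_before = rng.bit_generator.state
        x = np.exp(1j * 2 * math.pi * 100 * np.arange(1000) / fs)
        out1 = sim.apply_receiver_chain(sim.IQRecording(x, fs), radar, rng)
        assert rng.bit_generator.state == state_before
        out2 = sim.apply_receiver_chain(sim.IQRecording(x, fs), radar, None)
        np.testing.assert_array_equal(out1.samples, out2.samples)

    def test_noise_requires_rng(self):
        cfg = sim.RadarConfig(noise_rms=0.1)
        with pytest.raises(ValueError):
            sim.apply_receiver_chain(sim.IQRecording(np.zeros(10), cfg.sample_rate), cfg)


class TestComposeScene:
    def test_empty_timeline_zero_noise_is_silent(self, radar):
        tl = sim.EventTimeline([], 1.0)
        rec, _ = sim.compose_scene(tl, radar, seed=0)
        np.testing.assert_array_equal(rec.samples, 0)

    def test_superposition_linearity(self, radar):
        rng = np.random.default_rng(5)
        e1 = sim.Event("hover", 0.0, 0.5, sim.make_flight_profile("hover", rng, duration=0.5))
        e2 = sim.Event("inward", 0.0, 0.5, sim.make_flight_profile("inward", rng, duration=0.5))
        tl = sim.EventTimeline([e1, e2], 0.5)
        rec, _ = sim.compose_scene(tl, radar, seed=0)
        manual = (
            sim.synthesize_event(e1, radar).samples
            + sim.synthesize_event(e2, radar).samples
        )
        expected = sim.apply_receiver_chain(
            sim.IQRecording(manual, radar.sample_rate), radar
        )
        np.testing.assert_allclose(rec.samples, expected.samples, atol=1e-12)

    def test_seed_determinism(self):
        cfg = sim.RadarConfig(noise_rms=0.05, tone_1khz_amplitude=0.01)
        rng = np.random.default_rng(9)
        tl = sim.random_timeline(rng, 2.0, events_per_class=1)
        rec1, _ = sim.compose_scene(tl, cfg, seed=42)
        rec2, _ = sim.compose_scene(tl, cfg, seed=42)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)

    def test_event_past_total_duration_rejected(self, radar):
        rng = np.random.default_rng(0)
        ev = sim.Event("hover", 0.5, 1.5, sim.make_flight_profile("hover", rng, duration=1.0))
        with pytest.raises(ValueError, match="extends past"):
            sim.EventTimeline([ev], 1.0)
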