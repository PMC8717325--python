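import numpy as np
import pytest

from tympanomatch import (
    CallParams,
    CallType,
    F0Track,
    FMPattern,
    Waveform,
    classify_call_type,
    classify_fm_pattern,
    count_harmonics,
    extract_features,
    fundamental_and_dominant,
    measure_envelope,
    spectrum,
    synthesize_harmonic_call,
    synthesize_noisy_call,
    track_f0,
    ultrasound_flag,
)

from conftest import sine

BIN_HZ = 44100.0 / 1024


def harmonic_stack(f0, gains, rate=44100.0, duration_s=0.5):
    t = np.arange(int(rate * duration_s)) / rate
    x = sum(g * np.sin(2 * np.pi * f0 * (k + 1) * t) for k, g in enumerate(gains))
    return Waveform(x, rate)


class TestMeasureEnvelope:
    def test_central_call_landmarks(self, central_call):
        dur, ttm = measure_envelope(central_call)
        assert dur == pytest.approx(71.0, abs=2.0)
        assert ttm == pytest.approx(26.0, abs=2.0)

    def test_southern_call_landmarks(self, southern_call):
        dur, ttm = measure_envelope(southern_call)
        assert dur == pytest.approx(42.0, abs=2.0)
        assert ttm == pytest.approx(19.0, abs=2.0)

    def test_rectangular_tone_duration(self):
        dur, _ = measure_envelope(sine(1000.0, duration_s=0.1))
        assert dur == pytest.approx(100.0, abs=1.0)

    def test_silence_rejected(self):
        with pytest.raises(ValueError):
            measure_envelope(Waveform(np.zeros(4096), 44100))


class TestSpectrum:
    def test_peak_bin_of_pure_tone(self):
        spec = spectrum(sine(1000.0))
        assert spec.frequencies[np.argmax(spec.magnitude)] == pytest.approx(1000.0, abs=BIN_HZ)
        assert spec.resolution_hz == pytest.approx(BIN_HZ)

    def test_white_noise_is_flat(self, rng):
        w = Waveform(rng.standard_normal(2 * 44100), 44100)
        p = spectrum(w).magnitude ** 2
        flatness = np.exp(np.mean(np.log(p))) / np.mean(p)
        assert flatness > 0.9

    def test_parseval(self, rng):
        w = Waveform(rng.standard_normal(2 * 44100), 44100)
        total = (spectrum(w).magnitude ** 2).sum()
        assert total == pytest.approx(np.mean(w.samples**2), rel=0.01)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="power of two"):
            spectrum(sine(1000.0), n_fft=1000)
        with pytest.raises(ValueError, match="shorter"):
            spectrum(Waveform(np.ones(100), 44100))


class TestFundamentalAndDominant:
    def test_population_calls_hit_printed_dominants(self, central_call, southern_call):
        _, dom_c = fundamental_and_dominant(central_call)
        _, dom_s = fundamental_and_dominant(southern_call)
        assert dom_c == pytest.approx(2700.0, abs=BIN_HZ)
        assert dom_s == pytest.approx(6300.0, abs=BIN_HZ)

    def test_fundamental_equals_dominant_for_strongest_first_harmonic(self):
        f0, dom = fundamental_and_dominant(harmonic_stack(1000.0, [1.0, 0.3]))
        assert f0 == pytest.approx(1000.0, abs=BIN_HZ)
        assert dom == pytest.approx(1000.0, abs=BIN_HZ)

    def test_comb_root_recovers_missing_fundamental(self):
        # harmonics 2 and 3 of a 500 Hz comb; the root is absent
        t = np.arange(22050) / 44100.0
        w = Waveform(np.sin(2 * np.pi * 1000 * t) + 0.8 * np.sin(2 * np.pi * 1500 * t), 44100.0)
        f0, dom = fundamental_and_dominant(w)
        assert f0 == pytest.approx(500.0, abs=BIN_HZ)
        assert dom == pytest.approx(1000.0, abs=BIN_HZ)

    def test_white_noise_rejected(self, rng):
        with pytest.raises(ValueError):
            fundamental_and_dominant(Waveform(rng.standard_normal(8192), 44100.0))


class TestCountHarmonics:
    def test_printed_counts_on_population_calls(self, central_call, southern_call):
        f0_c, _ = fundamental_and_dominant(central_call)
        f0_s, _ = fundamental_and_dominant(southern_call)
        assert count_harmonics(central_call, f0_c) == 6
        assert count_harmonics(southern_call, f0_s) == 3

    def test_pure_tone_counts_one(self):
        assert count_harmonics(sine(2000.0), 2000.0) == 1

    def test_invalid_fundamental(self):
        with pytest.raises(ValueError):
            count_harmonics(sine(2000.0), -1.0)


class TestUltrasoundFlag:
    def test_low_frequency_call_is_negative(self, central_call):
        assert not ultrasound_flag(central_call)

    def test_pure_21khz_tone_is_positive(self):
        assert ultrasound_flag(sine(21000.0))

    def test_stack_with_7th_harmonic_at_21khz(self):
        # 3 kHz fundamental, 7 harmonics at 4 dB/harmonic: the 21 kHz line
        # sits 24 dB below the fundamental, within the 30 dB criterion
        gains = [10 ** (-k * 4 / 20) for k in range(7)]
        assert ultrasound_flag(harmonic_stack(3000.0, gains))

    def test_steep_rolloff_is_negative(self):
        gains = [10 ** (-k * 7 / 20) for k in range(7)]  # 21 kHz at -42 dB
        assert not ultrasound_flag(harmonic_stack(3000.0, gains))

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            ultrasound_flag(sine(1000.0, rate=22050.0))


class TestClassifyCallType:
    @pytest.mark.parametrize("seed", range(5))
    def test_harmonic_calls_classified_harmonic(self, seed):
        rng = np.random.default_rng(seed)
        p = CallParams(
            int(rng.integers(2, 7)), 60.0, 20.0,
            float(rng.uniform(2000, 3500)), float(rng.uniform(1800, 2000)),
        )
        assert classify_call_type(synthesize_harmonic_call(p)) is CallType.HARMONIC

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_calls_classified_noisy(self, seed):
        w = synthesize_noisy_call(47.0, 1000.0, 8000.0, 18.0, seed=seed)
        assert classify_call_type(w) is CallType.NOISY

    def test_pure_tone_is_harmonic(self):
        assert classify_call_type(sine(2000.0)) is CallType.HARMONIC


class TestFMPattern:
    def make_track(self, f0):
        f0 = np.asarray(f0, dtype=float)
        return F0Track(np.arange(f0.size) * 3.0, f0, np.ones(f0.size, bool))

    def test_central_call_sweep_is_downward(self, central_call):
        assert classify_fm_pattern(track_f0(central_call)) is FMPattern.DOWNWARD

    def test_constant_is_invariant(self):
        assert classify_fm_pattern(self.make_track([2000] * 8)) is FMPattern.INVARIANT

    def test_symmetric_rise_fall_is_bell(self):
        track = self.make_track([2000, 2200, 2500, 2700, 2500, 2200, 2000])
        assert classify_fm_pattern(track) is FMPattern.BELL

    def test_dip_is_u_shaped(self):
        track = self.make_track([2700, 2400, 2100, 2050, 2400, 2700])
        assert classify_fm_pattern(track) is FMPattern.U_SHAPED

    def test_time_reversal_swaps_down_and_up(self):
        down = self.make_track([2700, 2550, 2400, 2250, 2100])
        up = self.make_track([2700, 2550, 2400, 2250, 2100][::-1])
        assert classify_fm_pattern(down) is FMPattern.DOWNWARD
        assert classify_fm_pattern(up) is FMPattern.UPWARD

    def test_amplitude_scaling_does_not_change_pattern(self, central_call):
        scaled = central_call.scaled(0.05)
        assert classify_fm_pattern(track_f0(scaled)) is FMPattern.DOWNWARD

    def test_too_few_voiced_frames_rejected(self):
        with pytest.raises(ValueError):
            classify_fm_pattern(self.make_track([2000, 2100, 2200]))


class TestRoundTripProperty:
    def test_generator_parameters_recovered_from_random_calls(self):
        """Measured (duration, time-to-max, dominant, n_harmonics) must match
        the generating parameters for >= 95% of random parameter sets drawn
        within the observed call ranges."""
        rng = np.random.default_rng(20240601)
        ok = 0
        n = 40
        for _ in range(n):
            dur = float(rng.uniform(30, 110))
            ttm = float(rng.uniform(0.15 * dur, 0.6 * dur))
            f0 = float(rng.uniform(1800, 6500))
            nh = int(rng.integers(1, 7))
            while nh * f0 >= 0.95 * 22050:
                nh -= 1
            p = CallParams(nh, dur, ttm, f0, f0 * rng.uniform(0.78, 0.95))
            w = synthesize_harmonic_call(p)
            d, t = measure_envelope(w)
            fund, dom = fundamental_and_dominant(w)
            good = (
                abs(d - dur) <= 2.0
                and abs(t - ttm) <= 2.0
                and abs(dom - f0) <= BIN_HZ + 0.01 * f0
                and count_harmonics(w, fund) == nh
            )
            ok += good
        assert ok >= 0.95 * n


def test_extract_features_end_to_end(central_call):
    f = extract_features(central_call)
    assert f.call_type is CallType.HARMONIC
    assert f.n_harmonics == 6
    assert f.fm_pattern is FMPattern.DOWNWARD
    assert not f.has_ultrasound
    assert f.fundamental_hz == pytest.approx(2700.0, abs=BIN_HZ)
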