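import numpy as np
import pytest
from hypothesis import given, strategies as st

from tympanomatch import (
    EardrumModel,
    ReplicateSet,
    ToneStimulus,
    TransferFunction,
    Waveform,
    build_transfer_function,
    call_response_spectrum,
    filter_and_average,
    replicate_snr,
    simulate_call_response,
    summarize_tf,
    velocity_at_frequency,
)
from tympanomatch.vibrometry import (
    TRACE_UNIT_M_S,
    call_grid_resolution_hz,
    tone_grid_resolution_hz,
)

VIBRO = 200000.0
STIM = ToneStimulus(4000.0, 80.0)


def tone_trace(freq=4000.0, amp=1.0, noise_sd=0.0, seed=0, n=40000):
    """A synthetic acquisition window: 100 ms tone + 100 ms silence."""
    t = np.arange(n // 2) / VIBRO
    x = np.concatenate([amp * np.sin(2 * np.pi * freq * t), np.zeros(n // 2)])
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return Waveform(x, VIBRO)


class TestReplicateSNR:
    def test_tone_over_noise_closed_form(self):
        amp, eps = 1.0, 1e-3
        tr = tone_trace(amp=amp, noise_sd=eps, seed=1)
        rec = replicate_snr(tr, STIM)
        expected = (amp / np.sqrt(2)) / eps
        assert rec.ratio == pytest.approx(expected, rel=0.1)

    def test_identical_windows_give_unit_ratio(self):
        t = np.arange(40000) / VIBRO
        tr = Waveform(np.sin(2 * np.pi * 4000 * t), VIBRO)
        assert replicate_snr(tr, STIM).ratio == pytest.approx(1.0, rel=1e-6)

    def test_scale_invariance(self):
        tr = tone_trace(noise_sd=1e-3, seed=2)
        r1 = replicate_snr(tr, STIM).ratio
        r2 = replicate_snr(tr.scaled(7.5), STIM).ratio
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(IndexError):
            replicate_snr(Waveform(np.ones(100), VIBRO), STIM)


class TestFilterAndAverage:
    def test_quartile_discard_keeps_15_of_20(self):
        clean = tone_trace()
        traces = [Waveform(clean.samples + np.random.default_rng(s).normal(0, 0.01, len(clean)), VIBRO)
                  for s in range(20)]
        reps = ReplicateSet(STIM, tuple(traces))
        avg = filter_and_average(reps)
        # averaging 15 of 20 equal-signal replicates: the mean of any 15
        # noisy copies stays within the noise envelope of the clean tone
        assert len(avg) == len(clean)
        resid = avg.samples - clean.samples
        assert np.std(resid) == pytest.approx(0.01 / np.sqrt(15), rel=0.2)

    def test_snr_improves_like_sqrt_15(self):
        clean = tone_trace()
        gains = []
        for trial in range(10):
            rng = np.random.default_rng(trial)
            traces = [Waveform(clean.samples + rng.normal(0, 0.05, len(clean)), VIBRO)
                      for _ in range(20)]
            avg = filter_and_average(ReplicateSet(STIM, tuple(traces)))
            noise_single = np.std(traces[0].samples[25000:])
            noise_avg = np.std(avg.samples[25000:])
            gains.append(noise_single / noise_avg)
        assert np.mean(gains) == pytest.approx(np.sqrt(15), rel=0.15)

    def test_ties_broken_by_replicate_order(self):
        clean = tone_trace()
        traces = tuple(clean.scaled(1.0) for _ in range(8))  # all-equal SNR
        a = filter_and_average(ReplicateSet(STIM, traces))
        b = filter_and_average(ReplicateSet(STIM, traces))
        assert np.array_equal(a.samples, b.samples)

    def test_fewer_than_four_rejected(self):
        reps = ReplicateSet(STIM, tuple(tone_trace(seed=s, noise_sd=1e-3) for s in range(3)))
        with pytest.raises(ValueError):
            filter_and_average(reps)


class TestVelocityAtFrequency:
    def test_known_velocity_recovered_within_2pct(self):
        v_true = 2.3e-4  # m/s
        amp = v_true / TRACE_UNIT_M_S
        tr = tone_trace(freq=4000.0, amp=amp)
        v = velocity_at_frequency(tr, 4000.0)
        assert v == pytest.approx(v_true, rel=0.02)

    def test_off_grid_frequency_recovered(self):
        # 4300 Hz falls between 24.41 Hz bins; flat-top readout must hold
        tr = tone_trace(freq=4300.0, amp=1.0)
        v = velocity_at_frequency(tr, 4300.0)
        assert v == pytest.approx(TRACE_UNIT_M_S, rel=0.02)

    def test_zero_trace_gives_zero(self):
        assert velocity_at_frequency(Waveform(np.zeros(40000), VIBRO), 4000.0) == 0.0

    def test_linearity_in_amplitude(self):
        tr = tone_trace()
        v1 = velocity_at_frequency(tr, 4000.0)
        v2 = velocity_at_frequency(tr.scaled(2.0), 4000.0)
        assert v2 == pytest.approx(2 * v1, rel=1e-9)

    def test_grid_resolutions_match_acquisition(self):
        assert tone_grid_resolution_hz() == pytest.approx(24.41, abs=0.005)
        assert call_grid_resolution_hz() == pytest.approx(97.66, abs=0.005)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            velocity_at_frequency(tone_trace(), 150000.0)


class TestBuildTransferFunction:
    def test_schedule_sized_tf(self):
        from tympanomatch import make_tone_schedule

        sched = make_tone_schedule([80.0])
        responses = [(s, tone_trace(freq=s.frequency_hz, amp=1.0)) for s in sched]
        tf = build_transfer_function(responses)
        assert tf.frequencies.size == 78
        assert np.all(np.diff(tf.frequencies) > 0)

    def test_flat_input_gives_flat_tf(self):
        freqs = [1000.0, 2000.0, 3000.0, 4000.0]
        responses = [(ToneStimulus(f, 80.0), tone_trace(freq=f, amp=1.0)) for f in freqs]
        tf = build_transfer_function(responses)
        assert np.ptp(tf.velocity) / tf.velocity.mean() < 0.01

    def test_duplicate_frequency_rejected(self):
        resp = [(ToneStimulus(1000.0, 80.0), tone_trace(freq=1000.0))] * 2
        with pytest.raises(ValueError, match="duplicate"):
            build_transfer_function(resp)

    def test_mixed_spl_rejected(self):
        resp = [
            (ToneStimulus(1000.0, 80.0), tone_trace(freq=1000.0)),
            (ToneStimulus(2000.0, 70.0), tone_trace(freq=2000.0)),
        ]
        with pytest.raises(ValueError, match="SPL"):
            build_transfer_function(resp)


class TestSummarizeTF:
    def triangle(self, scale=1.0):
        f = np.array([3000.0, 4500.0, 6000.0, 7000.0, 8000.0])
        v = np.array([0.25, 0.5, 1.0, 0.5, 0.25]) * scale
        return TransferFunction(80.0, f, v)

    def test_triangular_tf_summary(self):
        s = summarize_tf(self.triangle())
        assert s.best_frequency_hz == 6000.0
        assert s.lower_limit_hz == pytest.approx(4500.0)
        assert s.upper_limit_hz == pytest.approx(7000.0)
        assert s.range_hz == pytest.approx(2500.0)
        assert not s.edge_clamped

    def test_db_reference_1um_s(self):
        tf = TransferFunction(80.0, np.array([1000.0, 2000.0, 3000.0]),
                              np.array([0.5e-6, 1e-6, 0.2e-6]))
        assert summarize_tf(tf).velocity_db == pytest.approx(0.0, abs=1e-9)

    def test_1mm_s_is_60db(self):
        tf = TransferFunction(80.0, np.array([1000.0, 2000.0, 3000.0]),
                              np.array([0.4e-3, 1e-3, 0.3e-3]))
        assert summarize_tf(tf).velocity_db == pytest.approx(60.0, abs=1e-9)

    @given(st.floats(min_value=1e-4, max_value=1e4))
    def test_scale_invariance_of_frequencies(self, scale):
        base = summarize_tf(self.triangle())
        scaled = summarize_tf(self.triangle(scale))
        assert scaled.best_frequency_hz == base.best_frequency_hz
        assert scaled.lower_limit_hz == pytest.approx(base.lower_limit_hz)
        assert scaled.upper_limit_hz == pytest.approx(base.upper_limit_hz)
        assert scaled.max_velocity == pytest.approx(base.max_velocity * scale, rel=1e-9)

    def test_edge_clamp_flagged(self):
        tf = TransferFunction(80.0, np.array([1000.0, 2000.0, 3000.0]),
                              np.array([0.9, 1.0, 0.9]))
        s = summarize_tf(tf)
        assert s.edge_clamped
        assert s.lower_limit_hz == 1000.0
        assert s.upper_limit_hz == 3000.0

    def test_ties_resolve_to_lowest_frequency(self):
        tf = TransferFunction(80.0, np.array([1000.0, 2000.0, 3000.0, 4000.0]),
                              np.array([0.1, 1.0, 1.0, 0.1]))
        assert summarize_tf(tf).best_frequency_hz == 2000.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            summarize_tf(TransferFunction(80.0, np.array([1.0, 2.0, 3.0]), np.zeros(3)))
        with pytest.raises(ValueError):
            summarize_tf(TransferFunction(80.0, np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestCallResponseSpectrum:
    def test_resonator_response_peaks_at_center(self, southern_call):
        model = EardrumModel(center_frequency_hz=6300.0, noise_sd=0.02)
        reps = simulate_call_response(model, southern_call, 80.0, n_reps=8, seed=4)
        spec = call_response_spectrum(reps)
        peak = spec.frequencies[np.argmax(spec.magnitude)]
        assert abs(peak - 6300.0) <= spec.resolution_hz

    def test_silence_gives_near_zero_flat_spectrum(self):
        traces = tuple(
            Waveform(np.random.default_rng(s).normal(0, 1e-6, 8192), VIBRO) for s in range(8)
        )
        spec = call_response_spectrum(ReplicateSet("silence", traces))
        assert spec.magnitude.max() < 1e-8  # trace units ~1e-6 -> velocity ~5e-10 m/s
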