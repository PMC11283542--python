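"""Strike segmentation: constructed waveforms and simulator-oracle checks."""

import numpy as np
import pytest

from qdg.segmentation import (
    SegmentationParams,
    cycle_isis,
    segment_strikes,
    strikes_to_frame,
)
from qdg.simulate import phenotype_profile, simulate_trace
from qdg.trace import RaftTrace

RATE = 200.0  # round sample rate keeps constructed waveforms exact


def trace_from_channel(x, rate=RATE):
    t = np.arange(len(x)) / rate
    return RaftTrace(
        sample_rate=rate, timestamps=t, channel_a=np.asarray(x, float),
        channel_b=np.zeros(len(x)), duration=len(x) / rate,
    )


def triangular_press(rise=0.1, hold=0.05, fall=0.1, amp=8.0, rate=RATE,
                     pad=1.0):
    n_pad = int(pad * rate)
    up = np.linspace(0, amp, int(rise * rate), endpoint=False)
    top = np.full(int(hold * rate), amp)
    down = np.linspace(amp, 0, int(fall * rate), endpoint=False)
    return np.concatenate(
        [np.zeros(n_pad), up, top, down, np.zeros(n_pad)]
    )


class TestConstructedWaveforms:
    def test_single_triangular_press(self):
        trace = trace_from_channel(triangular_press())
        seg = segment_strikes(trace)
        strikes = seg.strikes["index"]
        assert len(strikes) == 1
        s = strikes[0]
        dt = 1.0 / RATE
        assert s.press_amplitude == pytest.approx(8.0, abs=0.05)
        assert s.dwell_time == pytest.approx(0.05, abs=2 * dt)
        assert s.press_duration == pytest.approx(0.1, abs=2 * dt)
        assert s.press_speed == pytest.approx(80.0, rel=0.05)
        assert seg.strikes["middle"] == []

    def test_sub_threshold_wiggle_yields_no_strike(self):
        trace = trace_from_channel(triangular_press(amp=0.3))
        seg = segment_strikes(trace)
        assert seg.strikes["index"] == []

    def test_small_strike_diverted_to_debug_list(self):
        # above onset threshold but below min_strike_amplitude
        trace = trace_from_channel(triangular_press(amp=0.8))
        params = SegmentationParams(min_strike_amplitude=1.0)
        seg = segment_strikes(trace, params)
        assert seg.strikes["index"] == []
        assert len(seg.discarded["index"]) == 1

    def test_flat_trace_returns_empty(self):
        trace = trace_from_channel(np.zeros(int(30 * RATE)))
        seg = segment_strikes(trace)
        assert seg.strikes == {"index": [], "middle": []}

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(onset_threshold=0.7)
        with pytest.raises(ValueError):
            SegmentationParams(dwell_epsilon_frac=0.0)

    def test_press_speed_consistent_with_definition(self):
        trace = trace_from_channel(triangular_press())
        (s,) = segment_strikes(trace).strikes["index"]
        assert s.press_speed == s.press_amplitude / s.press_duration
        assert s.release_slope == s.release_amplitude / s.release_duration


class TestCycleIsis:
    def test_direct_onsets(self):
        press = triangular_press(pad=0.0, rise=0.08, hold=0.04, fall=0.08)
        x = np.zeros(500)
        for i in range(3):
            start = 100 + int(i * 0.4 * RATE)
            x[start:start + len(press)] = press
        strikes = segment_strikes(trace_from_channel(x)).strikes["index"]
        assert len(strikes) == 3
        isis = cycle_isis(strikes)
        np.testing.assert_allclose(isis, [0.4, 0.4], atol=1.5 / RATE)

    def test_single_strike_empty_series(self):
        strikes = segment_strikes(
            trace_from_channel(triangular_press())
        ).strikes["index"]
        assert cycle_isis(strikes).size == 0

    def test_metronomic_simulator_isis(self):
        profile = phenotype_profile(
            "healthy", seed=1, isi_jitter_cv=0.0, noise_sd=0.0,
            press_depth_sd=0.0,
        )
        trace, _ = simulate_trace(profile)
        seg = segment_strikes(trace)
        for finger in ("index", "middle"):
            isis = cycle_isis(seg.strikes[finger])
            np.testing.assert_allclose(
                isis, 0.4, atol=1.0 / profile.sample_rate
            )


class TestSimulatorOracle:
    @pytest.mark.parametrize(
        "phenotype,seed",
        [
            ("healthy", 11),
            ("healthy", 12),
            ("bradykinetic", 13),
            ("tremor_dominant", 14),
            ("mixed", 15),
        ],
    )
    def test_oracle_equivalence_noise_free(self, phenotype, seed):
        """Counts, amplitudes and onsets match ground truth without noise."""
        profile = phenotype_profile(phenotype, seed=seed, noise_sd=0.0)
        trace, gt = simulate_trace(profile)
        seg = segment_strikes(trace)
        truth = gt.per_finger()
        dt = 1.0 / profile.sample_rate
        for finger, expected in truth.items():
            detected = seg.strikes[finger]
            assert len(detected) == len(expected)
            for d, e in zip(detected, expected):
                assert d.press_amplitude == pytest.approx(
                    e.amplitude, abs=0.05
                )
                assert d.onset_t == pytest.approx(e.onset, abs=1.01 * dt)

    def test_exact_count_on_healthy_profile(self):
        profile = phenotype_profile(
            "healthy", seed=2, noise_sd=0.0, isi_jitter_cv=0.0
        )
        trace, gt = simulate_trace(profile)
        seg = segment_strikes(trace)
        for finger, expected in gt.per_finger().items():
            assert len(seg.strikes[finger]) == len(expected)

    def test_hysteresis_noise_immunity(self):
        """Bounded noise below half the onset threshold keeps strike counts."""
        profile = phenotype_profile("healthy", seed=3, noise_sd=0.0)
        trace, _ = simulate_trace(profile)
        clean_counts = {
            f: len(s) for f, s in segment_strikes(trace).strikes.items()
        }
        rng = np.random.default_rng(0)
        params = SegmentationParams()
        noise_amp = params.onset_mm / 2 * 0.9
        noisy = RaftTrace(
            sample_rate=trace.sample_rate,
            timestamps=trace.timestamps,
            channel_a=np.clip(
                trace.channel_a
                + rng.uniform(-noise_amp, noise_amp, trace.n_samples),
                0, trace.device_max,
            ),
            channel_b=np.clip(
                trace.channel_b
                + rng.uniform(-noise_amp, noise_amp, trace.n_samples),
                0, trace.device_max,
            ),
            duration=trace.duration,
        )
        noisy_counts = {
            f: len(s) for f, s in segment_strikes(noisy).strikes.items()
        }
        assert noisy_counts == clean_counts

    def test_sample_rate_doubling(self):
        """Doubling the grid leaves amplitudes unchanged, durations close."""
        base = phenotype_profile(
            "healthy", seed=4, noise_sd=0.0, isi_jitter_cv=0.0,
            press_depth_sd=0.0,
        )
        lo, _ = simulate_trace(base)
        hi, _ = simulate_trace(
            phenotype_profile(
                "healthy", seed=4, noise_sd=0.0, isi_jitter_cv=0.0,
                press_depth_sd=0.0, sample_rate=2 * base.sample_rate,
            )
        )
        s_lo = segment_strikes(lo).strikes["index"]
        s_hi = segment_strikes(hi).strikes["index"]
        assert len(s_lo) == len(s_hi)
        # duration quantisation is set by the coarser grid on both
        # the onset back-projection and the dwell entry
        dt_lo = 1.0 / base.sample_rate
        for a, b in zip(s_lo, s_hi):
            assert b.press_amplitude == pytest.approx(
                a.press_amplitude, abs=0.02
            )
            assert abs(b.press_duration - a.press_duration) <= 2 * dt_lo

    def test_strike_table_export_columns(self, scored_trial):
        _, _, seg, _ = scored_trial
        df = strikes_to_frame(seg)
        assert list(df.columns[:3]) == ["finger", "channel", "onset_t"]
        assert df["onset_t"].is_monotonic_increasing
        assert (df["press_amplitude"] > 0).all()
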