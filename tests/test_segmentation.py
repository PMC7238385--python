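import numpy as np
import pytest

from pcgdx import (
    CycleAnnotation,
    Envelope,
    HeartSoundInstant,
    PCGSignal,
    SegmentationError,
    SynthConfig,
    compute_envelope,
    decompose_bands,
    detect_instants,
    estimate_heart_rate,
    label_s1_s2,
    locate_durations,
    preprocess,
    recombine_hadamard,
    segment_pcg,
    synthesize_pcg,
)


def _band_energy(x, lo, hi, rate=2000.0):
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1 / rate)
    return spec[(freqs >= lo) & (freqs <= hi)].sum()


class TestDecomposeBands:
    def test_dc_signal_lands_in_approximation(self):
        sig = PCGSignal(np.ones(4096), 2000.0)
        bands = decompose_bands(sig)
        detail_energy = sum(np.sum(d**2) for d in bands.details)
        assert detail_energy < 1e-12 * np.sum(bands.approximations[-1] ** 2)

    def test_band_sum_reconstructs_input(self, rng):
        x = rng.standard_normal(4096)
        bands = decompose_bands(PCGSignal(x, 2000.0))
        total = bands.approximations[-1] + sum(bands.details)
        assert np.max(np.abs(total - x)) < 1e-8 * max(1.0, np.max(np.abs(x)))

    def test_mid_band_burst_dominates_d4(self):
        # 62.5-125 Hz is the fourth detail band at 2 kHz
        rate, n = 2000.0, 4096
        t = np.arange(n) / rate
        burst = np.exp(-0.5 * ((t - 1.0) / 0.1) ** 2) * np.cos(2 * np.pi * 90 * t)
        bands = decompose_bands(PCGSignal(burst, rate))
        energies = [np.sum(d**2) for d in bands.details]
        assert np.argmax(energies) == 3  # D4

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            decompose_bands(PCGSignal(np.ones(100), 2000.0))


class TestRecombineHadamard:
    def test_elementwise_product(self):
        out = recombine_hadamard(np.array([1.0, 2.0, -1.0]), np.array([3.0, -1.0, 2.0]))
        np.testing.assert_allclose(out, [3.0, -2.0, -2.0])

    def test_zero_band_annihilates(self, rng):
        d4 = rng.standard_normal(100)
        np.testing.assert_allclose(recombine_hadamard(d4, np.zeros(100)), 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            recombine_hadamard(np.ones(10), np.ones(11))

    def test_product_requires_joint_band_activity(self):
        # a burst confined to D4's band alone leaves the product near zero
        rate, n = 2000.0, 8192
        t = np.arange(n) / rate
        d4_only = np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2) * np.cos(2 * np.pi * 100 * t)
        sig = PCGSignal(d4_only + 1e-6, rate)
        bands = decompose_bands(sig)
        product = recombine_hadamard(bands.d4, bands.d5)
        window = (t > 0.85) & (t < 1.15)
        assert np.sum(product[window] ** 2) < 0.01 * np.sum(bands.d4[window] ** 2)


class TestEnvelope:
    def test_shannon_energy_closed_forms(self):
        # frame of ones -> log 1 = 0; frame at s^2 = 1/e -> energy 1/e;
        # all-zero frame -> 0 by the 0 log 0 convention
        x = np.concatenate(
            [np.ones(40), np.full(40, np.exp(-0.5)), np.zeros(40)]
        )
        env = compute_envelope(x, 2000.0)
        starts = {0: 0.0, 2: np.exp(-1.0), 4: 0.0}  # frame index -> energy
        for idx, expected in starts.items():
            assert env.raw[idx] == pytest.approx(expected, abs=1e-12)

    def test_z_score_normalization(self, rng):
        x = rng.standard_normal(8000)
        env = compute_envelope(x, 2000.0)
        assert abs(env.values.mean()) < 1e-9
        assert abs(env.values.std() - 1.0) < 1e-9

    def test_frame_geometry(self, rng):
        env = compute_envelope(rng.standard_normal(2000), 2000.0)
        assert env.frame_times[1] - env.frame_times[0] == pytest.approx(0.010)
        assert env.frame_len == pytest.approx(0.020)

    def test_short_signal_rejected(self):
        with pytest.raises(SegmentationError, match="frame"):
            compute_envelope(np.ones(10), 2000.0)


def _envelope_with_peaks(peak_times, magnitudes, duration=3.0, width=0.03):
    times = np.arange(0.0, duration, 0.010)
    raw = np.zeros_like(times)
    for t0, mag in zip(peak_times, magnitudes):
        raw += mag * np.exp(-0.5 * ((times - t0) / width) ** 2)
    return Envelope(values=raw, raw=raw + 1e-6, frame_times=times,
                    frame_len=0.020, hop=0.010)


class TestDetectInstants:
    def test_one_instant_per_isolated_burst(self):
        peaks = [0.4, 0.8, 1.2, 1.6, 2.0]
        env = _envelope_with_peaks(peaks, [1.0] * 5)
        instants, flags = detect_instants(env)
        assert len(instants) == 5
        for found, expected in zip(instants, peaks):
            assert found.time == pytest.approx(expected, abs=0.011)

    def test_local_max_constraint_keeps_dominant_peak(self):
        # two peaks 60 ms apart: only the larger survives the 100 ms rule
        env = _envelope_with_peaks([0.5, 0.56, 1.0, 1.5], [1.0, 0.8, 1.0, 1.0],
                                   width=0.012)
        instants, _ = detect_instants(env)
        times = [i.time for i in instants]
        assert any(abs(t - 0.5) < 0.015 for t in times)
        assert not any(abs(t - 0.56) < 0.015 for t in times)

    def test_adjacency_rule_drops_lower_magnitude(self):
        # peaks 120 ms apart both clear the local-max rule; the 180 ms
        # adjacency rule then removes the weaker one
        env = _envelope_with_peaks([0.5, 0.62, 1.1, 1.6], [1.0, 0.7, 1.0, 1.0],
                                   width=0.012)
        instants, _ = detect_instants(env)
        times = [i.time for i in instants]
        assert any(abs(t - 0.5) < 0.015 for t in times)
        assert not any(abs(t - 0.62) < 0.015 for t in times)

    def test_long_gaps_flagged_not_dropped(self):
        env = _envelope_with_peaks([0.3, 0.9, 1.8], [1.0, 1.0, 1.0])
        instants, flags = detect_instants(env)
        assert len(instants) == 3
        assert len(flags) == 2  # both gaps exceed 500 ms

    def test_fewer_than_three_instants_rejected(self):
        env = _envelope_with_peaks([0.5, 1.0], [1.0, 1.0])
        with pytest.raises(SegmentationError, match="insufficient beats"):
            detect_instants(env)

    def test_accepted_instants_respect_minimum_gap(self, rng):
        sig, _ = synthesize_pcg(SynthConfig(heart_rate=143.0, seed=3))
        seg = segment_pcg(preprocess(sig))
        gaps = np.diff([i.time for i in seg.instants])
        assert np.all(gaps >= 0.180)


class TestHeartRate:
    def test_hand_worked_spans(self):
        assert estimate_heart_rate([0.0, 0.3, 0.8, 1.1, 1.6]) == pytest.approx(75.0)
        assert estimate_heart_rate([0.0, 0.25, 0.5, 0.75]) == pytest.approx(120.0)

    def test_two_instants_rejected(self):
        with pytest.raises(ValueError):
            estimate_heart_rate([0.0, 0.8])

    @pytest.mark.parametrize("true_hr", [60.0, 100.0, 143.0])
    def test_recovered_rate_within_two_bpm(self, true_hr):
        sig, truth = synthesize_pcg(SynthConfig(heart_rate=true_hr, seed=2))
        seg = segment_pcg(preprocess(sig))
        assert abs(seg.heart_rate - truth.heart_rate) <= 2.0


def _instants(times):
    return [HeartSoundInstant(t, 1.0) for t in times]


class TestLabeling:
    def test_low_rate_short_gap_is_systole(self):
        labeled = label_s1_s2(_instants([0.0, 0.3, 0.8, 1.1, 1.6]), 75.0)
        assert [i.label for i in labeled] == ["S1", "S2", "S1", "S2", "S1"]

    def test_high_rate_short_gap_is_diastole(self):
        labeled = label_s1_s2(_instants([0.0, 0.2, 0.43, 0.63, 0.86]), 140.0)
        assert labeled[0].label == "S2"
        assert [i.label for i in labeled] == ["S2", "S1", "S2", "S1", "S2"]

    def test_cutoff_rate_uses_low_rate_branch(self):
        labeled = label_s1_s2(_instants([0.0, 0.3, 0.8, 1.1, 1.6]), 130.0)
        assert labeled[0].label == "S1"

    def test_equal_gaps_ambiguous(self):
        with pytest.raises(SegmentationError, match="ambiguous"):
            label_s1_s2(_instants([0.0, 0.4, 0.8, 1.2]), 75.0)

    def test_time_reversal_swaps_labels(self):
        # mirroring the instant sequence turns every systolic gap into a
        # diastolic one, so the alternating labels must swap consistently
        times = [0.0, 0.3, 0.8, 1.1, 1.6]
        fwd = label_s1_s2(_instants(times), 75.0)
        mirrored = sorted(times[-1] - t for t in times)
        rev = label_s1_s2(_instants(mirrored), 75.0)
        fwd_by_time = {round(t, 6): i.label for t, i in zip(times, fwd)}
        for t, inst in zip(mirrored, rev):
            original = fwd_by_time[round(times[-1] - t, 6)]
            assert inst.label != original


class TestDurations:
    def _triangle_env(self, peak_times, duration=2.0):
        times = np.arange(0.0, duration, 0.010)
        raw = np.full_like(times, 0.01)
        for t0 in peak_times:
            tri = 1.0 - np.abs(times - t0) / 0.025
            raw = np.maximum(raw, np.where(np.abs(times - t0) <= 0.025, tri, 0.01))
        return Envelope(values=raw, raw=raw, frame_times=times,
                        frame_len=0.020, hop=0.010)

    def test_triangular_peak_boundaries_at_ten_percent(self):
        # raw envelope falls below 10% of the peak 30 ms out on each side
        env = self._triangle_env([0.5, 0.8, 1.3])
        labeled = [
            HeartSoundInstant(0.5, 1.0, "S1"),
            HeartSoundInstant(0.8, 1.0, "S2"),
            HeartSoundInstant(1.3, 1.0, "S1"),
        ]
        cycles = locate_durations(env, labeled, 75.0)
        assert len(cycles) == 1
        cyc = cycles[0]
        assert cyc.s1_interval == pytest.approx((0.47, 0.53), abs=1e-6)
        assert cyc.s2_interval == pytest.approx((0.77, 0.83), abs=1e-6)
        assert cyc.cav_interval == pytest.approx((0.53, 0.77), abs=1e-6)
        assert cyc.csv_interval == pytest.approx((0.83, 1.27), abs=1e-6)
        assert not cyc.clamped

    def test_no_crossing_clamps_to_window_and_flags(self):
        times = np.arange(0.0, 2.0, 0.010)
        raw = np.ones_like(times)  # never below 10% of any peak
        env = Envelope(values=raw, raw=raw, frame_times=times,
                       frame_len=0.020, hop=0.010)
        labeled = [
            HeartSoundInstant(0.5, 1.0, "S1"),
            HeartSoundInstant(0.8, 1.0, "S2"),
            HeartSoundInstant(1.3, 1.0, "S1"),
        ]
        cycles = locate_durations(env, labeled, 75.0)
        assert len(cycles) == 1
        cyc = cycles[0]
        assert cyc.clamped
        s1_len = cyc.s1_interval[1] - cyc.s1_interval[0]
        s2_len = cyc.s2_interval[1] - cyc.s2_interval[0]
        assert s1_len == pytest.approx(0.120, abs=0.011)
        assert s2_len == pytest.approx(0.100, abs=0.011)

    def test_cycle_interval_arithmetic(self):
        cyc = CycleAnnotation(
            s1_interval=(0.05, 0.10), s2_interval=(0.28, 0.35),
            cav_interval=(0.10, 0.28), csv_interval=(0.35, 0.80),
            heart_rate=75.0,
        )
        assert cyc.cav_interval == (0.10, 0.28)
        assert cyc.csv_interval == (0.35, 0.80)

    def test_cycle_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            CycleAnnotation(
                s1_interval=(0.05, 0.30), s2_interval=(0.28, 0.35),
                cav_interval=(0.10, 0.28), csv_interval=(0.35, 0.80),
                heart_rate=75.0,
            )


class TestSegmentPcg:
    @pytest.mark.parametrize("murmur_level", [0.0, 1.0])
    def test_instant_recovery_with_and_without_murmur(self, murmur_level):
        # murmur amplitude equal to S1 exercises the Hadamard suppression
        sig, truth = synthesize_pcg(
            SynthConfig(heart_rate=90.0, murmur_level=murmur_level, seed=1)
        )
        seg = segment_pcg(preprocess(sig))
        detected = np.array([i.time for i in seg.instants])
        true_instants = truth.all_instants()
        hits = sum(np.min(np.abs(detected - t)) <= 0.020 for t in true_instants)
        assert hits / true_instants.size >= 0.95

    def test_single_beat_recording_rejected(self):
        rate = 2000.0
        t = np.arange(int(rate)) / rate
        burst = np.exp(-0.5 * ((t - 0.5) / 0.02) ** 2) * np.cos(2 * np.pi * 80 * t)
        x = burst + 0.001 * np.sin(2 * np.pi * 3 * t)
        with pytest.raises(SegmentationError, match="insufficient beats"):
            segment_pcg(PCGSignal(x / np.max(np.abs(x)), rate))

    def test_stage_name_attached_to_errors(self):
        with pytest.raises(SegmentationError, match=r"\[decompose\]"):
            segment_pcg(PCGSignal(np.ones(100), 2000.0))
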