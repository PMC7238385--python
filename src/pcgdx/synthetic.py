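"""Synthetic phonocardiograms with ground truth for every pipeline stage.

Real pediatric auscultation recordings are not publicly available, so this
module generates signals with the same gross morphology: quasi-periodic S1
and S2 tone bursts at a configurable heart rate, an optional systolic
murmur (band-limited noise confined to the CAV interval), and additive
broadband noise at a requested SNR. Each recording carries exact ground
truth — instants, boundaries, closed-valve intervals, heart rate, class
label — so segmentation and classification can be scored objectively.

What it emulates: cycle geometry (systole shorter than diastole below
130 bpm and longer above), low-frequency S1/S2 bursts, graded systolic
murmur energy, beat-to-beat variability. What it does not: valve mechanics,
S3/S4, respiration, crying or motion artifacts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal import CANONICAL_RATE, PCGSignal, write_wav

SYSTOLE_FRACTION_LOW_HR = 0.38   # heart rate <= 130 bpm
SYSTOLE_FRACTION_HIGH_HR = 0.55  # heart rate > 130 bpm
HR_CUTOFF = 130.0
S2_RELATIVE_AMPLITUDE = 0.8
CYCLE_JITTER = 0.02  # +/-2% beat-to-beat variation
MURMUR_RAMP = 0.010  # s, raised-cosine edges on the murmur window


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the nominal study conditions."""

    heart_rate: float = 90.0
    duration: float = 20.0
    s1_freq: float = 80.0
    s2_freq: float = 120.0
    s1_dur: float = 0.100
    s2_dur: float = 0.080
    systole_fraction: float | None = None  # None: rate-dependent default
    murmur_level: float = 0.0
    murmur_band: tuple[float, float] = (100.0, 600.0)
    noise_snr: float = 20.0
    seed: int = 0
    rate: float = CANONICAL_RATE

    def __post_init__(self) -> None:
        if not 40.0 <= self.heart_rate <= 220.0:
            raise ValueError("heart_rate must be within 40-220 bpm")
        if self.duration <= 0 or self.s1_dur <= 0 or self.s2_dur <= 0:
            raise ValueError("durations must be positive")
        if not 0.0 <= self.murmur_level <= 1.5:
            raise ValueError("murmur_level must be within [0, 1.5]")

    @property
    def resolved_systole_fraction(self) -> float:
        if self.systole_fraction is not None:
            return self.systole_fraction
        return (
            SYSTOLE_FRACTION_LOW_HR
            if self.heart_rate <= HR_CUTOFF
            else SYSTOLE_FRACTION_HIGH_HR
        )


@dataclass
class GroundTruth:
    """Exact annotations for one synthetic recording."""

    s1_instants: np.ndarray
    s2_instants: np.ndarray
    s1_intervals: list[tuple[float, float]]
    s2_intervals: list[tuple[float, float]]
    cav_intervals: list[tuple[float, float]]
    csv_intervals: list[tuple[float, float]]
    heart_rate: float
    label: int
    murmur_level: float

    def all_instants(self) -> np.ndarray:
        """S1 and S2 instants interleaved in time order."""
        return np.sort(np.concatenate([self.s1_instants, self.s2_instants]))


def _tone_burst(
    t: np.ndarray, center: float, freq: float, dur: float, amplitude: float
) -> np.ndarray:
    """Gaussian-windowed heart-sound burst centered at *freq*.

    Valve-closure sounds are broadband transients, not pure tones: their
    spectra extend an octave below the dominant component. The burst is
    therefore a two-component amplitude-modulated tone — the center
    frequency plus a half-frequency component at 80% amplitude — under one
    Gaussian window. Cosine phase makes the burst even-symmetric about its
    center, so the labeled instant coincides with the magnitude maximum
    that defines an S1/S2 instant.
    """
    envelope = np.exp(-0.5 * ((t - center) / (dur / 6.0)) ** 2)
    envelope[np.abs(t - center) > dur / 2.0] = 0.0
    tone = np.cos(2.0 * np.pi * freq * (t - center)) + 0.8 * np.cos(
        2.0 * np.pi * 0.5 * freq * (t - center)
    )
    return amplitude * envelope * tone


def _interval_window(
    t: np.ndarray, start: float, end: float, ramp: float
) -> np.ndarray:
    """Unit window over [start, end] with raised-cosine edges of width *ramp*."""
    w = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    w[inside] = 1.0
    if ramp > 0:
        left = inside & (t < start + ramp)
        right = inside & (t > end - ramp)
        w[left] = 0.5 * (1 - np.cos(np.pi * (t[left] - start) / ramp))
        w[right] = 0.5 * (1 - np.cos(np.pi * (end - t[right]) / ramp))
    return w


def synthesize_pcg(config: SynthConfig | None = None) -> tuple[PCGSignal, GroundTruth]:
    """Generate one recording and its exact ground truth.

    Cycles are laid out left to right with +/-2% seeded length jitter; only
    cycles that fit completely in the record are emitted. A cycle starts at
    the S1 onset; the S2 onset sits one systole fraction of the cycle later
    (systole and diastole are start-to-start durations), and each instant is
    its sound's center; the murmur (if any) is Gaussian noise
    band-passed to the murmur band and windowed to the CAV interval, scaled
    so its peak equals ``murmur_level`` times the S1 peak.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    rate = config.rate
    n = int(round(config.duration * rate))
    t = np.arange(n) / rate
    nominal_cycle = 60.0 / config.heart_rate
    sys_frac = config.resolved_systole_fraction
    if sys_frac * nominal_cycle <= config.s1_dur:
        raise ValueError(
            "cycle geometry impossible: systole (start-to-start) shorter "
            "than the S1 duration"
        )
    if (1.0 - sys_frac) * nominal_cycle <= config.s2_dur:
        raise ValueError(
            "cycle geometry impossible: diastole shorter than the S2 duration"
        )

    signal = np.zeros(n)
    truth = GroundTruth(
        s1_instants=np.empty(0), s2_instants=np.empty(0),
        s1_intervals=[], s2_intervals=[], cav_intervals=[], csv_intervals=[],
        heart_rate=config.heart_rate,
        label=int(config.murmur_level > 0),
        murmur_level=config.murmur_level,
    )
    s1_times: list[float] = []
    s2_times: list[float] = []
    cycle_starts: list[float] = []
    cycle_lens: list[float] = []
    t0 = 0.0
    while True:
        cycle = nominal_cycle * (1.0 + CYCLE_JITTER * rng.uniform(-1, 1))
        if t0 + cycle > config.duration:
            break
        # systole is defined start-to-start: S1 start -> S2 start spans
        # sys_frac of the cycle, diastole (S2 start -> next S1 start) the rest
        s1_instant = t0 + config.s1_dur / 2.0
        s2_instant = t0 + sys_frac * cycle + config.s2_dur / 2.0
        signal += _tone_burst(t, s1_instant, config.s1_freq, config.s1_dur, 1.0)
        signal += _tone_burst(
            t, s2_instant, config.s2_freq, config.s2_dur, S2_RELATIVE_AMPLITUDE
        )
        s1_times.append(s1_instant)
        s2_times.append(s2_instant)
        cycle_starts.append(t0)
        cycle_lens.append(cycle)
        t0 += cycle

    if len(s1_times) < 2:
        raise ValueError("duration too short to hold two complete cycles")

    for k in range(len(s1_times)):
        s1s = s1_times[k] - config.s1_dur / 2.0
        s1e = s1_times[k] + config.s1_dur / 2.0
        s2s = s2_times[k] - config.s2_dur / 2.0
        s2e = s2_times[k] + config.s2_dur / 2.0
        truth.s1_intervals.append((s1s, s1e))
        truth.s2_intervals.append((s2s, s2e))
        truth.cav_intervals.append((s1e, s2s))
        if k + 1 < len(s1_times):
            truth.csv_intervals.append(
                (s2e, s1_times[k + 1] - config.s1_dur / 2.0)
            )

    if config.murmur_level > 0:
        noise = rng.standard_normal(n)
        nyq = rate / 2.0
        lo = config.murmur_band[0] / nyq
        hi = min(config.murmur_band[1] / nyq, 0.99)
        sos = butter(4, [lo, hi], btype="bandpass", output="sos")
        murmur = sosfiltfilt(sos, noise)
        window = np.zeros(n)
        for cav in truth.cav_intervals:
            window += _interval_window(t, cav[0], cav[1], MURMUR_RAMP)
        murmur *= np.clip(window, 0.0, 1.0)
        peak = np.max(np.abs(murmur))
        if peak > 0:
            signal += murmur * (config.murmur_level / peak)

    # additive broadband noise at the requested SNR relative to signal RMS
    rms = float(np.sqrt(np.mean(signal**2)))
    noise_std = rms * 10.0 ** (-config.noise_snr / 20.0)
    signal += noise_std * rng.standard_normal(n)

    truth.s1_instants = np.array(s1_times)
    truth.s2_instants = np.array(s2_times)
    truth.heart_rate = 60.0 / float(np.mean(cycle_lens))
    pcg = PCGSignal(signal, rate, subject_id=f"synthetic_seed{config.seed}")
    return pcg, truth


@dataclass
class CohortMember:
    signal: PCGSignal
    truth: GroundTruth
    config: SynthConfig
    filename: str | None = None


@dataclass
class Cohort:
    members: list[CohortMember] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.truth.label for m in self.members])


def synthesize_cohort(
    n_normal: int,
    n_murmur: int,
    murmur_level_range: tuple[float, float] = (0.5, 1.2),
    hr_range: tuple[float, float] = (70.0, 140.0),
    seed: int = 0,
    duration: float = 20.0,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a labeled cohort; optionally write WAVs plus manifests.

    Deterministic for a fixed seed: subject heart rates, murmur levels and
    per-subject generator seeds all derive from one seeded stream. With
    *out_dir* set, 16-bit 2 kHz WAV files are written together with
    ``manifest.csv`` (filename, label, heart_rate, murmur_level) and
    ``ground_truth.csv`` (one row per cycle, interval schema).
    """
    if n_normal < 1 or n_murmur < 1:
        raise ValueError("cohort needs at least one member per class")
    rng = np.random.default_rng(seed)
    cohort = Cohort()
    labels = [0] * n_normal + [1] * n_murmur
    for idx, label in enumerate(labels):
        hr = float(rng.uniform(*hr_range))
        level = float(rng.uniform(*murmur_level_range)) if label else 0.0
        member_seed = int(rng.integers(0, 2**31 - 1))
        config = SynthConfig(
            heart_rate=hr, duration=duration, murmur_level=level,
            seed=member_seed,
        )
        signal, truth = synthesize_pcg(config)
        name = f"subject_{idx:03d}.wav"
        signal = PCGSignal(
            signal.samples / np.max(np.abs(signal.samples)) * 0.95,
            signal.rate, subject_id=f"subject_{idx:03d}",
        )
        cohort.members.append(CohortMember(signal, truth, config, name))
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "heart_rate", "murmur_level"])
        for m in cohort.members:
            write_wav(out_dir / m.filename, m.signal)
            writer.writerow(
                [m.filename, m.truth.label,
                 f"{m.truth.heart_rate:.2f}", f"{m.truth.murmur_level:.3f}"]
            )
    with open(out_dir / "ground_truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["subject_id", "cycle_index", "s1_start", "s1_end",
             "s2_start", "s2_end", "cav_start", "cav_end",
             "csv_start", "csv_end", "heart_rate"]
        )
        for m in cohort.members:
            tr = m.truth
            for k, csv_iv in enumerate(tr.csv_intervals):
                writer.writerow(
                    [m.signal.subject_id, k]
                    + [f"{v:.4f}" for iv in
                       (tr.s1_intervals[k], tr.s2_intervals[k],
                        tr.cav_intervals[k], csv_iv)
                       for v in iv]
                    + [f"{tr.heart_rate:.2f}"]
                )
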