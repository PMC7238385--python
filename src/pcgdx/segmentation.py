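"""Locate S1/S2 heart sounds and the closed-valve intervals of each cycle.

The denoised PCG is decomposed into per-level wavelet band reconstructions;
the Hadamard (element-wise) product of the D4 and D5 detail bands keeps only
components simultaneously active in both low-frequency bands — S1 and S2 —
while suppressing murmurs, whose energy sits higher. The average Shannon
energy of the recombined signal, framed at 20 ms with a 10 ms hop and
z-scored, forms the envelope on which peaks are detected, the heart rate is
estimated, S1/S2 are told apart by the systole/diastole duration rule, and
the sound boundaries are found by a 10% magnitude criterion. The systolic
gap between S1 end and S2 start is the closed-atrioventricular-valve (CAV)
interval; the diastolic gap from S2 end to the next S1 start is the
closed-semilunar-valve (CSV) interval. Systolic murmurs live in CAV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .denoise import check_decomposable
from .signal import PCGSignal


class SegmentationError(RuntimeError):
    """Raised when a stage of the segmentation pipeline cannot proceed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class SegmentationConfig:
    """Constants of the segmentation method.

    Defaults are the published operating point: db6 wavelet, five levels,
    20 ms frames with 10 ms hop (N = 40 samples at 2 kHz), candidate peaks
    must dominate a 100 ms neighbourhood and be at least 180 ms apart
    (500 ms is the expected upper bound between adjacent sounds), the
    systole-shorter-than-diastole rule flips above 130 bpm, boundary search
    windows are 120 ms (S1) and 100 ms (S2) with a 10% magnitude criterion.
    """

    wavelet_name: str = "db6"
    levels: int = 5
    frame_len: float = 0.020
    hop: float = 0.010
    local_max_window: float = 0.100
    min_gap: float = 0.180
    max_gap: float = 0.500
    hr_cutoff: float = 130.0
    s1_window: float = 0.120
    s2_window: float = 0.100
    boundary_fraction: float = 0.10


@dataclass(frozen=True)
class WaveletBands:
    """Per-level band reconstructions, each the length of the input.

    ``approximations[k]`` holds A(k+1), ``details[k]`` holds D(k+1); the
    deepest approximation plus all details sums back to the input signal.
    """

    approximations: tuple[np.ndarray, ...]
    details: tuple[np.ndarray, ...]

    @property
    def d4(self) -> np.ndarray:
        return self.details[3]

    @property
    def d5(self) -> np.ndarray:
        return self.details[4]


@dataclass(frozen=True)
class Envelope:
    """Framed average Shannon energy of the recombined signal.

    ``values`` is the z-scored envelope used for peak picking; ``raw``
    keeps the non-negative pre-normalization Shannon energies used by the
    10% boundary criterion. ``frame_times`` are frame-center timestamps.
    """

    values: np.ndarray
    raw: np.ndarray
    frame_times: np.ndarray
    frame_len: float
    hop: float


@dataclass
class HeartSoundInstant:
    """A detected envelope peak: its time, magnitude, and S1/S2 label."""

    time: float
    magnitude: float
    label: str | None = None  # "S1", "S2", or None while unlabeled


@dataclass(frozen=True)
class CycleAnnotation:
    """One complete cardiac cycle: S1/S2 durations and CAV/CSV intervals."""

    s1_interval: tuple[float, float]
    s2_interval: tuple[float, float]
    cav_interval: tuple[float, float]
    csv_interval: tuple[float, float]
    heart_rate: float
    clamped: bool = False  # a boundary hit its search-window edge

    def __post_init__(self) -> None:
        s1, s2 = self.s1_interval, self.s2_interval
        cav, csv = self.cav_interval, self.csv_interval
        if not (s1[1] <= cav[0] < cav[1] <= s2[0]):
            raise ValueError("CAV must lie between S1 end and S2 start")
        if not (s2[1] <= csv[0] < csv[1]):
            raise ValueError("CSV must start at or after S2 end")


@dataclass
class Segmentation:
    """Full segmentation output: cycles plus intermediate artifacts."""

    cycles: list[CycleAnnotation]
    instants: list[HeartSoundInstant]
    heart_rate: float
    envelope: Envelope
    long_gap_flags: list[tuple[float, float]] = field(default_factory=list)


def decompose_bands(
    signal: PCGSignal, wavelet: str = "db6", levels: int = 5
) -> WaveletBands:
    """Reconstruct each wavelet level as a full-length band signal.

    Detail band D_j is the inverse transform with every coefficient array
    except level j's details zeroed; approximations follow from the
    multiresolution identity A_j = A_{j+1} + D_{j+1}.
    """
    x = signal.samples
    check_decomposable(x.size, wavelet, levels)
    coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=levels)
    details: list[np.ndarray] = [None] * levels  # type: ignore[list-item]
    for j in range(1, levels + 1):
        sel = [np.zeros_like(c) for c in coeffs]
        sel[levels + 1 - j] = coeffs[levels + 1 - j]
        details[j - 1] = pywt.waverec(sel, wavelet, mode="symmetric")[: x.size]
    sel = [np.zeros_like(c) for c in coeffs]
    sel[0] = coeffs[0]
    deepest = pywt.waverec(sel, wavelet, mode="symmetric")[: x.size]
    approximations: list[np.ndarray] = [None] * levels  # type: ignore[list-item]
    approximations[levels - 1] = deepest
    for j in range(levels - 1, 0, -1):
        approximations[j - 1] = approximations[j] + details[j]
    return WaveletBands(tuple(approximations), tuple(details))


def recombine_hadamard(d4: np.ndarray, d5: np.ndarray) -> np.ndarray:
    """Element-wise product of the D4 and D5 detail bands."""
    d4 = np.asarray(d4, dtype=np.float64)
    d5 = np.asarray(d5, dtype=np.float64)
    if d4.shape != d5.shape:
        raise ValueError(f"length mismatch: {d4.shape} vs {d5.shape}")
    return d4 * d5


def compute_envelope(
    recombined: np.ndarray, rate: float, config: SegmentationConfig | None = None
) -> Envelope:
    """Framed average Shannon energy, z-scored across frames.

    The recombined signal is first normalized to +/-1; per 20 ms frame the
    average Shannon energy -(1/N) sum s^2 log s^2 is evaluated with the
    0 log 0 := 0 convention, then the frame series is centered and scaled
    to unit standard deviation.
    """
    config = config or SegmentationConfig()
    s = np.asarray(recombined, dtype=np.float64)
    n_frame = int(round(config.frame_len * rate))
    n_hop = int(round(config.hop * rate))
    if s.size < n_frame:
        raise SegmentationError(
            "envelope", f"signal shorter than one {n_frame}-sample frame"
        )
    peak = np.max(np.abs(s))
    if peak == 0:
        raise SegmentationError("envelope", "all-zero recombined signal")
    s_norm = s / peak
    starts = np.arange(0, s.size - n_frame + 1, n_hop)
    frames = s_norm[starts[:, None] + np.arange(n_frame)]
    sq = frames**2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(sq > 0, sq * np.log(sq), 0.0)
    raw = -terms.mean(axis=1)
    std = raw.std()
    if std == 0:
        raise SegmentationError("envelope", "degenerate (constant) envelope")
    values = (raw - raw.mean()) / std
    times = (starts + (n_frame - 1) / 2.0) / rate
    return Envelope(values, raw, times, config.frame_len, config.hop)


def _local_peaks(values: np.ndarray) -> list[int]:
    # strict rise followed by a fall; plateau peaks take the leftmost sample
    peaks: list[int] = []
    n = values.size
    i = 1
    while i < n:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[j]:
                j += 1
            if j + 1 < n and values[j + 1] < values[j]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return peaks


def _refine_peak_time(
    values: np.ndarray, times: np.ndarray, idx: int
) -> float:
    # parabolic sub-frame interpolation: the envelope is sampled every 10 ms,
    # so the vertex of a least-squares parabola over the peak frame and its
    # two neighbours each side recovers timing lost to frame quantization
    lo = max(idx - 2, 0)
    hi = min(idx + 3, values.size)
    if hi - lo < 3:
        return float(times[idx])
    k = np.arange(lo, hi) - idx
    a, b, _ = np.polyfit(k, values[lo:hi], 2)
    if a >= 0:
        return float(times[idx])
    shift = float(np.clip(-b / (2.0 * a), -1.0, 1.0))
    return float(times[idx] + shift * (times[1] - times[0]))


def detect_instants(
    env: Envelope, config: SegmentationConfig | None = None
) -> tuple[list[HeartSoundInstant], list[tuple[float, float]]]:
    """Peak-pick the envelope and filter candidates by the two constraints.

    Candidates are sign changes of the first difference (+ to -) whose
    z-scored magnitude is positive (heart sounds stand above the record
    mean; the quiet floor sits below it). A
    candidate survives only if it carries the maximal envelope magnitude
    within the 100 ms range centered on it; then, while two adjacent
    survivors are closer than 180 ms, the lower-magnitude one is dropped.
    Adjacent gaps longer than 500 ms are returned as flags (they indicate a
    probable missed sound, but deleting instants cannot repair them).

    Returns the accepted instants in time order and the list of flagged
    long gaps as (t_left, t_right) pairs.
    """
    config = config or SegmentationConfig()
    vals, times = env.values, env.frame_times
    candidates = _local_peaks(vals)
    half = config.local_max_window / 2.0
    kept: list[int] = []
    for idx in candidates:
        in_window = (times >= times[idx] - half) & (times <= times[idx] + half)
        if vals[idx] >= vals[in_window].max():
            kept.append(idx)
    instants = [
        HeartSoundInstant(_refine_peak_time(vals, times, i), float(vals[i]))
        for i in kept
    ]
    # adjacency rule: resolve too-close pairs in favour of the dominant sound
    changed = True
    while changed and len(instants) > 1:
        changed = False
        for k in range(len(instants) - 1):
            if instants[k + 1].time - instants[k].time < config.min_gap:
                drop = k if instants[k].magnitude < instants[k + 1].magnitude else k + 1
                del instants[drop]
                changed = True
                break
    long_gaps = [
        (instants[k].time, instants[k + 1].time)
        for k in range(len(instants) - 1)
        if instants[k + 1].time - instants[k].time > config.max_gap
    ]
    if len(instants) < 3:
        raise SegmentationError(
            "detect", f"insufficient beats: only {len(instants)} instants"
        )
    return instants, long_gaps


def estimate_heart_rate(instant_times: np.ndarray | list[float]) -> float:
    """Heart rate in bpm from alternating S1/S2 instant times.

    With instants alternating S1, S2, S1, ... every two-step span
    ``p[i+2] - p[i]`` covers one full cardiac cycle, so
    HR = 60 / mean(two-step spans).
    """
    p = np.asarray(instant_times, dtype=np.float64)
    if p.size < 3:
        raise ValueError(f"need at least 3 instants, got {p.size}")
    if np.any(np.diff(p) <= 0):
        raise ValueError("instant times must be strictly increasing")
    spans = p[2:] - p[:-2]
    return 60.0 / float(spans.mean())


def label_s1_s2(
    instants: list[HeartSoundInstant],
    heart_rate: float,
    config: SegmentationConfig | None = None,
) -> list[HeartSoundInstant]:
    """Assign S1/S2 labels via the rate-dependent systole/diastole rule.

    In each consecutive triple the shorter of the two gaps is systole
    (S1 -> S2) when the heart rate is at most 130 bpm and diastole
    (S2 -> S1) above, which labels all three instants of the triple. Each
    instant takes the majority label over the (up to three) triples it
    belongs to, so a single missed sound perturbs labels only locally
    instead of flipping the parity of the whole record. Triples with
    indistinguishable gaps abstain; an instant with tied votes stays
    unlabeled (and is skipped by cycle construction); a record where no
    triple can vote is ambiguous and raises.
    """
    config = config or SegmentationConfig()
    if len(instants) < 3:
        raise ValueError("need at least 3 instants to label")
    times = np.array([inst.time for inst in instants])
    systole_shorter = heart_rate <= config.hr_cutoff
    votes = [{"S1": 0, "S2": 0} for _ in instants]
    for i in range(len(times) - 2):
        g1 = times[i + 1] - times[i]
        g2 = times[i + 2] - times[i + 1]
        if abs(g1 - g2) < 1e-9:  # indistinguishable gaps: abstain
            continue
        first_gap_is_systole = (g1 < g2) == systole_shorter
        pattern = ("S1", "S2", "S1") if first_gap_is_systole else ("S2", "S1", "S2")
        for k, label in zip((i, i + 1, i + 2), pattern):
            votes[k][label] += 1
    if all(v["S1"] == v["S2"] for v in votes):
        raise SegmentationError("label", "ambiguous systole/diastole (tied votes)")
    labeled = []
    for inst, vote in zip(instants, votes):
        if vote["S1"] == vote["S2"]:
            label = None
        else:
            label = "S1" if vote["S1"] > vote["S2"] else "S2"
        labeled.append(HeartSoundInstant(inst.time, inst.magnitude, label))
    return labeled


def _duration_bounds(
    env: Envelope, instant: HeartSoundInstant, window: float, fraction: float
) -> tuple[float, float, bool]:
    """Boundary search on the raw (non-negative) Shannon energy.

    From the instant's frame, scan outward inside the centered window until
    the energy drops below ``fraction`` of the instant's energy; the first
    sub-threshold frame on each side marks the boundary. A side without a
    crossing is clamped to the window edge and flagged.
    """
    times, raw = env.frame_times, env.raw
    center = int(np.argmin(np.abs(times - instant.time)))
    threshold = fraction * raw[center]
    half = window / 2.0
    lo = int(np.searchsorted(times, instant.time - half, side="left"))
    hi = int(np.searchsorted(times, instant.time + half, side="right")) - 1
    start, end = times[lo], times[hi]
    clamped_left = clamped_right = True
    for k in range(center - 1, lo - 1, -1):
        if raw[k] < threshold:
            start, clamped_left = times[k], False
            break
    for k in range(center + 1, hi + 1):
        if raw[k] < threshold:
            end, clamped_right = times[k], False
            break
    return float(start), float(end), clamped_left or clamped_right


def locate_durations(
    env: Envelope,
    labeled: list[HeartSoundInstant],
    heart_rate: float,
    config: SegmentationConfig | None = None,
) -> list[CycleAnnotation]:
    """Derive S1/S2 durations and CAV/CSV intervals for each complete cycle.

    Search windows of 120 ms (S1) and 100 ms (S2) are centered on the
    instants; the boundaries come from the 10% criterion. A cycle runs
    S1 -> S2 -> next S1; edge cycles lacking a flanking instant are
    discarded, as are geometrically inconsistent ones (overlapping
    durations after clamping).
    """
    config = config or SegmentationConfig()
    bounds: dict[int, tuple[float, float, bool]] = {}
    for i, inst in enumerate(labeled):
        window = config.s1_window if inst.label == "S1" else config.s2_window
        bounds[i] = _duration_bounds(env, inst, window, config.boundary_fraction)
    cycles: list[CycleAnnotation] = []
    for i in range(len(labeled) - 2):
        a, b, c = labeled[i], labeled[i + 1], labeled[i + 2]
        if not (a.label == "S1" and b.label == "S2" and c.label == "S1"):
            continue
        s1s, s1e, f1 = bounds[i]
        s2s, s2e, f2 = bounds[i + 1]
        n1s = bounds[i + 2][0]
        if not (s1e < s2s and s2e < n1s):
            warnings.warn(
                f"cycle at t={a.time:.2f}s skipped: overlapping durations",
                stacklevel=2,
            )
            continue
        cycles.append(
            CycleAnnotation(
                s1_interval=(s1s, s1e),
                s2_interval=(s2s, s2e),
                cav_interval=(s1e, s2s),
                csv_interval=(s2e, n1s),
                heart_rate=heart_rate,
                clamped=f1 or f2,
            )
        )
    return cycles


def segment_pcg(
    signal: PCGSignal, config: SegmentationConfig | None = None
) -> Segmentation:
    """Run the full segmentation chain on a denoised, normalized 2 kHz PCG.

    decompose -> Hadamard(D4, D5) -> Shannon envelope -> peak detection ->
    heart rate -> S1/S2 labeling -> duration/interval location. Stage
    failures raise :class:`SegmentationError` naming the stage.
    """
    config = config or SegmentationConfig()
    try:
        bands = decompose_bands(signal, config.wavelet_name, config.levels)
    except ValueError as exc:
        raise SegmentationError("decompose", str(exc)) from exc
    recombined = recombine_hadamard(bands.d4, bands.d5)
    env = compute_envelope(recombined, signal.rate, config)
    instants, long_gaps = detect_instants(env, config)
    try:
        heart_rate = estimate_heart_rate([inst.time for inst in instants])
    except ValueError as exc:
        raise SegmentationError("heart_rate", str(exc)) from exc
    labeled = label_s1_s2(instants, heart_rate, config)
    cycles = locate_durations(env, labeled, heart_rate, config)
    if not cycles:
        raise SegmentationError("durations", "no complete cardiac cycle found")
    return Segmentation(cycles, labeled, heart_rate, env, long_gaps)
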