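"""The 10 time-frequency features of the closed-valve intervals.

Murmurs live between the principal heart sounds, so the feature set looks
only at the CAV (systolic) and CSV (diastolic) intervals of the denoised
PCG. Per cycle: maximum, minimum and mean absolute amplitude of each
interval (six time-domain features) and the maximum and mean of each
interval's Welch power spectral density (four frequency-domain features);
each is averaged over all complete cycles of the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .segmentation import CycleAnnotation
from .signal import PCGSignal

WELCH_SEGMENT = 128  # samples (64 ms at 2 kHz); shorter intervals fall back
                     # to a single full-interval Hanning periodogram

FEATURE_NAMES = (
    "cav_max",
    "cav_min",
    "cav_meanabs",
    "csv_max",
    "csv_min",
    "csv_meanabs",
    "cav_psd_max",
    "cav_psd_mean",
    "csv_psd_max",
    "csv_psd_mean",
)


@dataclass(frozen=True)
class FeatureVector:
    """The 10 features of one recording, cycle-averaged, in fixed order."""

    cav_max: float
    cav_min: float
    cav_meanabs: float
    csv_max: float
    csv_min: float
    csv_meanabs: float
    cav_psd_max: float
    cav_psd_mean: float
    csv_psd_max: float
    csv_psd_mean: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def _interval_samples(
    signal: PCGSignal, interval: tuple[float, float]
) -> np.ndarray:
    lo = int(round(interval[0] * signal.rate))
    hi = int(round(interval[1] * signal.rate))
    return signal.samples[max(lo, 0) : min(hi, signal.samples.size)]


def compute_time_features(
    signal: PCGSignal, annotations: list[CycleAnnotation]
) -> tuple[float, float, float, float, float, float]:
    """Cycle-averaged max, min and mean-absolute amplitude of CAV and CSV."""
    rows = []
    for k, cyc in enumerate(annotations):
        cav = _interval_samples(signal, cyc.cav_interval)
        csv = _interval_samples(signal, cyc.csv_interval)
        if cav.size == 0 or csv.size == 0:
            warnings.warn(f"cycle {k}: empty interval, skipped", stacklevel=2)
            continue
        rows.append(
            (
                cav.max(), cav.min(), np.abs(cav).mean(),
                csv.max(), csv.min(), np.abs(csv).mean(),
            )
        )
    if not rows:
        raise ValueError("no cycle with non-empty CAV and CSV intervals")
    return tuple(np.mean(rows, axis=0))  # type: ignore[return-value]


def compute_welch_psd(
    segment: np.ndarray, rate: float, nperseg: int = WELCH_SEGMENT
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density with a Hanning window and 50% overlap.

    Segments shorter than *nperseg* use a single full-length windowed
    periodogram instead of averaging.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.size < 8:
        raise ValueError(f"segment of {x.size} samples too short for a PSD")
    n = min(nperseg, x.size)
    freqs, psd = welch(x, fs=rate, window="hann", nperseg=n, noverlap=n // 2)
    return freqs, psd


def compute_freq_features(
    signal: PCGSignal, annotations: list[CycleAnnotation]
) -> tuple[float, float, float, float]:
    """Cycle-averaged maximum and mean of the CAV and CSV Welch PSDs.

    The PSD statistics are taken per cycle over the full band up to
    Nyquist, then averaged across cycles.
    """
    rows = []
    for k, cyc in enumerate(annotations):
        cav = _interval_samples(signal, cyc.cav_interval)
        csv = _interval_samples(signal, cyc.csv_interval)
        if cav.size < 8 or csv.size < 8:
            warnings.warn(f"cycle {k}: interval too short for PSD, skipped",
                          stacklevel=2)
            continue
        _, cav_psd = compute_welch_psd(cav, signal.rate)
        _, csv_psd = compute_welch_psd(csv, signal.rate)
        rows.append(
            (cav_psd.max(), cav_psd.mean(), csv_psd.max(), csv_psd.mean())
        )
    if not rows:
        raise ValueError("no cycle long enough for spectral features")
    return tuple(np.mean(rows, axis=0))  # type: ignore[return-value]


def extract_feature_vector(
    signal: PCGSignal, annotations: list[CycleAnnotation]
) -> FeatureVector:
    """Assemble the 10-feature vector: six time then four frequency features."""
    t = compute_time_features(signal, annotations)
    f = compute_freq_features(signal, annotations)
    return FeatureVector(*t, *f)
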