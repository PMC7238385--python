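"""WAV input/output, resampling and amplitude normalization for PCG recordings.

A phonocardiogram (PCG) is an acoustic recording of heart sounds. Everything
downstream of this module works on a :class:`PCGSignal` at the canonical
internal rate of 2000 Hz with samples peak-normalized to +/-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

CANONICAL_RATE = 2000.0
"""Internal sampling rate in Hz assumed by the segmentation stage."""


@dataclass(frozen=True)
class PCGSignal:
    """A mono phonocardiogram: amplitude samples plus sampling rate.

    Parameters
    ----------
    samples : np.ndarray
        Real-valued amplitudes (dimensionless, float64).
    rate : float
        Sampling frequency in Hz; must be positive.
    subject_id : str
        Opaque subject/recording label.
    site : str or None
        Optional auscultation-site tag (aortic, pulmonary, ...).
    """

    samples: np.ndarray
    rate: float
    subject_id: str = ""
    site: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("PCGSignal samples must be one-dimensional")
        if samples.size == 0:
            raise ValueError("PCGSignal requires non-empty samples")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return np.arange(self.samples.size) / self.rate


def read_wav(path: str | Path, subject_id: str | None = None) -> PCGSignal:
    """Read a PCM or float RIFF WAV file into a :class:`PCGSignal`.

    Integer PCM samples are rescaled to [-1, 1) by the full-scale value of
    their bit depth. Stereo files are reduced to channel 0 with a warning.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the payload is not WAV or the audio is zero-length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such WAV file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"not a readable WAV payload: {path} ({exc})") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    if data.ndim > 1:
        warnings.warn(
            f"{path.name}: multi-channel WAV, using channel 0", stacklevel=2
        )
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return PCGSignal(samples, float(rate), subject_id=subject_id or path.stem)


def write_wav(path: str | Path, signal: PCGSignal) -> None:
    """Write a signal as 16-bit PCM WAV. Samples are clipped to [-1, 1]."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(Path(path), int(round(signal.rate)), pcm)


def resample_to_rate(signal: PCGSignal, target_rate: float) -> PCGSignal:
    """Resample to *target_rate* with polyphase FIR anti-alias filtering.

    Only downsampling (or the identity) is supported; recordings arrive at
    8 kHz and are brought to the canonical 2 kHz. The anti-alias filter is
    the Kaiser-windowed FIR designed by ``scipy.signal.resample_poly``.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if target_rate > signal.rate:
        raise ValueError(
            f"upsampling not supported: {signal.rate} Hz -> {target_rate} Hz"
        )
    if target_rate == signal.rate:
        return signal
    ratio = Fraction(target_rate / signal.rate).limit_denominator(10_000)
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return replace(signal, samples=out, rate=float(target_rate))


def normalize_amplitude(signal: PCGSignal) -> PCGSignal:
    """Scale samples so the maximum absolute value is exactly 1.

    Raises
    ------
    ValueError
        For an all-zero signal; a silent recording carries no heart sounds
        and cannot be processed downstream.
    """
    peak = np.max(np.abs(signal.samples))
    if peak == 0:
        raise ValueError("all-zero signal cannot be amplitude-normalized")
    return replace(signal, samples=signal.samples / peak)
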