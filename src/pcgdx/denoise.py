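"""Discrete-wavelet soft-threshold denoising of the normalized PCG.

The recording is decomposed with the Daubechies-6 wavelet to five levels,
every detail band is shrunk by the universal soft threshold
``T = sigma * sqrt(2 ln n)`` (sigma estimated from the median absolute
level-1 detail coefficient), and the signal is rebuilt by the inverse
transform. The approximation band, which carries the S1/S2 energy, is never
thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

from .signal import PCGSignal

_MAD_TO_SIGMA = 0.6745  # median(|N(0,sigma)|) = 0.6745 sigma


@dataclass(frozen=True)
class WaveletDenoiseConfig:
    """Denoising parameters: wavelet basis, depth, threshold rule."""

    wavelet_name: str = "db6"
    levels: int = 5
    threshold_rule: str = "universal"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_rule != "universal":
            raise ValueError(f"unknown threshold rule: {self.threshold_rule}")


def min_length_for_levels(wavelet_name: str, levels: int) -> int:
    """Smallest signal length whose maximum DWT depth reaches *levels*."""
    filt = pywt.Wavelet(wavelet_name).dec_len
    return (filt - 1) * 2**levels


def check_decomposable(n: int, wavelet_name: str, levels: int) -> None:
    need = min_length_for_levels(wavelet_name, levels)
    if n < need:
        raise ValueError(
            f"signal of {n} samples too short for {levels} "
            f"{wavelet_name} levels (minimum {need} samples)"
        )


def compute_universal_threshold(detail_coeffs: np.ndarray, n: int) -> float:
    """Universal shrinkage threshold ``sigma_hat * sqrt(2 ln n)``.

    ``sigma_hat = median(|d|) / 0.6745`` is the robust noise-scale estimate
    from the finest-level detail coefficients *detail_coeffs*; *n* is the
    signal length.
    """
    detail_coeffs = np.asarray(detail_coeffs, dtype=np.float64)
    if detail_coeffs.size == 0:
        raise ValueError("detail_coeffs must be non-empty")
    if n < 2:
        raise ValueError("signal length n must be >= 2")
    sigma = float(np.median(np.abs(detail_coeffs))) / _MAD_TO_SIGMA
    return sigma * float(np.sqrt(2.0 * np.log(n)))


def soft_threshold(coeffs: np.ndarray | float, threshold: float):
    """Soft shrinkage: sgn(W)(|W|-T) where |W| >= T, else 0."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    w = np.asarray(coeffs, dtype=np.float64)
    out = np.sign(w) * np.maximum(np.abs(w) - threshold, 0.0)
    return float(out) if np.isscalar(coeffs) or out.ndim == 0 else out


def denoise_signal(
    signal: PCGSignal, config: WaveletDenoiseConfig | None = None
) -> PCGSignal:
    """Soft-threshold every detail band with one global universal threshold.

    Boundary handling uses symmetric extension; the reconstruction is
    trimmed back to the input length, so rate and length are preserved.
    """
    config = config or WaveletDenoiseConfig()
    x = signal.samples
    check_decomposable(x.size, config.wavelet_name, config.levels)
    coeffs = pywt.wavedec(
        x, config.wavelet_name, mode="symmetric", level=config.levels
    )
    # coeffs = [cA_L, cD_L, ..., cD_1]; finest details estimate the noise
    threshold = compute_universal_threshold(coeffs[-1], x.size)
    new_coeffs = [coeffs[0]] + [soft_threshold(c, threshold) for c in coeffs[1:]]
    rec = pywt.waverec(new_coeffs, config.wavelet_name, mode="symmetric")
    return replace(signal, samples=rec[: x.size])
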