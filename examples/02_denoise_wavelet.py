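"""Wavelet soft-threshold denoising of a noisy low-frequency burst.

A clean 40 Hz Gaussian burst (S1-like) is corrupted with broadband noise;
five-level db6 decomposition with universal soft thresholding removes most
of the out-of-band noise while preserving the burst.
"""

import numpy as np

from pcgdx import PCGSignal, denoise_signal

rate = 2000.0
rng = np.random.default_rng(0)
t = np.arange(8192) / rate
clean = np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2) * np.cos(2 * np.pi * 40.0 * t)
noisy = clean + 0.05 * rng.standard_normal(t.size)

denoised = denoise_signal(PCGSignal(noisy, rate))


def band_energy(x, lo, hi):
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1 / rate)
    return spec[(freqs >= lo) & (freqs <= hi)].sum()


hf_before = band_energy(noisy, 500, 1000)
hf_after = band_energy(denoised.samples, 500, 1000)
burst_before = band_energy(clean, 20, 60)
burst_after = band_energy(denoised.samples, 20, 60)

print(f"noise-band (500-1000 Hz) energy: {hf_before:.2f} -> {hf_after:.4f}")
print(f"burst-band (20-60 Hz) energy   : {burst_before:.2f} -> {burst_after:.2f}")
print(
    "The universal threshold kills nearly all fine-scale noise coefficients\n"
    "while the heart-sound band, carried by coarser scales, is retained."
)
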