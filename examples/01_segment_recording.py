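"""Segment a synthetic phonocardiogram into heart sounds and intervals.

Builds one 20 s recording at 90 bpm with a strong systolic murmur, runs the
preprocessing and segmentation chain, and compares the recovered S1/S2
instants and heart rate with the generator's ground truth.
"""

import numpy as np

from pcgdx import SynthConfig, preprocess, segment_pcg, synthesize_pcg

signal, truth = synthesize_pcg(
    SynthConfig(heart_rate=90.0, murmur_level=1.0, noise_snr=20.0, seed=1)
)
denoised = preprocess(signal)  # 2 kHz, peak-normalized, wavelet-denoised
seg = segment_pcg(denoised)

detected = np.array([inst.time for inst in seg.instants])
true_instants = truth.all_instants()
hits = sum(np.min(np.abs(detected - t)) <= 0.020 for t in true_instants)

print(f"true heart rate      : {truth.heart_rate:.1f} bpm")
print(f"estimated heart rate : {seg.heart_rate:.1f} bpm")
print(f"instants recovered   : {hits}/{true_instants.size} within 20 ms")
print(f"complete cycles      : {len(seg.cycles)}")
cyc = seg.cycles[0]
print(
    f"first cycle          : S1 {cyc.s1_interval[0]:.3f}-{cyc.s1_interval[1]:.3f} s, "
    f"CAV {cyc.cav_interval[0]:.3f}-{cyc.cav_interval[1]:.3f} s, "
    f"S2 {cyc.s2_interval[0]:.3f}-{cyc.s2_interval[1]:.3f} s, "
    f"CSV {cyc.csv_interval[0]:.3f}-{cyc.csv_interval[1]:.3f} s"
)
print(
    "CAV is the systolic closed-atrioventricular-valve interval (where a\n"
    "systolic murmur lives); CSV is the diastolic closed-semilunar-valve\n"
    "interval. Near-total instant recovery despite a murmur as loud as S1\n"
    "shows the Hadamard-product suppression of murmur frequency bands."
)
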