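# Methods

This note records the models, constants and design decisions behind
`pcgdx`, in the order the pipeline runs.

## Signal model and preprocessing

A phonocardiogram (PCG) is treated as a mono, dimensionless amplitude
sequence with a sampling rate. Recordings enter at any rate ≥ 2 kHz and
are brought to the canonical **2000 Hz** by polyphase resampling
(`scipy.signal.resample_poly`, Kaiser-windowed FIR anti-aliasing).
2 kHz is the rate every later constant assumes: the 20 ms Shannon-energy
frame is then exactly N = 40 samples, and the Nyquist band (0–1000 Hz)
covers all heart-sound and murmur energy of interest. Upsampling is
refused — there is no information to add. Stereo files reduce to channel
0 with a warning. Peak normalization divides by the maximum absolute
sample; an all-zero recording raises instead of propagating silently.

Denoising is five-level Daubechies-6 wavelet shrinkage. The universal
threshold `T = σ̂ √(2 ln n)` uses the robust noise scale
`σ̂ = median(|d₁|)/0.6745` from the finest detail coefficients; one
global T soft-thresholds every detail level, and the approximation band
— which carries the S1/S2 energy — is never touched. Boundary handling
is symmetric signal extension, the common default that minimizes edge
artifacts on 20 s records; the reconstruction is trimmed to the input
length. Whether the threshold should be per-level or global is an open
choice; the global-MAD construction is the standard one the term
"universal threshold" denotes, and is what this package implements.

## Segmentation

**Band recombination.** The denoised PCG is decomposed once (db6, five
levels) and each level is reconstructed alone to give full-length band
signals; approximations follow from A_j = A_{j+1} + D_{j+1}, so
A5 + D1 + … + D5 reproduces the input to numerical precision (a tested
invariant). At 2 kHz the detail bands are nominally D1 500–1000,
D2 250–500, D3 125–250, D4 62.5–125, D5 31.25–62.5 Hz. S1 and S2 are
broadband low-frequency transients active in both D4 and D5; murmurs
concentrate above ~100 Hz and are essentially absent from D5, so the
element-wise product S = D4·D5 amplifies the sounds and suppresses the
murmur — a time-domain AND of two frequency bands.

**Envelope.** S is normalized to ±1 and framed (20 ms window, 10 ms
hop). Per frame the average Shannon energy −(1/N) Σ s² log s² is
evaluated with the 0·log 0 := 0 convention (an explicit mask, not an
epsilon); the frame series is then z-scored (mean 0, SD 1 — asserted to
1e-9 in tests). Frame timestamps sit at frame centers. Shannon energy
deliberately emphasizes medium-intensity content: |s| = 1 contributes
zero, so the envelope is dominated by the body of each burst rather
than single extreme samples.

**Instant detection.** Envelope peaks are strict sign changes of the
first difference (plateaus take the leftmost sample). Peak times are
refined to sub-frame precision by the vertex of a least-squares parabola
over the peak frame ±2 neighbours — the envelope is sampled every 10 ms
and the quantization error would otherwise dominate the gap tests below.
Two filters follow, in this order: (1) a candidate must carry the
maximal envelope magnitude within the 100 ms range centered on it;
(2) while two surviving candidates are closer than 180 ms, the
lower-magnitude one is dropped (dominant sounds win). Gaps longer than
500 ms cannot be repaired by deletion; they are reported as flags on the
result rather than enforced, since at 60 bpm a perfectly healthy
diastolic gap already exceeds 500 ms.

**Heart rate.** With instants alternating S1, S2, S1, …, each two-step
span p_{i+2} − p_i is one cardiac cycle, so HR = 60 / mean(two-step
spans); at least three instants are required.

**S1/S2 labeling.** Systole is shorter than diastole at HR ≤ 130 bpm
and longer above — the pediatric regime makes the cutoff necessary.
Each consecutive triple compares its two gaps; the shorter one is
systole (S1 → S2) below the cutoff and diastole (S2 → S1) above, which
labels all three instants of the triple. Every instant takes the
majority label over the (up to three) triples containing it. The voting
is deliberately local: a single missed sound flips the alternation
parity of everything after it, so a global parity vote can tie on an
otherwise clean record, while local votes recover within two beats.
Instants with tied votes stay unlabeled and are skipped by cycle
construction; a record where no triple can vote (all gaps equal) raises
an "ambiguous systole/diastole" error. HR exactly 130 uses the ≤ 130
branch.

**Durations and intervals.** Windows of 120 ms (S1) and 100 ms (S2) are
centered on the labeled instants. Scanning outward from the instant,
the first envelope frame below 10 % of the instant's energy marks the
boundary on each side; a side with no crossing clamps to the window
edge and flags the cycle. The 10 % rule is applied to the
pre-normalization (non-negative) average Shannon energy, not the
z-scored envelope — z-scores are negative over most of the record, which
would make a relative threshold meaningless. CAV = [S1 end, S2 start]
and CSV = [S2 end, next S1 start] per complete S1–S2–S1 pattern; edge
cycles without both flanking instants are discarded, as are cycles whose
clamped boundaries would overlap. All times are seconds internally.

## Features

The ten features are computed on the **denoised PCG** (not the
recombined S — the recombination exists to find the sounds, the murmur
content of interest lives in the full-band signal). Per complete cycle:
max, min, mean(|x|) over the CAV samples and the CSV samples; Welch PSD
of each interval (Hanning window, 50 % overlap) with max and mean taken
per cycle; all ten statistics averaged across cycles, in the fixed order
6 time then 4 frequency features. The Welch segment length is 128
samples (64 ms), a compromise between frequency resolution (~15 Hz) and
averaging; an interval shorter than 128 samples falls back to a single
full-interval Hanning periodogram, which keeps short diastoles at high
heart rates computable. PSD statistics use the full 0–1000 Hz band.
Cycles with an empty or too-short interval are skipped with a warning.

## Classifier

A 10-10-1 multilayer perceptron: score = W2·tanh(W1·x + b1) + b2, with
10×10, 10, 1×10 and 1 parameters (121 total). Features are min-max
scaled to ±1; the scaling is fitted on training rows only and applied
affinely to held-out rows (which may land outside ±1) — fitting on all
rows before splitting would leak test information, so the global variant
exists only behind an explicit flag. Constant columns map to 0 with a
warning.

Training is Levenberg–Marquardt on the mean-squared error against 0/1
targets: solve (JᵀJ + μI)δ = Jᵀr with the analytic 121-column Jacobian
(verified against finite differences in tests); accept a step that
lowers the MSE and divide μ by 10, otherwise multiply μ by 10 and retry.
The "learning rate" of 0.01 is interpreted as the initial damping μ —
LM has no classical learning rate. Stops: MSE ≤ 1e-6, 1000 iterations,
or μ > 1e10 (a local minimum at machine precision, reported via a status
flag). Weights initialize uniformly in [−0.5, 0.5] from a seed; one
training run per fold, no restarts.

Evaluation is jack-knife: n recordings give n networks, each trained on
n−1 samples with its own fold-fitted scaler and fold-derived seed, and
each held-out sample is scored only by its own network. Scores quantize
at 0.5 (≤ 0.5 → class 0). The n held-out labels form TP/FP/TN/FN and
Acc/Se/Sp in percent; a zero denominator yields NaN plus a named flag,
never a silent 0. A fold whose training set degenerates to one class is
trained anyway and flagged. Prediction for a genuinely new subject uses
a single network trained on all samples (the CLI `predict` path);
the jack-knife ensemble exists for evaluation, not deployment.

## Synthetic data

The generator emulates the signal classes the pipeline must handle, not
valve mechanics. Defaults are the nominal study conditions and are not
meant to be tuned per experiment:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 2000 Hz | canonical pipeline rate |
| duration | 20 s | typical bedside recording length |
| S1 center / duration | 80 Hz / 100 ms | low-frequency, longer sound |
| S2 center / duration | 120 Hz / 80 ms | higher, shorter sound |
| S2 relative amplitude | 0.8 | S2 audibly weaker than S1 |
| systole fraction | 0.38 (HR ≤ 130), 0.55 (> 130) | encodes the rate-dependent systole/diastole hypothesis by construction |
| cycle jitter | ±2 % | physiological beat-to-beat variability |
| murmur band | 100–600 Hz | systolic CHD murmur energy |
| noise SNR | 20 dB | moderately noisy ward recording |

Each sound is a Gaussian-windowed **two-component** cosine burst at its
center frequency plus a half-frequency component at 80 % amplitude.
Real valve-closure sounds are broadband transients whose spectra extend
an octave below the dominant component; a pure tone at the center
frequency would leave the D5 band empty and the Hadamard product would
annihilate the sound — an artifact of over-idealized inputs, not a
property of the method. Cosine phase makes each burst even-symmetric,
so the labeled ground-truth instant coincides with the magnitude maximum
that defines an S1/S2 instant. Cycles are laid out start-to-start: a
cycle begins at the S1 onset and the S2 onset sits one systole fraction
later, matching the start-to-start definition of systole and diastole.
The murmur is Gaussian noise band-passed to 100–600 Hz, windowed to each
CAV interval with 10 ms raised-cosine ramps, and scaled so its peak is
`murmur_level` × the S1 peak; broadband noise is added at the requested
SNR. Ground truth (instants, boundaries, intervals, realized heart
rate, class label) is exact by construction.

What the generator does **not** model: S3/S4, respiration, crying and
motion artifacts, diastolic murmurs, murmur-severity grades, sensor
coloration. Passing tests therefore demonstrate the pipeline's
correctness on signals with the assumed morphology, not clinical
performance on ward recordings.

The default evaluation cohort is 24 normal + 62 murmur subjects with
heart rates uniform in 70–140 bpm (spanning both labeling regimes) and
murmur levels uniform in 0.5–1.2 for positives.

## Numerical choices and degenerate inputs

- 0·log 0 := 0 in the Shannon energy, via masking.
- Envelope z-scoring requires a non-constant envelope; an all-zero or
  constant recombined signal raises.
- Gap-equality ties in labeling use a 1e-9 s tolerance.
- Instant refinement clamps the parabola vertex to ±1 frame and falls
  back to the frame center when the fit is not concave.
- The LM normal equations fall back to increasing μ on a singular
  solve.
- Fold seeds derive as (seed·100003 + fold) mod (2³¹−1), keeping every
  derived seed reproducible and in range.

## Known limitations

- The systole fractions 0.38/0.55 change discontinuously at the 130 bpm
  cutoff. Just below the cutoff (≈ 127–130 bpm) the synthetic systolic
  instant gap drops under the 180 ms adjacency bound, so the detector
  merges sounds there; real systole does not shrink linearly with cycle
  length, so this is a generator idealization, and the pipeline degrades
  gracefully (such recordings lose S2s or are skipped with a structured
  error).
- The pipeline is not time-reversal equivariant: db6 filters are
  asymmetric, so band reconstructions of a reversed signal are not the
  reversed reconstructions. Label-swap symmetry holds at the labeling
  stage and is tested there.
- With an imbalanced cohort (24/62), a label-permutation null does not
  sit exactly at 50 %: a no-information classifier can reach the 72 %
  base rate, and observed null accuracies land between those anchors.
- Strong in-band noise (crying, motion) is outside the denoiser's
  model; the universal threshold targets broadband instrument noise.
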