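# Methods

## Problem and signal model

A single-antenna FMCW radar watches a bed from above. Each transmitted chirp
(bandwidth B = 5 GHz from 58 GHz, duration T_c = 133 µs, repeated every
463 µs, 32 chirps per 20-Hz frame) is mixed with its echo, producing a real
intermediate-frequency (IF) tone whose frequency encodes target range:

    x(m) = A sin(2π f₀ T_s m + φ₀),   f₀ = 2 s D / c,   φ₀ = 4π D / λ

with chirp slope s = B/T_c, ADC interval T_s = 1 µs, M = 128 samples per
chirp. Chirps are stacked into the fast-time × slow-time matrix R (M × N,
N = 640 per second). Each chirp is quasi-static: the target distance D is
frozen at the chirp start time.

Sleep postures (supine / lateral / prone — left and right lateral are one
class) differ in how the torso breathes at the radar: chest excursion
amplitude, and how many adjacent range bins carry correlated motion energy.
The pipeline makes that difference explicit and classifies it.

## Pipeline

1. **Mean subtraction, twice.** First every fast-time row has its slow-time
   mean removed (this nulls all static returns — clutter, the stationary
   part of the torso echo), then every chirp column has its fast-time mean
   removed (per-chirp offset). The conventional labels "DC suppression" /
   "clutter suppression" for these two steps are swapped relative to their
   actual effect; we implement the algebra exactly as stated and note the
   naming here. Both steps are idempotent, the pair is linear, and a fully
   static scene is annihilated to below 1e−6 of its energy (tested).
2. **Range FFT.** Per-chirp M-point DFT, one-sided (K = M/2 = 64 bins),
   rectangular window, no zero padding. Bin pitch follows from the ADC
   window: c / (2 s M T_s) ≈ 3.1 cm; the physical resolution is c/(2B) ≈
   3.0 cm. For physical-span reporting of the bin window a separate 4-cm
   reporting pitch is used (40 bins ↔ 1.6 m); both notions are kept because
   they answer different questions (FFT geometry vs body coverage).
3. **Motion features.** Sliding-window population standard deviation of the
   magnitude spectrogram along slow time: window W = 320 samples (0.5 s),
   step S = 64 (0.1 s), N_W = ⌊N/S⌋ windows with the tail edge-replicated
   by W − S samples so the final windows are full length (this reproduces
   N_W = 60 for a 6-s span). Std is computed on the magnitude, not the
   complex values: the statistic squares a real difference and the feature
   images are real. The K₁ = 40 contiguous bins maximizing the summed std
   (ties to the smallest offset) form the bin window, re-selected per 6-s
   image; the chosen offset is recorded so a fixed-offset mode can be
   configured downstream.
4. **Augmentation** (training split only): time shift by ±0.5–1 s (whole
   0.1-s columns, circular — respiration is quasi-periodic, so wrapped
   columns stay plausible), range shift by ±5–10 bins (zero-filled — body
   energy must not wrap across range), and mix-up between images of
   different classes with λ ~ Beta(0.4, 0.4). With multiplicity 2 (default)
   each original contributes two shifted and two mixed copies, i.e. the
   training set grows 5×.
5. **ResTCN classifier.** The single-channel feature image is cloned to 3
   channels and passed through a residual convolutional backbone that
   collapses the range axis while preserving a (pooled, ~15-step) temporal
   axis; the range-collapsed sequence is projected to a 1024-dimensional
   per-step embedding; a causal dilated temporal convolution stack (kernel
   3, dilations 1/2/4) reads it and the last time step feeds a linear layer
   to 3 logits. Ablation variants: *resnet_only* (backbone + mean over time
   + linear) and *tcn_only* (the feature image consumed directly as a
   length-N_W sequence of K₁-dim vectors).

## Training recipe

AdamW (decoupled weight decay on tensors of rank ≥ 2) on soft-label
cross-entropy; initial learning rate 0.005, L2 coefficient 0.001, learning
rate ×0.1 every 10 epochs, batch 32. The full schedule always runs and the
**final-epoch weights are kept**. We deliberately do not select a
best-validation checkpoint: under subject-wise splitting the validation set
here is a single subject (40 images), and its per-epoch accuracy is noisy
enough to be anti-correlated with held-out performance — selection froze
pre-convergence weights in our experiments. Validation accuracy is still
recorded per epoch for monitoring.

The network is implemented directly in numpy (explicit forward/backward
passes, im2col convolutions arranged as single BLAS gemms, batch
normalization with running statistics, inverted dropout). Everything is
deterministic given the seed; two builds with equal seeds have identical
weights and equal fits produce equal predictions.

### Architecture defaults and why

Stage widths (16, 32, 64) with one residual block per stage keep the model
small enough that a full benchmark trains in about two minutes on one CPU
core while retaining far more capacity than the task needs (it memorizes
8 images in under 200 steps; all widths are `ModelConfig` fields, so wider
backbones are a configuration change). The 1024-dim per-step embedding is
kept as the interface between backbone and temporal head. TCN dropout
defaults to 0.2 and augmentation multiplicity to 2: with only six training
subjects the failure mode is memorizing subject-specific amplitude
signatures, and these two knobs are the standard remedies.

## Evaluation

Per-class one-vs-rest TP/FP/FN/TN from the 3×3 confusion matrix give
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
reported scores are macro averages, and accuracy is the confusion trace
over the sample count. A class absent from a test set yields zero metrics
for that class plus a flag. Splits are always at the subject level — no
person contributes to two splits.

## Synthetic bed scenes

The simulator generates what the pipeline assumes and nothing more: a
dominant torso reflector at 0.6–1.2 m whose distance follows
d(t) = D + A_r sin(2π f_r t + φ_r) + A_h sin(2π f_h t + φ_h)
(respiration 0.2–0.4 Hz, 1–12 mm; heartbeat 0.9–1.3 Hz, 0.1–0.5 mm; phases
drawn once per scene), optionally smeared over adjacent range bins
(geometric 0.7 amplitude decay, fully correlated motion) to emulate the
extended body surface; static clutter reflectors; a DC offset; white
Gaussian noise (σ = 0.05 against a unit-order reflector). Chirp timestamps
honour the burst structure (463 µs inside a frame, idle dead time to the
next 50-ms frame boundary).

Posture presets drive the class structure: supine breathes 6–12 mm over
4–6 bins; lateral 1–4 mm over 1–3 bins; prone 3–7 mm over 2–4 bins with the
reflector damped ×0.7 (mattress absorption). Subject-level parameters
(distance, rates, clutter layout, reflector strength ±20%) are drawn once
per subject. These ranges are stipulated, not fitted to any recording: they
produce monotone amplitude/spread separation between classes with a
deliberately ambiguous lateral/prone overlap region.

**What passing tests do and do not show.** The simulator carries the
micro-motion signal faithfully — the unwrapped torso-bin phase correlates
> 0.99 with 4π d(t)/λ and the programmed breathing rate is recoverable to
within 5% — so the pipeline's signal-processing chain is exercised
realistically. It does not model electromagnetic scattering, body-surface
geometry, blankets/occlusion, posture transitions, or motion artifacts;
benchmark accuracies on synthetic scenes therefore validate the method's
machinery and relative orderings (full model vs ablations, features vs raw
input, augmentation on vs off), not clinical performance.

## Benchmark scale and numerical choices

The default benchmark simulates 9 subjects × 4 postures × 1 minute,
splits 6/1/2 by subject, and trains for 30 epochs — small enough that the
complete ablation grid (3 seeds × 5 model/input/augmentation settings) runs
on a single CPU core in well under half an hour, while every qualitative
comparison of interest is already expressed at this scale. The full recipe
(100 epochs, 16 subjects × 10 min) remains a configuration change.

Other numerical choices: float64 throughout the signal chain, float32 in
the network and on HDF5 persistence; population (1/W) normalization in the
sliding std; 0-based bin and slow-time indexing with 1-based formulas
translated accordingly; argmax ties resolved to the smallest index;
respiration-rate estimation decimates the unwrapped phase to one sample per
frame (uniform 20 Hz) and zero-pads the spectrum 4× to refine the peak.

## Known limitations

- The lateral/prone preset overlap bounds attainable synthetic accuracy;
  errors concentrate there, as in the confusion matrices the benchmark
  prints.
- A listed "velocity resolution" of the radar is not used: the method never
  forms a Doppler axis.
- The one-subject validation split makes per-epoch validation accuracy a
  monitoring signal only (see Training recipe).
- The numpy network targets clarity and single-core reproducibility, not
  GPU-scale throughput; widths beyond the defaults train slowly.
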