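# Methods

This note records the model, the choices made where the design was
open, and what the synthetic experiments do and do not show.

## Signal model and preprocessing

Inputs are single-channel EEG segments with patient, channel and class
labels, read from plain-text files indexed by a CSV manifest. The
standard front end applies an order-4 Butterworth band-pass
(0.5–150 Hz at 512 Hz, 0.5–85 Hz for 173.61 Hz material) as a
**zero-phase** forward–backward pass — chosen so waveform morphology is
not distorted; a causal single pass is available via
`bandpass(..., zero_phase=False)`. Records longer than one analysis
window can be expanded into 90 %-overlap windows
(`expand_overlap`), the device used to enlarge scarce fine-tuning data.

All material is resampled to a **256 Hz working rate**
(`resample_poly`, rational rate approximation) before the network.
Rationale: the spectral branch assigns dyadic DWT levels to the
physiological bands δ (0–4 Hz), θ (4–8), α (8–16), β (16–32),
γ (32–64), high-γ (64–128), and those edges are dyadic only at
fs = 256. The nominal 65 Hz lower edge of high-γ is treated as the
dyadic 64 Hz. Segments are z-scored per segment after filtering
(switchable off).

## Feature network

* **Embedding block** — two temporal convolutions (kernel 64, stride
  1, "same" padding) with batch norm and ELU produce 7 learned
  channels, concatenated with the raw signal: C = 8 sub-band channels.
  Depth/width are free choices; two convolutions keep the block a
  learned filter bank rather than a deep net.
* **Style-feature randomization** — per (sample, sub-band) spatial
  moments with variance floor ε = 1e-5 (σ = √(var + ε)); the
  "random disruption" of the moments is implemented as a fresh
  within-batch permutation of (μ, σ) pairs each step (mode
  `permute`), which keeps the assigned statistics realisable; a
  MixStyle-like convex-mixing mode (`mix`) is available. The
  permutation is drawn per sample with the sub-band axis kept aligned.
  SR is active only during pre-training.
* **Spectral branch** — 5-level cascaded conv-DWT with the 8-tap
  Daubechies-4 pair; detail levels 1…5 map to high-γ…θ and the level-5
  approximation is δ. The wrap padding
  (head = last R/2−1 samples, tail = first R/2−1) makes the strided
  convolution *exactly* a periodized pyramid DWT — verified against an
  independent reference implementation to 1e-8 at zero shift. The
  high-pass taps use the quadrature-mirror convention
  h[k] = (−1)^(k+1) g[R−1−k] (the sign that matches the common
  reference periodization; either overall sign is a valid wavelet
  filter and the validator accepts both).
* **Temporal branch** — six conv→BN→ELU branches, kernels
  {64, 64, 32, 16, 8, 4} and strides {32, 32, 16, 8, 4, 2} so each
  output length tracks its paired band map. Six branches (not five)
  because six kernel sizes are paired with six spectral maps in the
  fusion; a five-branch reading would leave the pairing undefined.
* **Fusion and attention** — band-matched concatenation
  [f_δ‖f_t1] … [f_high-γ‖f_t6], then per-level squeeze-and-excitation
  gating (global average → bottleneck, reduction ratio 8 → sigmoid).
* **Classifier input pooling** — each gated fused map is summarised by
  its per-channel **mean and RMS** (default `pooling="moments"`,
  96 features) rather than flattened. Raw wavelet coefficients carry
  sample-specific phase; feeding them flattened into the classifier
  lets it interpolate the training set without learning the band-power
  structure that generalises (observed: training accuracy 1.0 with
  held-out accuracy near chance at desk-scale sample sizes). The
  mean reads the signed temporal activations, the RMS the coefficient
  energy. `pooling="flatten"` retains the direct flattening.

Heads: a 3-layer classifier (hidden 128→64, ELU, 2 logits) and a
2-layer patient discriminator (hidden 128) behind the gradient
reversal layer.

## Training

Pre-training descends `L_cls + λ1·L_mse + λ2·CE_pd` with one Adam
optimiser (lr 5e-4, full-scale schedule 100 epochs × batch 100;
reduced desk-scale runs below). The discriminator CE reaches the
feature extractor through the GRL, which realises the minimax
(θ_f, θ_c minimise, θ_pd maximises `L_sum = L_cls + λ1·L_mse −
λ2·L_pd`); λ1 = λ2 = 0.01. The GRL strength is a constant λ_r = 1 —
λ2 already carries the weighting, and no warm-up schedule is
prescribed for this method. The clean (non-SR) path feeds the
discriminator; the SR path exists to train invariance in the
classifier. `L_mse` is the batch mean of the squared difference of the
two softmax outputs summed over classes. Gradients are clipped at
global norm 5.0, and a non-finite objective aborts with diagnostics.
No validation-based early stopping is used (the schedule is a fixed
epoch count by design).

Fine-tuning freezes everything upstream of the classifier — embedding
block, DWT/temporal branches and the SE gates — verified bit-for-bit
by parameter checksums. Batch norm uses its running moments and SR is
inactive, so features are fixed and are precomputed once. The loss is
the class-weighted cross-entropy with w_c = (N − N_c)/N;
`weighted=False` gives the plain-CE control for paired comparisons.

Localization scores each channel by the mean focal-class softmax
probability over that channel's segments (the aggregation across a
channel's multiple segments is a package choice; a single segment per
channel reduces to the plain probability) and returns the argmax.
Exact ties resolve to the first channel in recording order, with a
warning.

## Synthetic data

The generator emulates only the two structures the method exploits:

* **Class effect** — each segment is 1/f-shaped Gaussian noise plus
  one oscillation per physiological band; focal segments have the
  whole 4–16 Hz (θ+α) content scaled so band power is
  ×(1 + class_effect), applied through an FFT mask so the ratio is
  exact in expectation. Which bands discriminate real focal EEG is not
  a claim being made; the band is configurable.
* **Patient style** — a per-patient amplitude scale (uniform in
  [0.5, 2]), a spectral tilt (a ±0.5-weighted first-difference
  component), and patient-specific oscillation peak frequencies drawn
  once per patient (mimicking, e.g., the individual alpha frequency)
  with ±2 % frequency and ±10 % amplitude jitter per segment. Styles
  are applied identically to both classes, so within-patient class
  contrasts survive; a patient-identity probe on band powers beats
  chance under the zero-effect null, confirming the confound exists.

Every segment is a pure function of (config, seed, patient, class,
segment index). With class_effect = 0 the two classes are
distributionally identical by construction — the end-to-end null check
rests on this.

Not emulated: seizure morphology (spikes, sharp waves), artifacts
(EMG, ocular), volume conduction, montage geometry, non-stationarity.
Passing tests therefore show the pipeline recovers the assumed
band-power/style structure — not clinical performance.

## Desk-scale study conditions

The full-scale schedule (100 epochs, thousands of 20 s samples) is not
meaningful for a self-contained test suite, so the packaged
experiments use: 4 s segments at 256 Hz; 5 patients × 60
segments/class for pre-training (25 % held out); a 20-epoch reduced
pre-training run; a transfer cohort of 6 unseen patients × 16 channels
with 10 fine-tuning and up to 4 held-out recordings each (fine-tuning
30 epochs on precomputed features); the zero-effect null uses 30
segments/class and 12 epochs. Under these conditions the reduced run
reaches ≈ 0.93 held-out segment accuracy and localization ≈ 0.8–1.0
over 20 held-out recordings depending on the seed, while the null
stays at chance.

## Numerical choices and degenerate inputs

* ε = 1e-5 in the SR moments; 1e-12 probability clamp in the weighted
  CE (with a warning); SE bottleneck floor of one unit.
* Metrics with empty denominators (e.g. sensitivity with no positive
  ground truth) are reported as NaN ("missing"), never as 0.
* k-fold splits are shuffled by seed, sizes differ by ≤ 1; a
  patient-stratified variant avoids identity leakage and is exposed
  because segment-level splitting lets patient style inform the
  test-fold predictions — the default remains segment-level to match
  the method's standard evaluation.
* Checkpoints are an `.npz` of named parameters/buffers plus a JSON
  sidecar (format version 1).
* The autodiff engine is float64 throughout; convolution backward
  recomputes its strided view instead of caching the im2col buffer,
  keeping peak memory of a 100-segment batch around 1–2 GB.

## Known limitations

* The discriminator and SR act on a fixture whose style is mostly
  second-order (scale/tilt); gains from adversarial training are
  accordingly modest at desk scale.
* Localization accuracy on unseen-patient cohorts varies by seed
  (≈ 0.8–1.0 over 20 recordings); per-patient style occasionally makes
  a non-focal channel's θ+α share dominate.
* Filter-edge ringing: the 0.5 Hz high-pass edge rings for roughly 2 s
  at record boundaries under zero-phase filtering; stop-band claims are
  therefore steady-state statements.
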