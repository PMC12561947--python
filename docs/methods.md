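# Methods

This note documents the models, algorithms and numerical choices behind
`radarcough`: what is computed, under which assumptions, and what the
synthetic benchmark does and does not demonstrate.

## 1. Problem setting

A 60 GHz frequency-modulated continuous-wave (FMCW) radar watches a person
in bed or seated in a room. Every recording is 3 s of dechirped complex
intermediate-frequency (IF) data: 1500 chirps at a 500 Hz repetition rate,
108 complex ADC samples per chirp, one transmit and four receive channels —
a `(1500, 1, 4, 108)` complex cube. The task is binary: does this recording
contain a cough, or some other daily activity (quiet breathing, arm or head
movement, turning over, sitting up / lying down / standing up)?

Coughs are compelling radar targets because the chest wall jerks through a
few rapid centimeter-scale cycles, producing a short broadband
micro-Doppler stripe, while the body otherwise stays in place. The
challenge is distinguishing that stripe from other short transient motions,
which is why the classifier consumes the joint evolution of range, velocity
and time rather than a single spectrogram.

## 2. Scene simulator

The simulator replaces the measurement campaign. Each recording is a small
set of point scatterers with parameterized radial trajectories `R_k(t)`;
the dechirped IF sample for chirp `i`, antenna `r`, fast-time sample `n` is

    s(i, r, n) = Σ_k a_k exp[ j( 2π f_b,k(t_i) n / f_s + 4π R_k(t_i)/λ + φ_r ) ] + w(i, r, n)

with beat frequency `f_b = 2 S R / c` (sweep slope `S`), chirp time
`t_i = i / f_rep`, fixed small per-antenna phase offsets `φ_r` and circular
complex Gaussian noise `w` scaled so the mean SNR matches the requested
value. Increasing range means "moving away" and lands on the positive side
of the Doppler axis. Antennas are geometry-free copies (no angle
processing anywhere downstream) with independent noise, which is exactly
what antenna averaging in the pipeline assumes.

Trajectories decompose into a base range, an optional constant radial
velocity, sinusoidal breathing, and transient events. Two transient shapes
are used:

* **monotonic pulse** — `d(t) = A sin²(π τ)` over the event window
  (peak speed `π A / duration`): limb and posture movements, which travel
  far (0.1–0.4 m) over 0.8–2 s;
* **oscillatory jerk** — `d(t) = A sin(2π f_osc (t−onset)) sin²(π τ)` with
  `f_osc` ∈ 3–8 Hz: the cough chest wall. The amplitude is derived from the
  drawn peak speed (0.3–1.0 m/s), giving 0.6–5 cm of displacement — fast
  but spatially small, the opposite of a posture change.

Per-activity parameter ranges live in `simulate.MOTION_RANGES` (all
overridable per call). Breathing uses 3–8 mm chest excursion at 0.2–0.4 Hz.
Each synthetic subject carries persistent traits (typical distance,
breathing rate and depth) drawn from a subject-specific stream, so
subject-independent evaluation is a real distribution-shift test rather
than a relabeled random split.

The default dataset composition mirrors the study conditions: 15 subjects;
per subject 21 cough + 82 non-cough recordings in the bed scene and
18 cough + 90 non-cough in the sitting scene (3165 recordings). Non-cough
recordings cycle deterministically through the scene's activity inventory.
Every record's seed is derived as `SeedSequence([master_seed, subject,
index])` and stored in the manifest, so any cube can be replayed
bit-identically without storing it.

**What the simulator does not emulate:** multipath and wall clutter beyond
a static mean (removed exactly by the clutter filter), radar cross-section
variation with aspect angle, range-dependent path loss, antenna coupling,
phase noise, and real cough-to-cough physiological variability. Passing
the benchmark therefore demonstrates that the pipeline, model and protocol
are implemented correctly and can recover a cough signature under
controlled conditions — not that the trained weights transfer to hardware
recordings.

## 3. Range-Doppler preprocessing

1. **Range FFT** along fast time (rectangular window, no normalization;
   all 108 complex bins kept).
2. **Clutter removal**: subtract the per-(antenna, range-bin) mean over
   chirps. Static reflectors are chirp-independent, so they are removed
   exactly; every output series has zero slow-time mean.
3. **Primary bin**: average the complex signal over antennas, take the
   modulus, average over chirps, argmax over range bins (ties to the
   lowest index). Selection runs on the clutter-removed profiles so it
   locks onto the moving subject rather than furniture.
4. **Band extraction**: 48 bins `[p−24, p+24)`, shifted at the array edges
   so exactly 48 bins always come out.
5. **Sliding Doppler FFT**: 125-chirp windows stepped by 40 chirps
   (`⌊(1500−125)/40⌋+1 = 35` frames), FFT along slow time, centered so the
   zero-velocity column is at index 62; "toward the radar" is the negative
   side. Frame `t` covers chirps `[40t, 40t+125)` (0-based, half-open).
6. **Magnitude → antenna average → log**: `ln(10⁻⁶ + mean_r |·|)`. The
   additive floor keeps empty scenes finite; the log compresses the
   dynamic range so weak cough sidebands survive next to the torso line.

Output: `(35, 1, 48, 125)` real sequences. Derived physical scales at the
default waveform: 46.3 mm range per bin, 4 Hz (≈10 mm/s) per Doppler bin,
±0.62 m/s unambiguous speed. Cough peak speeds near 1 m/s alias — as they
do on the real system, where they still read as broadband stripes.

A per-sequence standardization (zero mean, unit variance over the whole
sequence) is applied at model input, not stored in the RDM files. A Hann
window for both FFTs is available (`PipelineConfig.window_fn`) but off by
default (rectangular).

## 4. Augmentation

Both transforms are drawn once per sequence and applied to every frame
identically, preserving temporal structure:

* **range translation** — uniform integer shift in [−12, +12] range bins;
  vacated rows are filled with the sequence minimum (the post-log noise
  floor), not zero, to avoid out-of-distribution pixels. Positive shifts
  move the subject away from the radar.
* **random erasing** — one rectangle covering 5–20 % of the frame with
  width/height ratio in [0.3, 3.33] (sides `round(√(area/aspect))`,
  `round(√(area·aspect))`; draws rejected until the rectangle fits),
  filled with fresh uniform draws from the sequence's own [min, max] per
  pixel per frame.

Each transform fires independently with probability 0.5 by default,
on-the-fly during training only; validation and test data are never
augmented. Range translation matters beyond generic regularization here:
band extraction clamps at the array edges, so near subjects sit at a
subject-specific row — translation removes that shortcut.

## 5. Classifier

Per frame, a residual CNN (standard 34-layer basic-block configuration;
stem modified to 1 input channel; classification head removed) produces a
512-dim embedding, linearly projected to the model dimension d=256:

    f_t = P · ResNet(X_t),  t = 1..T

A two-layer post-norm self-attention encoder (4 heads, position-wise FFN
of width 4d, residual connections and layer normalization after each
sublayer) contextualizes the frame sequence; temporal mean pooling and a
linear layer finish the job:

    h_{1..T} = Enc(f_{1..T} + PE),   k = (1/T) Σ_t h_t,   p = softmax(W k + b)

trained with mean cross-entropy. Fixed sinusoidal positional encodings are
added by default: with mean pooling, an attention encoder without them is
permutation-invariant, and the temporal order of frames is part of the
signal (a property test asserts both behaviors). Setting
`positional_encoding="none"` restores the literal order-free variant.

Ablation variants: `resnet_only` (frame embeddings mean-pooled straight
into the classifier) and `attention_only` (flattened frames linearly
embedded, no CNN).

The layers are implemented in numpy with hand-derived backward passes
(`radarcough.nn`): im2col convolution, batch norm, max pooling, layer
norm, multi-head attention, Adam. Every backward pass is verified against
central-difference numerical gradients in float64. The convolution
backward uses a numba kernel for the column-to-image scatter, with a pure
numpy fallback. Initialization: He-normal for convolutions, scaled-uniform
for linear layers, all from a single seeded generator.

`ModelConfig.base_channels` scales the trunk width uniformly
(`resnet18`/`resnet34` select the depth), so a narrow trunk can be trained
end-to-end on one CPU while the default stays the full-width 34-layer
network.

## 6. Evaluation protocol

Subject-independent 5-fold cross-validation: the 15 subjects are randomly
partitioned into five disjoint groups of three; per fold the held-out
group is the test set and the remaining subjects' recordings are split
80/20 into train/validation, stratified by label. Subject leakage is
asserted on every run. Training uses Adam (defaults: learning rate 1e-4,
weight decay 0.3 in coupled L2 form, batch size 32, 15 epochs); after each
epoch the validation F1 at threshold 0.5 is computed and the
best-validation-F1 weights (ties to the later epoch) are restored before
the single test evaluation.

Metrics (cough = positive): accuracy, precision, recall/sensitivity,
specificity, F1, Brier score, and rank-based AUC (ties counted ½),
aggregated as mean ± sample standard deviation (ddof=1) across folds.
Zero-denominator ratios are reported as 0 with an explicit flag rather
than dropped. Per-fold scores of two models are compared with the standard
two-sided paired t-test (`t = mean(d)/(sd(d)/√n)`, n−1 degrees of
freedom); identical vectors are rejected as degenerate rather than
reported as t = 0.

## 7. Benchmark problem sizes

End-to-end training in pure numpy on a single CPU core is the binding
resource, so the self-contained benchmark (`radarcough.benchmark`, used by
the tests and the acceptance script) runs the protocol at desk scale: 5
subjects × 20 recordings (10 cough / 10 non-cough split over both scenes),
20 dB SNR, five folds with one held-out subject each, the width-reduced
18-layer trunk (base 20 channels, feature dim 128, FFN width 512), and
5 epochs of Adam at batch size 2 with a warmup+cosine schedule peaking at
1e-3, weight decay 0.01 and betas (0.9, 0.95). Two recipe notes for this
short-horizon regime (~160 optimizer steps): the reduced `beta2` lets the
second-moment estimate track the rapidly changing gradient scale (the
default 0.999 effectively averages over more steps than the run contains),
and augmentation is disabled — at this step count it prevents convergence
rather than regularizing (it needs the longer 15-epoch full-scale
schedule to pay off). The full-width configuration is identical code; only
the width/batch/epoch knobs differ.

## 8. Numerical and design choices

* FFTs unnormalized, rectangular window (Hann available per config).
* Primary-bin ties break to the lowest index; band extraction clamps at
  edges; frame windows are 0-based half-open.
* Log floor ε = 10⁻⁶ (configurable); a static noiseless scene maps to the
  constant ln ε and standardizes to all-zeros.
* Decision threshold 0.5 on the cough probability for confusion metrics;
  AUC/Brier use raw probabilities.
* Noise power is set from the realized mean signal power, so requested SNR
  is matched in expectation (verified to ±1 dB over repeated draws).
* All randomness flows from explicit `numpy` generators; dataset records
  carry their derived seeds for exact replay; training is deterministic
  given `TrainConfig.seed`.
* Adam uses coupled L2 weight decay (added to the gradient), matching the
  stated optimizer convention; optional recipe knobs — a warmup+cosine
  learning-rate schedule (`lr_schedule`), global-norm gradient clipping
  (`max_grad_norm`), Adam betas (`adam_betas`), and zero-initialized
  residual-block BN scales (`ResNetTrunk(zero_init_residual=...)`) — all
  default to the standard conventions (constant schedule, no clipping,
  betas (0.9, 0.999), normal BN init).

## 9. Known limitations

* Simulator realism is bounded (Section 2); reported benchmark metrics
  characterize the implementation, not clinical performance.
* The attention baseline ("attention_only") is a linear-embedding
  variant, not a reproduction of any specific external architecture.
* Checkpoints store raw parameter arrays keyed by construction order;
  loading requires the same architecture configuration.
* With four identical-geometry antennas, antenna averaging is a pure
  noise-reduction device; no direction-of-arrival information exists or
  is used.
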