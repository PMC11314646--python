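# Methods

## Problem and model

The detector classifies a fixed-length window of 30 consecutive inter-beat
intervals (RR intervals from ECG R peaks, or beat-to-beat intervals from PPG
pulse peaks) as AF or non-AF. The discriminating signal is temporal
irregularity: AF produces serially independent, high-variance intervals,
while sinus rhythm varies slowly and smoothly. A window either lies wholly
inside one annotated rhythm episode or is not formed at all, so labels are
unambiguous.

Two 1-D CNN architectures are provided. Both use length-5 kernels with
length-preserving zero padding, batch normalization and a pluggable
pointwise activation on every conv layer, one max-pool (size 2, stride 2),
dropout 0.5 on the last conv layer, and a 2-way fully connected softmax
head. The convolution follows the neural-convolution convention
`y[n] = Σ_m x[n−m]·w[M−1−m]` (the kernel is flipped; padding is applied on
the causal side so output length equals input length). The baseline stacks
60/40/20/10 feature maps (pool before the last layer, 17,992 learnables);
the compressed variant stacks 20/10/5 (pool before the last layer, 1,607
backbone learnables) and recovers capacity with a channel-attention module
on the second conv layer's output:

- **SE**: squeeze `z_c = mean_n x_c[n]`, excite
  `s = σ(W₂ δ(W₁ z + b₁) + b₂)` through a `⌊C/r⌋` bottleneck (r = 3, biased
  fully connected layers, δ = ReLU), rescale `x̃_c = s_c x_c`. One scalar
  gate per channel, constant over positions. +73 parameters at C = 10.
- **ATAC**: `g = σ(BN(PW₂ δ(BN(PW₁ x))))` with two biased point-wise
  (kernel-length-1) convolutions through the same bottleneck width, gate
  applied elementwise `x′ = g ⊙ x`. The gate varies across positions —
  local channel attention. +99 parameters at C = 10. The module gates the
  activated conv output rather than replacing the activation.

Parameter accounting counts conv weights+biases, batch-norm scale+offset,
attention weights+biases (+ ATAC's batch norms) and FC weights+biases.
Truncating totals down to the nearest hundred gives the budgets the models
are quoted at: 17,900 / 1,600 (SE) / 1,700 (ATAC) — a ~91% reduction either
way. Attention is placed on exactly one layer (the second; configurable):
with r = 3 and floor bottleneck widths this single-layer placement is the
configuration consistent with all three quoted budgets.

Activations: `relu`, `swish = x·σ(x)`, and `sine = sin(x)` (no frequency
scaling — none is specified for these models; the periodic activation is
used as-is).

## Training

Softmax cross-entropy `−log softmax(o)[y]` (log-sum-exp stabilized),
minibatch SGD `θ ← θ − η·∇θJ`, η = 1e-4, batch 100, 25 epochs, data
reshuffled every epoch, last short minibatch used. Momentum defaults to 0.9 and
weight init to Glorot-uniform — the stock settings of the MATLAB-style
'sgdm' training regime these hyperparameters come from; both are config
fields. No LR schedule, no early stopping. Dropout is active only during
training; batch norm uses batch statistics during training (running-stat
momentum 0.1) and running statistics at inference. Training is
bit-reproducible under a fixed seed.

The whole stack is implemented in numpy with explicit forward/backward
passes; every layer and all three full architectures are gradient-checked
against central finite differences (tolerance 1e-4) in the test suite.

## Preprocessing rules

- An RR interval joins an episode iff **both** endpoints fall inside one
  rhythm segment (containment `start ≤ t < end`); boundary-spanning
  intervals are dropped, so no episode mixes rhythms.
- Default label maps: `(AFIB` → AF and `(N` → non-AF, with atrial flutter
  `(AFL` and junctional `(J` excluded (the AF-database convention where
  `(N` denotes all other rhythms); unmapped labels warn and exclude.
- Windows are consecutive, non-overlapping blocks of 30 intervals from the
  episode start; remainders and episodes shorter than 30 intervals are
  discarded (`floor(n/30)` windows exactly).
- The train/test split is 76%/24%, by whole records by default (no
  within-patient leakage); window-level splitting is available since either
  reading of the original protocol is defensible.
- Each side is balanced 50/50 **after** splitting by removing a uniformly
  random excess from the larger class (survivor order preserved;
  idempotent).
- No input normalization: raw interval values in seconds feed the network.

## Synthetic data

The generator emulates the statistical contrast only, not cardiac
electrophysiology:

| parameter | default | meaning |
|---|---|---|
| non-AF mean RR | 0.85 s | sinus rhythm around 70 bpm |
| sinusoidal modulation | ±0.03 s, period 12 beats, random phase | respiratory-scale variation |
| non-AF jitter sd | 0.02 s | measurement/physiological noise |
| AF mean RR | 0.70 s | faster ventricular response |
| AF noise sd | 0.13 s | serially independent irregularity |
| pause probability / length | 0.05 per beat / +0.4 s | occasional long pauses |
| floor | 0.25 s | all intervals clipped positive |

Within-window SD is ~0.03 s (non-AF) vs ~0.14 s (AF), so the **default
preset** is solvable by a plain SD threshold (≥ 0.99 accuracy) — it
verifies trainability, not discrimination skill. The **hard preset** gives
10% of non-AF windows a 5-beat AF-like burst (AF mean + AF-sd noise + one
long pause). Burst amplitude is chosen by the preset's definition: burst
windows must reach AF-range overall SD, which drops the SD-threshold
reference to ~0.97 and forces a classifier to use *where* irregularity
occurs. What passing on these presets does **not** show: robustness to
ectopy, flutter, detector noise or inter-patient rate variation — real
annotated records remain necessary for clinical claims.

Study sizes used by the test suite: 1,000 windows/class. Trainability:
76/24 record-level split of the default preset, compressed attention models
reach ≥ 95% held-out accuracy (measured ~99.5%). Value of attention: on the
hard preset with an independent same-size test set, mean accuracy over 5
seeds is SE ≈ 0.991 and ATAC ≈ 0.990 vs ≈ 0.983 for the ablated twin. At
500 windows/class this comparison is noise-dominated (per-seed spread ±0.05
swamps the ~0.01 effect), which is why the study size is 1,000/class.

## Explainability

1-D Grad-CAM: for a target class score (pre-softmax logit), channel weights
are the positionwise mean of `∂score/∂A_c` at a chosen conv block's output
(default: final conv layer, length 15 after pooling); the map
`relu(Σ_c w_c A_c)` is linearly interpolated back to the 30-interval grid
and max-normalized to [0, 1] per window (an all-zero rectified map stays
all-zero). Normalization makes traces invariant to positive rescaling of
the head. The companion trace is the first difference of the RR series, the
natural irregularity signal to compare the network's focus against.

## Numerical choices and edge cases

- Batch-norm ε = 1e-5; unit tests needing closed-form hand values set ε = 0
  and identity running statistics.
- Max-pool drops a trailing odd position; pooling is non-overlapping.
- Metrics with zero denominators (e.g. sensitivity with no AF windows) are
  reported as missing, never as 0; metrics are quoted in % to two decimals.
- Window tables are CSV with 12 significant digits (round-trip ≪ 1e-9 s);
  checkpoints are a single `.npz` of parameter/buffer arrays plus the JSON
  model config.
- The annotation codec implements the MIT format subset relevant to
  beat-interval work: beat codes, rhythm marks with aux strings, SKIP
  escapes for gaps > 1023 samples, NUM/SUB/CHN (ignored), EOF. Rhythm
  labels hold until the next mark; the final segment closes just past the
  last annotation.
- k-fold partitions are seeded, sizes differ by ≤ 1, and each fold
  validates once; per-fold training derives its seed from the base seed +
  fold index.

## Known limitations

Beat detection is out of scope — beat times are taken as given. The
synthetic generator has no flutter, ectopy or noise-artifact classes, so
specificity against AF mimics is untested here. Training is single-threaded
numpy: adequate for these model sizes (a compressed model trains in
seconds), not for architecture search. The 76/24 protocol treats each
record as one patient; multi-record patients need an external patient map.
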