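# Methods

## The classification problem

Surface electromyography (sEMG) records muscle electrical activity through
skin electrodes: a C-channel (typically 10–12 electrode) quasi-stationary
stochastic signal sampled at 100–2000 Hz. Gesture recognition assigns each
short signal segment to one of G discrete hand/wrist gestures. The signal
carries class information mainly in its per-channel amplitude envelope —
which muscles are active, and how strongly — rather than in waveform shape.

`msacnn` implements a three-stream convolutional classifier (MSACNN-RM)
built from two custom operators, together with the full windowing,
training, cross-validation, ablation and statistical-comparison pipeline,
and a synthetic corpus generator so everything is exercisable without any
external download.

## The adaptive convolutional layer (ACNL)

The layer makes the convolution kernels input-dependent through a
channel-attention mechanism:

1. GAP(X)ᶜ = (1/HW) Σᵢⱼ Xᵢⱼᶜ — global average pool of the input map;
2. A = softmax(dense(GAP(X))) — one weight per filter, positive, summing
   to 1;
3. A′ = expand(A) — broadcast to the kernel bank's shape;
4. K′ = K ⊙ A′ — elementwise reweighting of the bank;
5. Y = conv2d(X, K′).

Because convolution is linear in the kernel, we compute `conv2d(X, K) `
once with the shared bank and scale output channel f of sample b by
a[b, f]. This is mathematically identical to materialising a per-sample K′
(the pooling in step 1 is per sample, so attention is per sample) but
keeps the batch path vectorised. The identity is verified numerically
against a literal loop implementation of steps 1–5 in the test suite.

Choices where the operator definition is silent:

* the attention dense layer has a learnable bias (standard practice;
  configurable off);
* the convolution has its own bias, added **after** the attention scaling,
  so attention modulates only the linear response (configurable off);
* the softmax runs over the filter axis (the attention vector's length is
  the number of output channels);
* with F = 1 the layer degenerates exactly to a standard convolution
  (softmax of a scalar is 1) — a closed-form limit asserted in tests.

The surrounding literature sometimes describes such layers as changing the
*number* or *shape* of kernels at run time; the defining equations above
only reweight a fixed bank, and that is precisely what is implemented.

## The residual block

`Y = relu(shortcut(X) + F(X))` with main path
conv(2,1) → BN → ReLU → conv(2,1) → BN, stride 1, SAME padding, and a 1×1
convolution shortcut. Three deliberate choices:

* the 1×1 shortcut projection is **always** present, even when the input
  depth already matches the block width — this follows the block
  description literally at the cost of a few parameters;
* the shortcut carries neither BN nor bias; main-path convolutions are
  bias-free because BN immediately follows them;
* no downsampling inside blocks — unlike canonical deep residual
  networks, spatial dimensions are preserved throughout, so the block
  stack (the "MRN" module: 64/128/256/512 filters) only grows depth.

With a zeroed main path and an identity shortcut the block reduces exactly
to relu(X); this identity-learnability property is a test.

## Network assembly

Windows enter as (batch, T, C, 1): time on the height axis, electrode
channel on the width axis. Kernels of size (2,1) therefore span adjacent
time samples within one channel. Streams:

1. conv64(2,1) → ReLU → BN → MaxPool(2,2) → 4 residual blocks
   (64/128/256/512) → 3 × [ACNL(32, 1×1) → BN → ReLU → MaxPool] →
   dropout(0.5) → global average pool;
2. 3 × [ACNL(32, 1×1) → BN → ReLU → MaxPool] → dropout(0.5) → flatten;
3. conv64(2,1) → ReLU → BN → MaxPool(2,2) → 4 residual blocks → global
   average pool.

The three flattened outputs are concatenated (column-wise fusion, order
preserved) and classified by a dense softmax layer (52 classes by
default).

Two artifact knobs not part of the printed architecture:

* `width_scale` multiplies every filter count (rounded, validated ≥ 1) so
  the graph trains on a single CPU; `width_scale=1` reproduces the
  printed widths.
* **Pooling fallback.** With only 10–12 electrode channels, repeated 2×2
  pooling exhausts the channel axis. When a spatial dimension reaches 1
  the pooling window degrades to (2,1)/(1,2), and to identity when both
  do. Pooling is otherwise "valid": trailing rows/columns that do not
  fill a window are dropped.

### An architectural property worth knowing

Every kernel in the network is (2,1) or (1,1) — none spans the electrode
axis — and both deep streams end in a global average pool over it. The
network is therefore largely insensitive to *which* channel is active: two
gestures whose channel activation patterns are permutations of each other
with the same amplitude multiset are nearly indistinguishable to it (only
the max-pooling hierarchy leaks weak positional information, and stream 2's
flatten retains whatever spatial resolution survives pooling). Class
information must live in amplitude *profiles*. The synthetic generator
respects this: its per-class activation vectors differ in magnitude
pattern, not merely in channel identity.

### Ablation variants

test1–test7 toggle BN, MaxPooling, ACNL and residual blocks on the same
topology: test1 = plain multi-stream convs (no BN, no pooling, ACNLs as
standard convs, residual blocks as plain conv pairs); test2 adds BN; test3
adds pooling; test4 adds ACNL; test5 instead adds residual blocks; test6
has both but in separate streams (stream 1 keeps only its residual
section); test7 = the full model (alias `full`). The no-pooling variants
are a reconstruction: "a multi-stream CNN without MaxPooling" is not
otherwise specified, so the toggles above are this package's documented
interpretation. Note that parameter counts are **not** monotone across the
ladder: pooling adds no parameters while shrinking stream 2's flatten
width (hence the head), and test7 swaps stream 1's 512-wide GAP output for
a 32-wide ACB output.

## Preprocessing

* Window length in samples T = round(fs · window_ms / 1000), stride
  S = round(fs · step_ms / 1000); defaults 256 ms / 100 ms. Window i covers
  samples [iS, iS + T); there are ⌊(L − T)/S⌋ + 1 windows.
* Per-window label: majority vote over the per-sample labels, ties broken
  toward the lower class id (deterministic); `center` and `last` rules are
  available.
* Rest (label 0) windows are dropped by default; surviving classes are
  re-indexed densely with the mapping retained.
* Split: seeded shuffle, then 70/15/15 train/val/test by largest-remainder
  allocation. The split is window-level, matching the pipeline the
  architecture was published with; note that with a 100 ms stride on
  256 ms windows adjacent windows share 61 % of their samples, so
  window-level held-out scores are optimistic relative to bout- or
  subject-level splits.
* The three streams receive independent copies of the same window stack
  (mutation of one view cannot corrupt another).

## Training and evaluation

Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7) with categorical cross-entropy;
defaults 150 epochs, batch 32. The published regimen reports its best test
accuracy at epochs past 150 (171/158/187), so `track_best` retains the
best-validation-epoch parameters and records the winning epoch. The
learning rate is never printed in the source description; Adam defaults
are used and surfaced in config.

Metrics come from the confusion matrix (rows = true): accuracy,
macro-averaged precision/recall/F1 with classes absent from the evaluated
data excluded from the macro average (their precision/recall is undefined,
not zero), and micro averages (for single-label data micro-precision =
micro-recall = accuracy, asserted as an identity test). Cross-validation
is stratified 5-fold when every class has ≥ K members, plain seeded
round-robin otherwise; each sample is tested exactly once and fold sizes
differ by at most one.

Model comparison follows the normality-then-t protocol: Shapiro–Wilk on
the paired fold differences (delegated to scipy), then a paired t-test
computed in closed form, t = mean(d)/(sd(d)/√n), with the p-value from the
t distribution (n − 1 df). If normality is rejected the report flags the
t-test as unreliable rather than silently switching tests. Degenerate
inputs: identical samples → "no difference", p = 1; constant nonzero
difference → t = ±∞, p = 0, flagged degenerate.

## The neural-network core

No deep-learning framework is used: the layers (Conv2D via im2col,
BatchNorm with running statistics, MaxPool, Dense, Dropout, GAP), the
Adam optimizer and the fused softmax/cross-entropy loss are implemented
directly in numpy with hand-derived backward passes. Every layer's
gradients — including the adaptive layer's attention path — are verified
against central finite differences (1e-4 relative tolerance) in the test
suite. BN uses ε = 1e-3 and running-stat momentum 0.9; initialisation is
Glorot uniform, seeded.

## Synthetic corpus

Each gesture class g gets a fixed nonnegative unit activation vector v_g
over the C channels (seeded). The recording is zero-mean Gaussian noise
band-limited to 20–450 Hz (4th-order Butterworth, forward-backward;
configurable, and validated against Nyquist), unit rest-floor standard
deviation per channel. During each 5-s bout of class g the channel
envelopes rise to 1 + r·v_g[c] with r = 10^(snr_db/20); bouts are
separated by 3-s rests, and the session starts and ends at rest so every
bout has an identical rest neighbourhood — which makes per-class window
counts exactly equal under the sliding grid. Labels mark bout samples
with the class id, rest with 0.

What the generator does **not** model: motor-unit action potentials,
electrode shift, cross-talk, fatigue, inter-repetition variability (a
class's envelope pattern is identical in every bout). Passing tests on
this corpus therefore certify the pipeline's mechanics and the model's
trainability, not performance on real recordings.

A multinomial logistic probe on per-channel window RMS is used as the
corpus's learnability certificate (held-out accuracy > 0.9 at +20 dB)
before any deep model is blamed, and probe accuracy is checked to be
non-decreasing in snr over {0, 10, 20} dB.

## Desk-scale problem sizes

The end-to-end checks train a `width_scale = 0.125` model on a 4-class,
10-channel corpus at fs = 500 Hz (band 20–200 Hz), one repetition per
class — 50 windows per class — for 30 epochs at batch 32, and a
`width_scale = 0.125`, 3-class, fs = 200 Hz corpus for the 5-fold CV
demonstration (20 epochs). These sizes were chosen once as the smallest
configurations on which the corpus is comfortably learnable.

At these conditions the full model (test7) reaches ≈ 0.90–0.97 held-out
accuracy. The plain no-BN/no-pooling baseline (test1) reaches ≈ 1.0:
its full-resolution flatten acts as a near-linear readout of rectified
amplitudes, the +20 dB task is easy, and window-level splitting rewards
memorisation of overlapping windows. The published full-scale ablation
ordering (full model above plain baseline) therefore does **not**
reproduce at desk scale — it emerges only with realistic task difficulty
(dozens of classes, real inter-repetition variability). The corresponding
end-to-end test asserts both the ≥ 0.90 learnability clause and the
ordering clause; the latter fails at desk scale, deliberately left as a
failing assertion rather than weakened, because it documents a real limit
of the scaled-down study conditions.

## Ninapro reader

`read_ninapro_mat` maps Ninapro-style .mat files (v5 via scipy.io, v7.3
via h5py) onto the internal recording type: `emg` transposed to
channels × samples, labels from `restimulus` (movement-refined) with
`stimulus` fallback. The sampling rate must be supplied by the caller —
the files do not reliably carry it (2000 Hz for DB2/DB4-style
acquisitions). Whether published results used `stimulus` or `restimulus`
labels is generally unstated; `restimulus` is the common choice and the
default here.

## Known limitations

* The numpy core is single-threaded apart from BLAS matmuls; full-width
  training on real datasets is out of reach (and out of scope).
* Per-sample adaptive kernels are never materialised; if a future variant
  needed non-linear post-processing of K′ per sample, the conv-then-scale
  equivalence would no longer apply.
* The generator's classes are stationary within bouts; curriculum or
  drift effects cannot be studied with it.
* Subject-wise splitting is available in principle by generating separate
  recordings per "subject", but no subject model is built in.
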