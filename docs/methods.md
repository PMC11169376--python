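# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `eegemotion`, in the spirit of a model
description that a maintainer or reviewer can check against the code.

## Signal model and feature extraction

Input recordings are assumed preprocessed (128 Hz, artifact-corrected), as
the supported public datasets ship them; the package deliberately performs
no artifact removal, re-referencing or resampling. Trials are segmented
into non-overlapping windows (default 1 s); a trailing remainder shorter
than one window is dropped rather than padded, so segment counts are exact
integers (`floor(samples / (window_s · fs))` per trial).

Band-pass filtering uses 4th-order Butterworth filters on the canonical
bands θ 4–8, α 8–13, β 13–31, γ 31–45 Hz. Filtering is **zero-phase**
(forward–backward, `sosfiltfilt`) and is applied to the whole trial before
slicing into windows, so the filter sees full-length context and no
band-dependent group delay misaligns the four planes. The phase convention
is this package's choice; with one-second windows a causal filter would
shift band energy across window boundaries asymmetrically per band.

Differential entropy is computed under a Gaussian approximation,
DE = ½ ln(2π e σ²) with σ the sample standard deviation and natural
logarithms throughout (consistent with the DE derivation itself). A
zero-variance window is treated as an error with full provenance (subject,
trial, channel, second) rather than silently clamped.

**Normalisation scope.** Min–max normalisation is applied per subject ×
channel × band over *all* of that subject's segments, before
cross-validation splitting — the whole-session protocol that the reported
magnitudes of segment-level CV studies imply. Because held-out statistics
leak into training folds under this protocol, a strict mode
(`strict_normalization=True` on `EmotionClassifier.from_recording`)
recomputes min/max from training folds only and clips held-out values to
[0, 1]; it is off by default. A constant channel normalises to all zeros
(guarded division).

**Grid mapping.** Per-channel scalars are scattered onto a 9 × 9 grid
reconstructed from 10–20 electrode geometry (row 0 frontal, 0-based
(row, col)); unmapped cells are exactly zero on every plane. The shipped
layouts (`layouts/deap.txt`, 32 channels; `layouts/dreamer.txt`, 14) are
plain-text configuration, not code constants, so users can supply their own
montages.

**Enhancement.** The log dynamic-range transform is read as
M₁ = ln(1 + 255·M), i.e. the ×255 coefficient multiplies the matrix inside
the logarithm — the classic log dynamic-range compression of an 8-bit-scaled
image. The alternative reading 255·ln(1 + M) is selectable
(`enhancement="outside"`); both fix zero cells at zero. The default feature
set stacks four DE planes and four enhanced planes (C = 8) in the order
(DE_θ, DE_α, DE_β, DE_γ, EN_θ, EN_α, EN_β, EN_γ); `de_only` /
`enhanced_only` keep the respective half (C = 4).

## Network

All layers are NumPy with hand-written backpropagation; gradient
correctness is enforced by finite-difference tests at relative error
< 1e-3, and the element-wise attention additionally by a literal
loop-based re-evaluation at max-abs error < 1e-5.

* **Conv front-end**: two 3×3 convolutions, stride 1, padding 1, channels
  C → 32 → C, each followed by ReLU. The activation is this package's
  choice (two stacked linear convolutions would collapse into one); no
  pooling or normalisation is used in the front-end.
* **Tokens**: each output plane flattened row-major to a token of width
  d = 81; two trainable rows (init N(0, 0.02²)) are *prepended*, giving
  n = C + 2 tokens. The origin of the two extra tokens is an
  interpretation; prepending vs appending is immaterial but fixed for
  reproducibility. No positional encoding is used — token identity is
  carried by the learned tokens, the gate `D` and the token-mixing matrix.
* **Element-wise attention (`isa`)**: `[Q,K,V] = z U_qkv` (bias-free);
  keys and values scaled by their per-token feature-axis L2 norm with an
  ε = 1e-6 guard; `A = (K/‖K‖) ⊙ (V/‖V‖)`; output
  `(D ⊙ Q ⊙ (U_copy A U_sum)) U_proj`. Shapes chosen here: `U_copy` n × n
  initialised to the constant 1/n (an aggregate-and-broadcast at
  initialisation), `U_sum` and `U_proj` d × d Xavier-initialised, `D` n × d
  all-ones. A scale for Q is mathematically definable but unused — the
  operator as printed consumes only the K and V norms — so it is omitted.
  Projections are bias-free, which makes the `D = 0` annihilation property
  exact.
* **Encoder block** (pre-norm): `z′ = Attn(LN(z)) + z`;
  `z = Linear(GELU(Linear(LN(z′)))) + LN(z′)`. The second residual adds the
  *normalised* intermediate — a deliberate departure from the standard
  `+ z′`, implemented exactly as specified; with zeroed FFN weights the
  block returns LN(z′) bit-for-bit, which the tests assert. FFN linears
  carry biases; hidden width defaults to 4·d = 324 (the usual transformer
  expansion; configurable). GELU is the exact erf form. Depth L = 15.
* **Baseline variant (`original`)**: single-head scaled-dot-product
  self-attention with fused qkv (d × 3d) and output (d × d) projections,
  same pre-norm block and FFN — the minimal standard encoder for the
  ablation.
* **Head**: a trainable token-mixing vector w (length n, init 1/n)
  collapses tokens to one d-vector, followed by an affine map to the class
  logits and softmax.

**Initialisation**: Xavier-uniform for dense/conv/attention projections,
zeros for biases, plus the special initialisations above; all drawn from a
single seeded generator in construction order, so a config seed fully
determines the network.

**Optimisation**: AdamW (β = 0.9/0.999, ε = 1e-8, decoupled weight decay
0.01 applied to all parameters), lr 0.001, batch 240, cross-entropy loss,
fixed epoch count with the final-epoch model evaluated (no early stopping,
no schedule, no checkpoint selection). Parameters are float32 for GEMM
throughput; optimiser moments are kept in float64 because squared float32
gradients can overflow early in training. Training is deterministic given
the seeds (same machine/BLAS).

## Evaluation protocol

Subject-dependent: one model per subject, shuffled 5-fold cross-validation
at **segment** level by default — the protocol that published
segment-level accuracies imply — with a stricter trial-level split
available (`split_by="trial"`), under which no segment of a test trial is
seen in training. Per fold, a fresh network (seed offset by the fold index)
is trained and the held-out confusion matrix recorded.

Metrics are macro averages of per-class one-vs-rest accuracy, precision,
specificity, recall and F1; a zero-denominator per-class value is defined
as 0 and the class flagged as degenerate. Two consequences worth noting:
(i) for two classes, macro specificity equals macro recall identically —
the package asserts this self-check; (ii) a class absent from both truth
and predictions contributes per-class accuracy ≈ 1 (it is all true
negatives) but precision/recall 0, so sparsely populated label spaces
dilute macro precision/recall but not macro accuracy. Aggregation across
subjects reports mean ± std over subjects of per-subject fold means.

**Composite labels**: per-dimension binary labels are combined
big-endian in (valence, arousal[, dominance]) order — (V,A) → 4 classes,
(V,A,D) → 8. The ordering is this package's convention.

## Efficiency audit

`audit()` enumerates trainable parameters exactly and counts forward-pass
multiply-accumulates analytically at batch 1, counting matrix-product MACs
only (element-wise work excluded for both variants alike); 1 MAC = 1 FLOP
by default, with the ×2 convention switchable. With the shapes chosen here
(n = 10, d = 81), the element-wise attention has *more* parameters and MACs
per layer than the single-head softmax baseline (33,715 vs 26,244
parameters; 336,150 vs 278,640 MACs), because the d × d feature-mixing and
projection matrices dominate at this small token count — its linear-in-n
scaling pays off only for longer token sequences. The audit reports both
variants and the signed percentage difference rather than asserting a
direction.

## Synthetic benchmark

The generator emulates exactly what the feature extractor measures: each
trial's class adds band-limited noise (filtered with the same Butterworth
bank) at gain 4 over a unit broadband Gaussian floor, independently per
channel; classes are assigned round-robin so counts are balanced within ±1.
Defaults — 32 channels, 128 Hz, 40 trials × 60 s, four classes mapped to
θ/α/β/γ, ratings at fine-grained bin centres (1.5, 3.5, 5.5, 8.5) so binary
and 8-bin rules both separate classes — are fixed as the package's study
conditions. The end-to-end study trains 5 epochs per fold: the synthetic
classes are strongly separable and converge within a few epochs.

What passing this benchmark shows: the full chain (filtering → DE →
normalisation → grid → network → CV → metrics) preserves and recovers
band-power class structure. What it does not show: performance on real EEG,
whose 1/f spectra, artifacts, inter-channel covariance and weak,
non-stationary label signal the generator deliberately omits.

## Known limitations

* Real-dataset headline accuracies require the gated DEAP / DREAMER
  downloads; the loaders and protocol support them but no real-data result
  is claimed here.
* The element-wise attention's mixing-matrix shapes are one consistent
  reading of an under-determined operator; other shape choices change the
  parameter/FLOP totals, which is why the audit reports rather than asserts
  the comparison.
* Cross-subject transfer, hyperparameter search, interpolated topographic
  maps and alternative enhancement transforms (exponential, 1−M) are out of
  scope.
* CPU-only: a full 32-subject × 5-fold × 100-epoch run is feasible but
  slow in NumPy; the package targets method transparency and desk-scale
  experiments.
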