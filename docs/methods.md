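# Methods

## Problem and model

`tffusion` implements self-supervised representation learning for
fixed-length windows of multichannel physiological-style time series
(EEG sleep stages, accelerometry, gesture traces), where labels are
scarce but unlabeled windows are plentiful. The pretext task is
instance discrimination: an encoder `f : R^{S x T} -> R^D` is trained so
that a window and an augmented view of itself ("positive pair") land
close in embedding space while views of other windows in the same batch
("negatives") are pushed apart. A classifier head `g : R^D -> R^C` is
then fine-tuned on a small labeled split.

The distinguishing element is how the augmented view is built. Two
views are drawn per window:

- a **time-domain view** from a bank of four stochastic operators —
  jitter (additive Gaussian noise), scaling (one uniform factor per
  window), permutation (shuffle of near-equal time segments), masking
  (a fixed fraction of time points set to a constant);
- a **frequency-domain view**: the window's one-sided FFT is perturbed
  by a bank of four spectral operators — brick-wall low-pass, phase
  perturbation (per-bin Gaussian noise plus one global uniform(-pi, pi)
  shift per window), random bin removal, random bin addition — and
  inverse-transformed back to a real time series.

Each operator fires independently per window with probability
`p = 0.25`, so one operator per bank fires in expectation. The two
views are then **fused at the data level** with a pair of kernel PCAs:

    fused = KernelPCA_t(flatten(view_t)) (+) KernelPCA_f(flatten(view_f))

i.e. each flattened view is mapped to its top-C kernel principal
component scores and the two score vectors are concatenated, zero-padded
to a multiple of S and reshaped to `(S, ceil(2C/S))`. The fused vector
re-enters the shared encoder, whose adaptive average pooling makes the
altered "window length" harmless.

Training minimizes the NT-Xent loss over the 2N-sample pool of a batch
(original windows + fused views),

    L_{i,j} = -log[ exp(sim(z_i, z_j)/tau) / sum_{k != i} exp(sim(z_i, z_k)/tau) ]
    L = (1/N) sum_i (1/2) (L_{i,i'} + L_{i',i})

with cosine similarity, temperature `tau`, and `z` the output of a
2-layer projection MLP (FC-BN-ReLU-FC) that is discarded after
pre-training; fine-tuning consumes encoder embeddings directly
(standard SimCLR-family protocol).

## Architecture and numerics

The encoder is three 1-D residual blocks
(conv-BN-ReLU-conv-BN + identity/1x1 shortcut, then ReLU) with default
widths 32/64/128, kernel width 7, followed by global (adaptive, one-bin)
average pooling and a linear map to `D = 128`. The classification head
is FC(256)-ReLU-dropout(0.2)-FC(128)-ReLU-dropout(0.2)-FC(C)-softmax.

Because the package targets a plain scientific-Python stack, the
networks, the NT-Xent gradients, and the Adam optimizer are implemented
directly in NumPy with hand-written backpropagation. Every layer's
backward pass and the loss gradient are validated against central
finite differences in the test suite; this is a first-class design
choice, not an approximation — in eval mode the forward pass is exactly
deterministic, which is what makes the bit-reproducibility guarantees
below possible.

Numerical conventions worth knowing:

- One-sided (real-input) FFT everywhere, so conjugate symmetry — and a
  real-valued inverse — is automatic. The DC bin and, for even T, the
  Nyquist bin are held real under phase and addition edits.
- Kernel PCA branches are backed by `sklearn.decomposition.KernelPCA`
  (default RBF with `gamma = 1/(S*T)`, `C = min(floor(S*T/2), n_fit-1)`;
  with the default C the fused view has the same shape as the input).
  Eigenvector signs are fixed to "largest-magnitude loading positive"
  so transforms are reproducible across runs. The pair is fitted once
  per pre-training run on a capped (default 1000 rows), seeded
  subsample of augmented pretrain windows — per-batch refitting would
  make representations depend on batch composition.
- The NT-Xent batch drops incomplete trailing batches so every
  denominator sees a fixed 2N pool.
- Augmentations are re-drawn each epoch from an RNG substream keyed by
  `(seed, epoch, window index)`, making results independent of batch
  partitioning and bit-reproducible.
- Stride for sliding windows is `round(T * (1 - overlap))` (round half
  to even); trailing partial windows are dropped.
- During a contrastive step the two views pass through the network
  sequentially (view A is re-forwarded before its backward pass to
  restore layer caches), so batch-norm running statistics see view A
  twice per step; statistics are deterministic and this has no effect
  on gradients.

## Deliberately open choices

Several quantities of the modeled setting are not pinned down by the
experimental description this package follows; the defaults below are
the package's own choices, all exposed in the config:

- scaling-factor law: uniform on (0.9, 1.1) (the stated experimental
  range) rather than Gaussian; configurable;
- mask value 0; permutation segment count 4; masked time indices shared
  across channels (point-in-time dropout), per-channel masking optional;
- low-pass keeps the lower 50% of bins; phase-noise sd 0.1 rad;
  added-component magnitude 0.1 x the per-channel spectral maximum;
- operator composition order fixed (jitter-scale-permute-mask;
  lowpass-phase-remove-add) for reproducibility; each operator is an
  independent Bernoulli(p) per window;
- temperature 0.2, batch 128, L2 coefficient 1e-5;
- the frequency-augmented branch is inverse-transformed to the time
  domain before fusion (it is literally a "time series" again); head
  dropout after both hidden layers; fine-tuning updates the whole
  network by default (`freeze_encoder` available), up to 50 epochs with
  early stopping (patience 10) on the fine-tune-split loss;
- splits are window-wise and stratified by class.

## Synthetic data: what it emulates and what it does not

`generate_dataset` produces balanced classes whose noise-free templates
combine one spectral cue (a unit sinusoid at bin `3 + 3c`, classes at
least 3 bins apart to avoid leakage) and one temporal cue (a unit
square pulse whose onset advances with the class), plus white Gaussian
noise (default sd 1.5, about -5 dB SNR against either cue — the regime
where class structure sits below the noise floor, as in single-channel
EEG). Both cue families must be present for the time-only /
freq-only / fused ablation to be meaningful; `cues="spectral"` or
`"temporal"` restricts the templates for targeted probes.

What synthetic passes do **not** show about real data: stationary
Gaussian noise (no 1/f background, artifacts, or non-stationarity),
exactly balanced classes, windows i.i.d. given the class (no
subject-level correlation — real splits should be subject-wise), and
cue geometry far simpler than physiological waveforms. Passing here
demonstrates the machinery and its expected orderings, not clinical
performance.

## The desk-scale benchmark

`tffusion.benchmark` fixes the package's standard end-to-end check:
3 classes, S=1, T=128, 501 windows (167/class) split 60/20/20 into
300/99/102 pretrain/finetune/test; encoder narrowed to 8/16/32 with
D=64; 30 pre-training epochs, Adam lr 1e-3, batch 64; fine-tuning at
lr 3e-4, batch 32, up to 100 epochs with patience 10. The
small-problem learning rates are deliberate: the headline-scale recipe
(lr 1e-4, 100 epochs, batch 128) is calibrated for datasets with
thousands of optimizer steps per epoch, while this benchmark has four —
at 1e-4 nothing moves, and full-network fine-tuning at 1e-3
catastrophically overwrites pre-trained features. lr 3e-4 for
fine-tuning is the standard one-notch-lower rate for updating
pre-trained weights.

Observed 3-seed means (seeds 1-3; recomputed by the test suite and
`scripts/acceptance.py`): fused tf-fc ≈ 0.93 test accuracy, freq-only
≈ 0.91, time-only ≈ 0.86, random-init fine-tune ≈ 0.78 — the fused
pretext task at least matches the better single-domain task and clearly
beats no pre-training, the qualitative ordering this framework claims.
Seed-to-seed spread of a few points is expected at this problem size.

## Known limitations

- NumPy convolutions are CPU-bound; the full-width default encoder at
  100 epochs is a long run on one core. The benchmark sizes above are
  the supported fast path.
- Kernel-PCA fusion is transductive in spirit: fused views depend on
  the fitted subsample; transform of far-out-of-distribution windows
  can saturate the RBF kernel.
- No subject-wise splitting is provided (the synthetic generator has no
  subjects).
- The loss history records the NT-Xent term only; the L2 penalty enters
  gradients but not the logged value.
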