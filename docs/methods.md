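# Methods

`mviteeg` implements an epileptic-seizure-prediction pipeline for
multichannel EEG: clips labelled *preictal* (the hour before a seizure,
excluding a five-minute offset immediately before onset) or *interictal*
(at least four hours from any seizure) are segmented, converted to
time–frequency images, and classified by a multi-channel vision transformer
(MViT) with one encoder branch per EEG channel. Evaluation is
leave-one-subject-out (LOSO): every fold holds out all data of one subject,
so reported performance reflects generalisation to unseen patients.

## Data model and preprocessing

A clip is an `N × D` array of amplitudes in microvolts at sampling rate
`fs`, with a clip-level label (labels are never assigned per sample; segments
inherit their clip's label). Ten-minute clips at 256 Hz (scalp montages,
N = 23) hold 153,600 samples per channel; at 400 Hz (invasive recordings,
N = 16) they hold 240,000. Each clip is split into non-overlapping 10-s
segments — 60 per 10-min clip, 2560 or 4000 samples per channel — and any
trailing remainder is dropped. Scalp recordings with 24 or 26 electrodes are
reduced to the first 23 channels in recording order; the choice is arbitrary
but deterministic, and recorded here because no principled reduction exists
without montage information.

Each segment channel is mapped to a scalogram: the squared magnitude of its
continuous wavelet transform. The mother wavelet is the analytic Morlet
`ψ(t) = π^(−1/4) e^(iω₀t) e^(−t²/2)` with ω₀ = 6, the standard choice for
EEG time–frequency analysis; its scale-to-frequency map is
`f = ω₀ / (2πs)`. One hundred scales are placed so that centre frequencies
are log-spaced on [0.5 Hz, min(fs/2, 50 Hz)], covering the clinical EEG
bands; rows are stored highest-frequency first. The transform is an exact
zero-padded discrete convolution with the explicitly sampled, L2-normalised
wavelet (truncated at |t| ≤ 5·scale, where the Gaussian envelope is below
4·10⁻⁶), evaluated by FFT. The cone of influence is not masked. Because the
convolution is exact rather than an integral approximation, the transform can
be verified sample-for-sample against a direct time-domain convolution; the
test suite does this, and separately cross-checks frequency localisation
against PyWavelets' complex-Morlet implementation.

For modelling, raw `100 × d` power images are impractical token grids, so the
default pipeline applies, in order: `log1p` (compresses the heavy-tailed
power distribution), bilinear resize to a configurable `(H, W)` — 64 × 256 by
default, 32 × 64 in the desk-scale benchmark — and per-image z-scoring
(removes overall gain, which shifts between subjects and would otherwise be
an easy but non-generalising cue). Each step can be disabled; the full
configuration is written into every scalogram-store manifest so stored
tensors are re-derivable.

## Model

Each channel's image is split into non-overlapping `P_h × P_w` patches
(rectangular patches generalise square ones because the default images are
non-square), giving `L = HW/(P_h P_w)` tokens per branch. Patches are
flattened row-major, linearly projected to the latent dimension `D_e`, and
added to learned per-branch position embeddings. There is no class token.
Each branch runs `depth` pre-norm encoder blocks

    u   = tokens + MSA(LN(tokens))
    out = u + MLP(LN(u)),   MLP = linear → GELU → linear,

with multi-head scaled dot-product attention (softmax over keys, scale
`1/√(D_e/heads)`). Branch outputs are mean-pooled over tokens, concatenated
in channel order into an `N·D_e` vector, and classified by an MLP head with a
softmax. Branches are independent up to the aggregation point — perturbing
one channel cannot change another branch's feature — which is the defining
property of the multi-channel design and is asserted structurally in tests.
A `share_branch_weights` switch ties all branch parameters; the default is
untied (channels are distinct inputs), but sharing is the right reading when
channels are statistically exchangeable, as in the synthetic benchmark below.

The forward and backward passes are written directly in NumPy (float64).
Gradients are exact: the cross-entropy gradient uses the softmax identity
`∂loss/∂logits = p − onehot` with the log guarded only at the float floor,
and the whole backward pass is validated against central finite differences
to 10⁻⁴ relative on small configurations. Weights initialise from a
truncated normal (σ = 0.02, resampled beyond 2σ); biases and LayerNorm
offsets start at zero, LayerNorm gains at one. Dropout (inverted, default
rate 0.1) applies during training to the attention and MLP residual
contributions and the head's hidden activation; evaluation is deterministic.

Default architecture: depth 4, 4 heads, `D_e` 64, MLP hidden 128, patch
8 × 8 on 64 × 256 images (L = 256). These are package choices — recorded in
every checkpoint and report — not values inherited from prior work.

## Training and evaluation

Training minimises class-weighted cross-entropy (inverse-frequency weights,
so no interictal data is discarded under imbalance) with Adam
(β = 0.9/0.999). The validation split is made at clip level within the
training subjects — segments of one clip are correlated, so a segment-level
split would leak — and early stopping monitors validation AUC with the
best-validation-AUC parameters returned. Library defaults: learning rate
1e-4, batch 32, up to 50 epochs, patience 5, validation fraction 0.2. All
randomness (split, initialisation, shuffling, dropout) derives from one seed;
identical inputs and seeds reproduce checkpoints bit-exactly.

Evaluation is segment-level: each 10-s segment is one decision at threshold
0.5 (configurable; a threshold-sweep utility emits the full ROC). Reported
metrics: SENS = TP/(TP+FN), SPEC = TN/(TN+FP), ACC = (TP+TN)/all, AUC as the
pairwise-concordance probability (ties half), and FPR/h = false positives per
interictal hour evaluated, each 10-s segment contributing 1/360 h. The FPR/h
definition is a declared convention — segment-wise, with no alarm
post-processing. Metrics whose class is absent are reported as undefined,
never as zero. All metrics are recomputable from the stored per-segment
prediction CSVs, which the tests verify.

## Synthetic data

The generator produces the one statistical contrast the method relies on —
preictal segments carry more power than interictal ones in the same
time–frequency scales — with none of the confounds of real EEG. Interictal
activity is per-channel pink (1/f) noise (spectrum shaped by 1/√f with a
0.1 Hz floor, base RMS 10 µV) scaled by a per-subject gain drawn log-uniform
on [0.7, 1.4], so LOSO folds face inter-subject amplitude shift. A matched
preictal clip shares the identical background realisation and adds (i) a
band-limited oscillation whose envelope ramps linearly from zero to
`snr · RMS(background)` across the clip, emulating power build-up towards
onset, and (ii) Poisson-timed 70-ms biphasic bursts (half-sine up, half-sine
down, amplitude 3·RMS) at a default 6/min. The entire signature — bursts
included — is present only when `snr > 0`, so the `snr = 0` dataset is an
exact null: preictal and interictal arrays are bit-identical. Random streams
are seeded per (subject, clip, channel, role), making regeneration
reproducible clip by clip.

What this emulates: labelled clip collections, spectral contrast, subject
heterogeneity. What it does not: real seizure dynamics, artifacts (EMG, eye
blink, electrode pops), non-stationary background, montage structure, or
channel-specific physiology. Passing the benchmark therefore demonstrates
that the pipeline learns and generalises a spectral contrast across subjects
— not clinical performance.

## The desk-scale benchmark

`mviteeg.benchmark` fixes a study small enough to run end-to-end on one CPU
in a few minutes: 4 subjects × (10 preictal + 10 interictal) clips of 120 s,
4 channels at 100 Hz, snr 2 in the 18–24 Hz band; scalograms resized to
32 × 64; model with 8 × 8 patches, `D_e` 32, depth 2, 2 heads, MLP hidden 64
(twice `D_e`, matching the default ratio). Because the four synthetic
channels are exchangeable by construction, the benchmark shares branch
weights, which quadruples the data each branch sees. It trains with learning
rate 3e-4 and patience 8: the small problem tolerates the larger step, and
at the library defaults the benchmark model stops before convergence (a
Welch band-power oracle reaches AUC ≈ 0.99 on the same segments, so the
residual gap at the defaults is an optimisation artifact, not missing
information). Ramp-up makes early-clip preictal segments genuinely hard —
near the clip start the signature is close to zero — so segment-level
sensitivity saturates below 1 by design.

`scripts/acceptance.py` reruns this benchmark from scratch (generation →
scalograms → per-fold training → pooled LOSO metrics at threshold 0.5) plus
the matched `snr = 0` null control, whose pooled AUC should sit near 0.5.

## Numerical choices and limitations

* Float64 throughout; attention softmax is max-shifted; LayerNorm ε = 1e-5.
* Bilinear resize (no anti-aliasing) keeps the pipeline exactly
  deterministic across runs and platforms.
* Ties in AUC count one half; thresholding uses `p ≥ t`.
* The per-fold training seed derives from (training seed, fold index), so
  folds are independent but the whole LOSO run is reproducible from one
  integer.
* The NumPy implementation favours verifiability over speed: it is adequate
  for desk-scale studies and oracle testing, not for full CHB-MIT/Kaggle
  scale training.
* EDF reading trusts the file's physical-dimension calibration and converts
  to microvolts; EDF is an int16 format, so round-trips through EDF are exact
  only on the quantisation grid.
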