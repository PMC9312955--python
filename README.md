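# mviteeg

Seizure prediction from multichannel EEG with continuous-wavelet-transform
scalograms and a **multi-channel vision transformer (MViT)** — one
transformer-encoder branch per EEG channel — evaluated with
leave-one-subject-out cross-validation.

## Who this is for

Researchers working on EEG-based seizure prediction who want a transparent,
fully testable reference implementation of the scalogram + ViT approach:
every stage, from clip ingestion to the attention arithmetic to the
FPR-per-hour metric, is plain NumPy/SciPy with exact oracles in the test
suite (the backward pass is checked against finite differences, the CWT
against a direct time-domain convolution).

## The method

EEG arrives as 10-min clips labelled *preictal* (the hour before seizure
onset minus a 5-min offset) or *interictal* (≥ 4 h from any seizure), at
256 Hz/23 channels (scalp) or 400 Hz/16 channels (invasive). Each clip is
split into 60 non-overlapping 10-s segments; each segment channel becomes a
scalogram — wavelet power |W(s, t)|² under an analytic Morlet (ω₀ = 6) on
100 log-spaced centre frequencies in [0.5, 50] Hz — then log-compressed,
resized, and z-scored.

Each channel's image x ∈ R^{H×W} is split into non-overlapping patches
x_p ∈ R^{L×P_hP_w}, L = HW/(P_h P_w), linearly projected to D_e dimensions,
given learned position embeddings, and encoded by pre-norm transformer
blocks (u = x + MSA(LN(x)); out = u + MLP(LN(u))). The N branch outputs are
mean-pooled, concatenated, and classified preictal vs. interictal by an MLP
head. Performance is reported as SENS, SPEC, ACC, AUC, and false positives
per interictal hour (FPR/h), at segment level, pooled over LOSO folds.

A synthetic-data module generates labelled clips with the statistical
premise the method relies on — preictal power elevation in a chosen band,
ramping toward "onset", over a pink-noise background with per-subject gain —
so the whole pipeline is testable with no data download. See
`docs/methods.md` for the model, assumptions, and limitations.

## Worked example

```python
from mviteeg import (SynthConfig, generate_dataset, ScalogramConfig,
                     MViTConfig, TrainConfig, run_loso)

clips = generate_dataset(SynthConfig(n_subjects=4, clips_per_class=10,
                                     n_channels=4, fs=100, clip_len_s=120,
                                     snr=2.0, sig_band=(18, 24), seed=1))
result = run_loso(
    clips,
    ScalogramConfig(log_power=True, resize_to=(32, 64), normalize=True),
    MViTConfig(n_branches=4, image_hw=(32, 64), patch_hw=(8, 8), embed_dim=32,
               depth=2, n_heads=2, mlp_hidden=64, share_branch_weights=True),
    TrainConfig(learning_rate=3e-4, patience=8, seed=1),
)
r = result.pooled_report
print(f"AUC {r.auc:.3f}  SENS {r.sens:.3f}  SPEC {r.spec:.3f}  "
      f"ACC {r.acc:.3f}  FPR/h {r.fpr_per_hour:.2f}")
```

Output (4 LOSO folds, 960 held-out 10-s segments):

```
AUC 0.971  SENS 0.910  SPEC 0.977  ACC 0.944  FPR/h 8.25
```

AUC 0.971 means a random preictal segment outscores a random interictal one
97% of the time on held-out subjects; SENS/SPEC are the segment-level hit
rates at threshold 0.5; FPR/h counts false alarms per interictal hour (here
8.25/h at segment granularity — no alarm smoothing is applied). Preictal
segments near the start of a clip carry almost no signature yet (the
synthetic power ramp starts at zero), so sensitivity below 1 is expected.

The same pipeline runs from the shell:

```bash
mviteeg simulate --config run.yaml --out clips/
mviteeg run-all  --config run.yaml --out results/   # simulate → scalograms → LOSO
```

Real data enters through `read_edf_clips` (EDF recordings + labelled
intervals) or `read_competition_clip` (MAT v5/HDF5 10-min clip containers).

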