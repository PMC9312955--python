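"""LOSO fold structure, training behaviour, and evaluation plumbing on small
synthetic problems."""

import numpy as np
import pytest

from mviteeg.errors import DataError, TrainingError
from mviteeg.metrics import auc_rank
from mviteeg.model import MViTConfig
from mviteeg.preprocess import ScalogramConfig, clip_to_scalograms
from mviteeg.train import (
    TrainConfig,
    evaluate,
    loso_splits,
    run_loso,
    stacks_to_arrays,
    train,
)

SCAL = ScalogramConfig(n_scales=32, f_min=1.0, f_max=None, log_power=True,
                       resize_to=(16, 32), normalize=True)
MODEL = MViTConfig(n_branches=2, image_hw=(16, 32), patch_hw=(4, 4), embed_dim=16,
                   depth=1, n_heads=2, mlp_hidden=24, dropout=0.0)
FAST = TrainConfig(learning_rate=3e-4, batch_size=16, max_epochs=8, patience=8,
                   val_fraction=0.25, seed=0)


@pytest.fixture(scope="module")
def tiny_stacks(tiny_synth_clips):
    _, clips = tiny_synth_clips
    return clips, [s for c in clips for s in clip_to_scalograms(c, SCAL)]


# ---------------------------------------------------------------------------
# splits


def test_loso_folds_partition_clips(tiny_synth_clips):
    _, clips = tiny_synth_clips
    folds = loso_splits(clips)
    assert len(folds) == 2
    all_test = [cid for f in folds for cid in f.test_ids]
    assert sorted(all_test) == sorted(c.clip_id for c in clips)
    by_id = {c.clip_id: c.subject_id for c in clips}
    for f in folds:
        train_subjects = {by_id[c] for c in f.train_ids}
        test_subjects = {by_id[c] for c in f.test_ids}
        assert not train_subjects & test_subjects
        assert test_subjects == {f.test_subject}


def test_loso_unequal_clip_counts():
    from mviteeg.synthetic import SynthConfig, generate_dataset

    a = generate_dataset(SynthConfig(n_subjects=1, clips_per_class=3, n_channels=1,
                                     fs=100, clip_len_s=10, seed=1))
    b = generate_dataset(SynthConfig(n_subjects=1, clips_per_class=1, n_channels=1,
                                     fs=100, clip_len_s=10, seed=2))
    for c in b:
        c.subject_id = "subjZZ"
    folds = loso_splits(a + b)
    sizes = {f.test_subject: len(f.test_ids) for f in folds}
    assert sizes == {"subj00": 6, "subjZZ": 2}


def test_loso_single_subject_rejected():
    from mviteeg.synthetic import SynthConfig, generate_dataset

    clips = generate_dataset(SynthConfig(n_subjects=1, clips_per_class=1, n_channels=1,
                                         fs=100, clip_len_s=10, seed=3))
    with pytest.raises(DataError):
        loso_splits(clips)


# ---------------------------------------------------------------------------
# training


def test_training_loss_decreases(tiny_stacks):
    _, stacks = tiny_stacks
    _, log = train(stacks, MODEL, FAST)
    assert log[-1]["train_loss"] < log[0]["train_loss"]


def test_training_reproducible_bit_exact(tiny_stacks):
    _, stacks = tiny_stacks
    p1, log1 = train(stacks, MODEL, FAST)
    p2, log2 = train(stacks, MODEL, FAST)
    assert log1 == log2
    for k in p1:
        assert np.array_equal(p1[k], p2[k])


def test_single_class_training_rejected(tiny_stacks):
    _, stacks = tiny_stacks
    only_pre = [s for s in stacks if s.label == "preictal"]
    with pytest.raises(TrainingError):
        train(only_pre, MODEL, FAST)


def test_validation_split_is_clip_level(tiny_stacks):
    """No clip may straddle the train/validation boundary."""
    from mviteeg.train import _clip_level_val_split

    _, stacks = tiny_stacks
    tr, va = _clip_level_val_split(stacks, 0.25, np.random.default_rng(0))
    tr_clips = {stacks[i].clip_id for i in tr}
    va_clips = {stacks[i].clip_id for i in va}
    assert not tr_clips & va_clips
    assert len(tr) + len(va) == len(stacks)


def test_permuted_labels_give_chance_auc(tiny_synth_clips):
    """Clip-level label permutation destroys the signal: held-out AUC is near
    chance (mean over 5 seeds within [0.35, 0.65])."""
    _, clips = tiny_synth_clips
    train_clips = [c for c in clips if c.subject_id == "subj00"]
    test_clips = [c for c in clips if c.subject_id == "subj01"]
    aucs = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        labels = [c.label for c in train_clips]
        perm = rng.permutation(len(labels))
        shuffled = []
        for c, j in zip(train_clips, perm):
            shuffled.append(
                type(c)(c.subject_id, c.clip_id, labels[j], c.fs, c.channel_names,
                        c.data, c.provenance)
            )
        stacks = [s for c in shuffled for s in clip_to_scalograms(c, SCAL)]
        test_stacks = [s for c in test_clips for s in clip_to_scalograms(c, SCAL)]
        cfg = TrainConfig(learning_rate=3e-4, batch_size=16, max_epochs=5,
                          patience=5, val_fraction=0.25, seed=seed)
        params, _ = train(stacks, MODEL, cfg)
        preds, _ = evaluate(params, MODEL, test_stacks)
        aucs.append(auc_rank(preds.y_true, preds.probabilities))
    assert 0.35 <= float(np.mean(aucs)) <= 0.65


# ---------------------------------------------------------------------------
# evaluation & LOSO


def test_evaluate_produces_one_record_per_segment(tiny_stacks):
    _, stacks = tiny_stacks
    params, _ = train(stacks, MODEL, FAST)
    preds, report = evaluate(params, MODEL, stacks)
    assert len(preds) == len(stacks)
    assert report.tp + report.fn + report.tn + report.fp == len(stacks)
    assert np.all((preds.probabilities >= 0) & (preds.probabilities <= 1))


def test_run_loso_counts_and_pooled_additivity(tiny_synth_clips):
    _, clips = tiny_synth_clips
    res = run_loso(clips, SCAL, MODEL, FAST)
    assert len(res.fold_reports) == 2  # 2 subjects -> 2 folds (+1 pooled report)
    assert res.pooled_report is not None
    fold_counts = np.array(
        [[r.tp, r.fn, r.tn, r.fp] for r in res.fold_reports.values()]
    ).sum(axis=0)
    pooled = res.pooled_report
    assert list(fold_counts) == [pooled.tp, pooled.fn, pooled.tn, pooled.fp]
    # pooled metrics reproducible from the stored prediction set
    from mviteeg.metrics import compute_metrics

    re = compute_metrics(res.pooled_predictions, pooled.threshold)
    assert re.to_dict() == pooled.to_dict()


def test_stacks_to_arrays_label_coding(tiny_stacks):
    _, stacks = tiny_stacks
    X, y = stacks_to_arrays(stacks)
    assert X.shape[0] == len(stacks)
    assert set(y) == {0, 1}
    for s, yi in zip(stacks, y):
        assert yi == (1 if s.label == "preictal" else 0)
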