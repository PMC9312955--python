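"""Training and leave-one-subject-out evaluation.

Training minimises class-weighted cross-entropy with Adam on segment
scalogram stacks.  The validation split is made at clip level (never segment
level) within the training subjects, so segments of one clip can never sit on
both sides of the split; early stopping monitors validation AUC and the
best-validation-AUC parameters are returned.

LOSO: one fold per subject, the held-out subject's clips form the test set,
everything else trains.  The pooled report is computed over the union of all
test-fold prediction sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError, TrainingError
from .io import EEGClip
from .metrics import MetricsReport, PredictionSet, auc_rank, compute_metrics
from .model import MViTConfig, init_params, forward, loss_and_grads
from .preprocess import ScalogramConfig, ScalogramStack, clip_to_scalograms

logger = logging.getLogger(__name__)

_LABEL_TO_CLASS = {"interictal": 0, "preictal": 1}


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam)."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 50
    class_weighting: bool = True
    patience: int = 5
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigError(f"val_fraction must be in (0,1), got {self.val_fraction}")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("learning_rate, batch_size, max_epochs must be positive")


@dataclass
class LOSOFold:
    """One cross-validation fold: all of one subject's clips held out."""

    test_subject: str
    train_ids: list[str]
    test_ids: list[str]


def loso_splits(clips: Sequence[EEGClip]) -> list[LOSOFold]:
    """Leave-one-subject-out folds over a labelled clip collection.

    One fold per subject (sorted order); test = that subject's clips, train =
    everyone else's.  Folds partition the collection."""
    subjects = sorted({c.subject_id for c in clips})
    if len(subjects) < 2:
        raise DataError("LOSO needs at least 2 subjects")
    folds = []
    for s in subjects:
        test = [c.clip_id for c in clips if c.subject_id == s]
        train = [c.clip_id for c in clips if c.subject_id != s]
        folds.append(LOSOFold(test_subject=s, train_ids=train, test_ids=test))
    return folds


# ---------------------------------------------------------------------------
# data marshalling


def stacks_to_arrays(stacks: Sequence[ScalogramStack]) -> tuple[np.ndarray, np.ndarray]:
    """(images, labels) arrays from scalogram stacks; labels 1 = preictal."""
    X = np.stack([s.images for s in stacks]).astype(np.float64)
    y = np.array([_LABEL_TO_CLASS[s.label] for s in stacks], dtype=int)
    return X, y


def _clip_level_val_split(
    stacks: Sequence[ScalogramStack], val_fraction: float, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Split stack indices into train/val so no clip straddles the split.

    Clips are split per label (stratified), at least one validation clip per
    label where possible."""
    by_clip: dict[str, list[int]] = {}
    clip_label: dict[str, str] = {}
    for i, s in enumerate(stacks):
        by_clip.setdefault(s.clip_id, []).append(i)
        clip_label[s.clip_id] = s.label
    train_idx: list[int] = []
    val_idx: list[int] = []
    for label in sorted({*clip_label.values()}):
        ids = sorted(c for c, l in clip_label.items() if l == label)
        perm = rng.permutation(len(ids))
        n_val = max(1, int(round(val_fraction * len(ids)))) if len(ids) > 1 else 0
        val_ids = {ids[j] for j in perm[:n_val]}
        for c in ids:
            (val_idx if c in val_ids else train_idx).extend(by_clip[c])
    return sorted(train_idx), sorted(val_idx)


def _class_weights(y: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled:
        return np.ones(2)
    counts = np.bincount(y, minlength=2).astype(float)
    # inverse-frequency, normalised to mean 1
    w = len(y) / (2.0 * np.maximum(counts, 1.0))
    return w


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _batched_probs(X: np.ndarray, params, cfg, batch: int = 64) -> np.ndarray:
    out = np.empty((len(X), cfg.n_classes))
    for a in range(0, len(X), batch):
        out[a : a + batch] = forward(X[a : a + batch], params, cfg)
    return out


def train(
    stacks: Sequence[ScalogramStack],
    model_cfg: MViTConfig,
    train_cfg: TrainConfig,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Train an MViT on segment scalogram stacks.

    Returns the best-validation-AUC parameters and the per-epoch training log
    (loss, validation AUC).  Fully seeded: identical inputs and seeds give
    identical checkpoints."""
    labels = {s.label for s in stacks}
    if not {"preictal", "interictal"} <= labels:
        raise TrainingError(f"training data must contain both classes, got {sorted(labels)}")

    children = np.random.SeedSequence(train_cfg.seed).spawn(4)
    split_rng = np.random.default_rng(children[0])
    init_seed = int(children[1].generate_state(1)[0] % (2**31))
    shuffle_rng = np.random.default_rng(children[2])
    drop_rng = np.random.default_rng(children[3])
    tr_idx, va_idx = _clip_level_val_split(stacks, train_cfg.val_fraction, split_rng)
    X, y = stacks_to_arrays(stacks)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xva, yva = X[va_idx], y[va_idx]
    if len(set(ytr.tolist())) < 2:
        raise TrainingError("train split lost a class; lower val_fraction or add clips")
    weights = _class_weights(ytr, train_cfg.class_weighting)

    params = init_params(model_cfg, seed=init_seed)
    opt = _Adam(params, train_cfg.learning_rate)
    best_auc = -np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    since_best = 0
    log: list[dict] = []
    for epoch in range(train_cfg.max_epochs):
        order = shuffle_rng.permutation(len(Xtr))
        losses = []
        for a in range(0, len(order), train_cfg.batch_size):
            idx = order[a : a + train_cfg.batch_size]
            try:
                loss, grads, _ = loss_and_grads(
                    Xtr[idx], ytr[idx], params, model_cfg, weights, rng=drop_rng
                )
            except DataError as exc:
                raise TrainingError(f"divergence at epoch {epoch}: {exc}") from exc
            opt.step(params, grads)
            losses.append(loss)
        val_probs = _batched_probs(Xva, params, model_cfg)[:, 1] if len(Xva) else np.array([])
        val_auc = auc_rank(yva == 1, val_probs) if len(Xva) else None
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": val_auc}
        log.append(entry)
        logger.info("epoch %d loss %.4f val_auc %s", epoch, entry["train_loss"], val_auc)
        score = val_auc if val_auc is not None else -entry["train_loss"]
        if score > best_auc + 1e-12:
            best_auc = score
            best_params = {k: v.copy() for k, v in params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_cfg.patience:
                break
    return best_params, log


def evaluate(
    params: dict[str, np.ndarray],
    model_cfg: MViTConfig,
    stacks: Sequence[ScalogramStack],
    threshold: float = 0.5,
) -> tuple[PredictionSet, MetricsReport]:
    """Score test segments and compute the metric suite at the threshold."""
    X, _ = stacks_to_arrays(stacks)
    probs = _batched_probs(X, params, model_cfg)[:, 1]
    records = [
        {
            "subject_id": s.subject_id,
            "clip_id": s.clip_id,
            "segment_index": s.segment_index,
            "label": s.label,
            "probability": float(p),
            "duration_s": s.duration_s,
        }
        for s, p in zip(stacks, probs)
    ]
    preds = PredictionSet.from_records(records)
    return preds, compute_metrics(preds, threshold)


@dataclass
class LOSOResult:
    """Per-fold and pooled LOSO outputs."""

    fold_reports: dict[str, MetricsReport]
    fold_predictions: dict[str, PredictionSet]
    pooled_predictions: PredictionSet
    pooled_report: MetricsReport
    training_logs: dict[str, list[dict]] = field(default_factory=dict)


def run_loso(
    clips: Sequence[EEGClip],
    scal_cfg: ScalogramConfig,
    model_cfg: MViTConfig,
    train_cfg: TrainConfig,
    threshold: float = 0.5,
) -> LOSOResult:
    """Full leave-one-subject-out run.

    Scalograms are computed once per clip and shared across folds; one model
    is trained per fold with a fold-specific seed derived from the training
    seed; the pooled report aggregates the union of the held-out predictions."""
    folds = loso_splits(clips)
    stacks_by_clip: dict[str, list[ScalogramStack]] = {
        c.clip_id: clip_to_scalograms(c, scal_cfg) for c in clips
    }

    fold_reports: dict[str, MetricsReport] = {}
    fold_preds: dict[str, PredictionSet] = {}
    logs: dict[str, list[dict]] = {}
    for k, fold in enumerate(folds):
        train_stacks = [s for cid in fold.train_ids for s in stacks_by_clip[cid]]
        test_stacks = [s for cid in fold.test_ids for s in stacks_by_clip[cid]]
        assert not {s.subject_id for s in train_stacks} & {fold.test_subject}, "LOSO leakage"
        fold_seed = int(
            np.random.SeedSequence((train_cfg.seed, k)).generate_state(1)[0] % (2**31)
        )
        fold_cfg = TrainConfig(
            learning_rate=train_cfg.learning_rate,
            batch_size=train_cfg.batch_size,
            max_epochs=train_cfg.max_epochs,
            class_weighting=train_cfg.class_weighting,
            patience=train_cfg.patience,
            val_fraction=train_cfg.val_fraction,
            seed=fold_seed,
        )
        params, log = train(train_stacks, model_cfg, fold_cfg)
        preds, report = evaluate(params, model_cfg, test_stacks, threshold)
        fold_reports[fold.test_subject] = report
        fold_preds[fold.test_subject] = preds
        logs[fold.test_subject] = log
        logger.info(
            "fold %s: auc %s sens %s spec %s",
            fold.test_subject,
            report.auc,
            report.sens,
            report.spec,
        )
    pooled = PredictionSet.concat([fold_preds[f.test_subject] for f in folds])
    pooled_report = compute_metrics(pooled, threshold)
    return LOSOResult(
        fold_reports=fold_reports,
        fold_predictions=fold_preds,
        pooled_predictions=pooled,
        pooled_report=pooled_report,
        training_logs=logs,
    )
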