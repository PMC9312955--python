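"""Segment-level evaluation: predictions container and the metric suite.

Each 10-s segment is one decision.  At a stated probability threshold the
confusion counts give

    SENS = TP / (TP + FN)          (over preictal segments)
    SPEC = TN / (TN + FP)          (over interictal segments)
    ACC  = (TP + TN) / all
    FPR/h = FP / interictal hours evaluated   (a 10-s segment is 1/360 h)

and AUC is the probability that a uniformly random preictal segment outscores
a uniformly random interictal one, ties counted one half (equivalently the
trapezoidal ROC area).  Metrics whose class is absent from the test set are
reported as undefined (None), never as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

_COLUMNS = ["subject_id", "clip_id", "segment_index", "label", "probability", "duration_s"]


@dataclass
class PredictionSet:
    """Per-segment preictal probabilities with labels and provenance."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"prediction frame missing columns {missing}")
        p = self.frame["probability"].to_numpy()
        if len(p) and (p.min() < 0 or p.max() > 1):
            raise DataError("probabilities outside [0, 1]")

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "PredictionSet":
        return cls(pd.DataFrame(list(records), columns=_COLUMNS))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def probabilities(self) -> np.ndarray:
        return self.frame["probability"].to_numpy(dtype=float)

    @property
    def y_true(self) -> np.ndarray:
        return (self.frame["label"] == "preictal").to_numpy()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "PredictionSet":
        return cls(pd.read_csv(path))

    @staticmethod
    def concat(sets: Sequence["PredictionSet"]) -> "PredictionSet":
        return PredictionSet(pd.concat([s.frame for s in sets], ignore_index=True))


@dataclass
class MetricsReport:
    """SENS/SPEC/ACC/FPR-per-hour/AUC at a stated threshold.

    Undefined metrics (missing class) are None."""

    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int
    interictal_hours: float
    sens: float | None
    spec: float | None
    acc: float | None
    fpr_per_hour: float | None
    auc: float | None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "interictal_hours": self.interictal_hours,
            "sens": self.sens,
            "spec": self.spec,
            "acc": self.acc,
            "fpr_per_hour": self.fpr_per_hour,
            "auc": self.auc,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """AUC as pairwise concordance probability (ties count one half)."""
    y_true = np.asarray(y_true, dtype=bool)
    n_pos, n_neg = int(y_true.sum()), int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y_true, scores))


def compute_metrics(preds: PredictionSet, threshold: float = 0.5) -> MetricsReport:
    """Metric suite from a prediction set at the given decision threshold."""
    y = preds.y_true
    p = preds.probabilities
    pred_pos = p >= threshold
    tp = int(np.sum(y & pred_pos))
    fn = int(np.sum(y & ~pred_pos))
    fp = int(np.sum(~y & pred_pos))
    tn = int(np.sum(~y & ~pred_pos))
    dur = preds.frame["duration_s"].to_numpy(dtype=float)
    inter_hours = float(dur[~y].sum() / 3600.0)
    n = tp + fn + tn + fp
    return MetricsReport(
        threshold=threshold,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        interictal_hours=inter_hours,
        sens=tp / (tp + fn) if (tp + fn) else None,
        spec=tn / (tn + fp) if (tn + fp) else None,
        acc=(tp + tn) / n if n else None,
        fpr_per_hour=fp / inter_hours if inter_hours > 0 else None,
        auc=auc_rank(y, p),
    )


def roc_curve_points(preds: PredictionSet) -> pd.DataFrame:
    """Full threshold sweep: (threshold, fpr, tpr) rows for the ROC."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(preds.y_true, preds.probabilities)
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
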