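"""Metric protocol: validation-F1 threshold selection, per-image metrics
inside the eroded FOV, two-stage aggregation, and cross-database transfer.

The AUC of the ROC is the primary, threshold-free indicator; the binarized
metrics (sensitivity, specificity, F1, accuracy) use a single threshold
chosen to maximize the mean per-image F1 on the validation images.  All
metrics are restricted to the four-pixel-eroded FOV.  Aggregation follows a
two-stage rule: per test image, mean and (sample) standard deviation over
the training repetitions; those values are then averaged over the test
images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model_family import NetworkModel, predict_image
from .preprocessing import (
    FOV_EROSION_MARGIN,
    FundusSample,
    erode_fov,
    preprocess,
    resample_pair,
    restore_prediction,
)

__all__ = [
    "MetricsRecord",
    "AggregateRow",
    "METRICS",
    "THRESHOLD_GRID_SIZE",
    "select_threshold",
    "image_metrics",
    "aggregate",
    "predict_sample",
    "transfer_evaluate",
]

METRICS = ("auc", "sensitivity", "specificity", "f1", "accuracy")
THRESHOLD_GRID_SIZE = 256


@dataclass
class MetricsRecord:
    image_id: str
    rollout_id: int
    auc: float
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float

    def as_dict(self) -> dict:
        return {"image_id": self.image_id, "rollout_id": self.rollout_id,
                **{m: getattr(self, m) for m in METRICS}}


@dataclass
class AggregateRow:
    """Per-metric mean and standard deviation under the two-stage rule."""

    mean: dict
    std: dict
    n_images: int
    n_rollouts: int


def _f1(tp: int, fp: int, fn: int) -> float:
    if tp + fp + fn == 0:
        # no predicted and no true foreground: perfect degenerate agreement
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def _confusion(scores, y, threshold):
    pred = scores >= threshold
    tp = int(np.count_nonzero(pred & y))
    fp = int(np.count_nonzero(pred & ~y))
    fn = int(np.count_nonzero(~pred & y))
    tn = int(np.count_nonzero(~pred & ~y))
    return tp, fp, fn, tn


def threshold_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, THRESHOLD_GRID_SIZE)


def select_threshold(predictions, labels, fovs) -> float:
    """Grid threshold maximizing the mean per-image F1 on validation images.

    The search is exhaustive over a 256-point uniform grid on [0, 1]; ties
    resolve toward the smaller threshold.
    """
    preds = [np.asarray(p) for p in predictions]
    ys = [np.asarray(l).astype(bool) for l in labels]
    ms = [np.asarray(f).astype(bool) for f in fovs]
    if len(preds) == 0:
        raise ValueError("need at least one validation image")
    if not any(y[m].any() for y, m in zip(ys, ms)):
        raise ValueError("all validation labels are background; F1 undefined")
    grid = threshold_grid()
    mean_f1 = np.zeros_like(grid)
    for p, y, m in zip(preds, ys, ms):
        s, t = p[m], y[m]
        order = np.argsort(s)
        s_sorted = s[order]
        y_sorted = t[order]
        n_pos = int(t.sum())
        # cumulative positives below each grid threshold -> O(n log n) sweep
        idx = np.searchsorted(s_sorted, grid, side="left")
        cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
        fn = cum_pos[idx]                 # positives predicted negative
        tp = n_pos - fn
        fp = (len(s_sorted) - idx) - tp   # negatives at/above the threshold
        denom = 2 * tp + fp + fn
        f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 1.0)
        mean_f1 += f1
    mean_f1 /= len(preds)
    return float(grid[int(np.argmax(mean_f1))])


def image_metrics(pred: np.ndarray, label: np.ndarray, fov_eroded: np.ndarray,
                  threshold: float, image_id: str = "",
                  rollout_id: int = 0) -> MetricsRecord:
    """All five metrics of one prediction map inside the eroded FOV.

    AUC is computed on the unbinarized foreground probabilities (ties count
    one half); the remaining metrics binarize at ``threshold``.
    """
    m = np.asarray(fov_eroded).astype(bool)
    if not m.any():
        raise ValueError("empty eroded FOV")
    scores = np.asarray(pred, dtype=float)[m]
    y = np.asarray(label).astype(bool)[m]
    if y.all() or not y.any():
        raise ValueError("AUC undefined: single-class labels inside the FOV")
    auc = float(roc_auc_score(y, scores))
    tp, fp, fn, tn = _confusion(scores, y, threshold)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / m.sum()
    return MetricsRecord(image_id=image_id, rollout_id=rollout_id, auc=auc,
                         sensitivity=sens, specificity=spec,
                         f1=_f1(tp, fp, fn), accuracy=acc)


def aggregate(records) -> AggregateRow:
    """Two-stage aggregation of a complete image x roll-out grid.

    Per image: mean and sample standard deviation over the roll-outs (a
    single roll-out yields std 0 by convention).  The per-image values are
    then averaged over all images.
    """
    df = pd.DataFrame([r.as_dict() if isinstance(r, MetricsRecord) else dict(r)
                       for r in records])
    if df.empty:
        raise ValueError("no records to aggregate")
    counts = df.groupby("image_id")["rollout_id"].count()
    if counts.nunique() != 1:
        raise ValueError("incomplete image x roll-out grid")
    n_roll = int(counts.iloc[0])
    per_image_mean = df.groupby("image_id")[list(METRICS)].mean()
    if n_roll > 1:
        per_image_std = df.groupby("image_id")[list(METRICS)].std(ddof=1)
    else:
        per_image_std = per_image_mean * 0.0
    return AggregateRow(mean=per_image_mean.mean().to_dict(),
                        std=per_image_std.mean().to_dict(),
                        n_images=int(counts.size), n_rollouts=n_roll)


def predict_sample(model: NetworkModel, sample: FundusSample,
                   resample_factor: int = 1) -> np.ndarray:
    """Preprocess one sample with its database's resampling factor, run
    whole-image inference and restore the prediction to annotation shape."""
    pre = preprocess(sample)
    if resample_factor > 1:
        pre = resample_pair(pre, resample_factor)
    prob = predict_image(model, pre.values)
    return restore_prediction(prob, sample.fov.shape)


def transfer_evaluate(model: NetworkModel, samples, threshold: float,
                      resample_factor: int = 1, rollout_id: int = 0,
                      erosion_margin: int = FOV_EROSION_MARGIN):
    """Evaluate a trained model on another database without retraining.

    The binarization threshold is carried over from the source database (the
    AUC, the headline transfer metric, is threshold-free).  Returns the
    per-image records and their aggregate.
    """
    records = []
    for sample in samples:
        pred = predict_sample(model, sample, resample_factor)
        fov_e = erode_fov(sample.fov, erosion_margin)
        records.append(image_metrics(pred, sample.annotation, fov_e,
                                     threshold, image_id=sample.image_id,
                                     rollout_id=rollout_id))
    return records, aggregate(records)
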