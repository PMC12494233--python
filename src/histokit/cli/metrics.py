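"""Pixel-wise segmentation evaluation metrics.

Any positive label counts as foreground; metrics are the standard
confusion-matrix quantities.  Degenerate conventions: precision is 0
(with ``degenerate=True``) when nothing is predicted, recall is 0 when
the truth is empty, F1 is 0 when precision + recall is 0, IoU is 1 when
both masks are empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["evaluate_segmentation", "EvalReport", "aggregate_reports"]


@dataclass
class EvalReport:
    precision: float
    recall: float
    accuracy: float
    f1: float
    iou: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "iou": self.iou,
            "degenerate": self.degenerate,
        }


def evaluate_segmentation(pred, truth) -> EvalReport:
    """Pixel-wise binary metrics of a predicted labeling against truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred > 0
    t = truth > 0
    tp = float(np.count_nonzero(p & t))
    fp = float(np.count_nonzero(p & ~t))
    fn = float(np.count_nonzero(~p & t))
    tn = float(np.count_nonzero(~p & ~t))

    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    union = tp + fp + fn
    iou = tp / union if union > 0 else 1.0
    return EvalReport(precision, recall, accuracy, f1, iou, degenerate)


def aggregate_reports(reports) -> dict:
    """Mean and std of each metric over per-tile reports."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to aggregate")
    out = {}
    for name in ("precision", "recall", "accuracy", "f1", "iou"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[name] = {"mean": float(vals.mean()), "std": float(vals.std())}
    return out
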