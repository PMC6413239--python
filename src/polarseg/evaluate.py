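"""Correctness criterion and accuracy accounting for detection results.

A prediction on a positive image counts as correct when its centroid lies
strictly within ``tol`` pixels (default 10, Euclidean) of the ground-truth
centroid; on a negative image, declaring "no polar body" is the correct
answer.  A missed detection on a positive image and a spurious detection
on a negative image are both incorrect.  Accuracy is tallied overall and
per class (positive / negative), with per-sample records retained so that
failures can be traced to individual images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import DetectionResult
from .io import LabelMask

__all__ = ["GroundTruth", "EvalReport", "is_correct", "evaluate", "truth_from_mask"]

DEFAULT_TOL_PX = 10.0


@dataclass(frozen=True)
class GroundTruth:
    present: bool
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.present != (self.centroid is not None):
            raise ValueError("centroid must be given exactly when present")


def truth_from_mask(mask: LabelMask) -> GroundTruth:
    """Ground truth from an annotation mask: present iff the mask is
    nonempty, centroid = mean of foreground pixel locations."""
    c = mask.foreground_centroid()
    return GroundTruth(present=c is not None, centroid=c)


def _distance(a: tuple[float, float], b: tuple[float, float], norm: str) -> float:
    dr, dc = a[0] - b[0], a[1] - b[1]
    if norm == "euclidean":
        return float(np.hypot(dr, dc))
    if norm == "chebyshev":
        return float(max(abs(dr), abs(dc)))
    raise ValueError(f"unknown norm {norm!r}")


def is_correct(
    pred: DetectionResult,
    truth: GroundTruth,
    tol: float = DEFAULT_TOL_PX,
    norm: str = "euclidean",
) -> bool:
    """Apply the tolerance criterion; distance must be strictly below tol."""
    if not truth.present:
        return not pred.present
    if not pred.present:
        return False
    return _distance(pred.centroid, truth.centroid, norm) < tol


@dataclass
class EvalReport:
    n_total: int
    n_positive: int
    n_negative: int
    n_correct: int
    n_correct_positive: int
    n_correct_negative: int
    records: pd.DataFrame = field(repr=False, default=None)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total

    @property
    def positive_accuracy(self) -> float:
        return self.n_correct_positive / self.n_positive if self.n_positive else float("nan")

    @property
    def negative_accuracy(self) -> float:
        return self.n_correct_negative / self.n_negative if self.n_negative else float("nan")

    def summary(self) -> str:
        """Human-readable class/samples/correct/accuracy table."""
        rows = [
            ("Positive", self.n_positive, self.n_correct_positive, self.positive_accuracy),
            ("Negative", self.n_negative, self.n_correct_negative, self.negative_accuracy),
            ("Summary", self.n_total, self.n_correct, self.accuracy),
        ]
        lines = [f"{'Class':<10}{'Samples':>9}{'Correct':>9}{'ACC':>8}"]
        for name, n, k, acc in rows:
            acc_s = f"{100 * acc:.1f}%" if np.isfinite(acc) else "n/a"
            lines.append(f"{name:<10}{n:>9}{k:>9}{acc_s:>8}")
        return "\n".join(lines)


def evaluate(
    predictions: Sequence[DetectionResult],
    truths: Sequence[GroundTruth],
    tol: float = DEFAULT_TOL_PX,
    norm: str = "euclidean",
) -> EvalReport:
    """Tally correctness over aligned prediction/truth collections."""
    if len(predictions) != len(truths):
        raise ValueError(f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths")
    if len(predictions) == 0:
        raise ValueError("cannot evaluate an empty collection")

    rows = []
    for i, (pred, truth) in enumerate(zip(predictions, truths)):
        dist = (
            _distance(pred.centroid, truth.centroid, norm)
            if pred.present and truth.present
            else None
        )
        rows.append(
            {
                "index": i,
                "truth_present": truth.present,
                "pred_present": pred.present,
                "truth_row": truth.centroid[0] if truth.present else np.nan,
                "truth_col": truth.centroid[1] if truth.present else np.nan,
                "pred_row": pred.centroid[0] if pred.present else np.nan,
                "pred_col": pred.centroid[1] if pred.present else np.nan,
                "distance": np.nan if dist is None else dist,
                "confidence": pred.confidence,
                "area": pred.area,
                "correct": is_correct(pred, truth, tol, norm),
            }
        )
    df = pd.DataFrame(rows)
    pos = df[df.truth_present]
    neg = df[~df.truth_present]
    return EvalReport(
        n_total=len(df),
        n_positive=len(pos),
        n_negative=len(neg),
        n_correct=int(df.correct.sum()),
        n_correct_positive=int(pos.correct.sum()),
        n_correct_negative=int(neg.correct.sum()),
        records=df,
    )
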