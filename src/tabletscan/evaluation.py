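"""Accuracy bookkeeping: confusion matrices, accuracy %, model comparison.

Accuracy is the fraction of tablets whose predicted class equals the true
class, printed as a percentage rounded half-up to one decimal.  Class 0
(rejected / not strictly predicted) always counts as misclassified and is
kept as its own confusion-matrix row, never merged into a numbered class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EvalReport", "accuracy", "accuracy_pct", "compare_models"]

_TRUE_CLASSES = (1, 2, 3, 4)
_PRED_CLASSES = (0, 1, 2, 3, 4)


def accuracy_pct(n_correct: int, n_total: int) -> float:
    """100 * n_correct / n_total, rounded half-up to one decimal place."""
    if n_total < 1:
        raise ValueError("n_total must be positive")
    frac = Decimal(100 * n_correct) / Decimal(n_total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    """Classification outcome for one model on one tablet set.

    ``confusion`` is a 5x4 matrix: rows are predicted classes 0-4,
    columns true classes 1-4; entries sum to ``n_total``.
    """

    name: str
    n_total: int
    n_correct: int
    n_misclassified: int
    accuracy_pct: float
    confusion: np.ndarray
    misclassified_ids: list = field(default_factory=list)

    def per_class_recall(self) -> dict[int, float]:
        out = {}
        for j, k in enumerate(_TRUE_CLASSES):
            col = self.confusion[:, j].sum()
            out[k] = float(self.confusion[k, j] / col) if col else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "n_misclassified": self.n_misclassified,
            "accuracy_pct": self.accuracy_pct,
            "confusion_rows_pred0_to_4": self.confusion.tolist(),
            "misclassified_ids": list(self.misclassified_ids),
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def accuracy(
    predicted: Sequence[int],
    truth: Sequence[int],
    ids: Sequence | None = None,
    name: str = "",
) -> EvalReport:
    """Score predictions in {0..4} against true classes in {1..4}.

    Inputs must be aligned and non-empty; class-0 predictions are counted
    as misclassifications.
    """
    pred = np.asarray(predicted, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.size == 0:
        raise ValueError("empty prediction set")
    if pred.shape != true.shape:
        raise ValueError(f"misaligned inputs: {pred.shape} vs {true.shape}")
    if not np.isin(true, _TRUE_CLASSES).all():
        raise ValueError("true classes must lie in {1, 2, 3, 4}")
    if not np.isin(pred, _PRED_CLASSES).all():
        raise ValueError("predicted classes must lie in {0, 1, 2, 3, 4}")
    if ids is None:
        ids = list(range(len(pred)))
    ids = list(ids)
    if len(ids) != len(pred):
        raise ValueError("ids misaligned with predictions")

    confusion = np.zeros((5, 4), dtype=int)
    for p, t in zip(pred, true):
        confusion[p, t - 1] += 1
    correct_mask = pred == true  # class 0 never equals a true class
    n_correct = int(correct_mask.sum())
    mis_ids = [i for i, ok in zip(ids, correct_mask) if not ok]
    return EvalReport(
        name=name,
        n_total=int(pred.size),
        n_correct=n_correct,
        n_misclassified=int(pred.size - n_correct),
        accuracy_pct=accuracy_pct(n_correct, int(pred.size)),
        confusion=confusion,
        misclassified_ids=mis_ids,
    )


def compare_models(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Rank models evaluated on the identical tablet set.

    Sorted by accuracy descending, ties broken alphabetically by name;
    includes per-class recall columns.  Raises if the reports' true-class
    marginals differ (different tablet sets are not comparable).
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    marginals = [r.confusion.sum(axis=0) for r in reports]
    for m in marginals[1:]:
        if not np.array_equal(m, marginals[0]):
            raise ValueError("reports cover different tablet sets "
                             f"(truth marginals {marginals[0]} vs {m})")
    rows = []
    for r in reports:
        rec = r.per_class_recall()
        rows.append(
            {
                "model": r.name,
                "accuracy_pct": r.accuracy_pct,
                "n_misclassified": r.n_misclassified,
                **{f"recall_class{k}": rec[k] for k in _TRUE_CLASSES},
            }
        )
    df = pd.DataFrame(rows).sort_values(
        by=["accuracy_pct", "model"], ascending=[False, True]
    )
    return df.reset_index(drop=True)
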