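"""Grid-discretised detection scoring and pore-accuracy bookkeeping.

Detection is scored on grid cells rather than matched objects: the
manually and automatically labelled masks are both discretised onto a
coarse grid (a cell is "stomate" when at least half of its pixels are),
and the cell-wise agreement yields TP/FP/FN/TN, from which precision,
recall and F-score follow.  Pore estimation is scored per stomate as a
count table: total patches, no-detections, available (= total minus
no-detections), incorrect and correct (= available minus incorrect), with
the percentage correct taken over the available patches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class UndefinedMetricError(ArithmeticError):
    """Raised when a metric's denominator is zero (reported as NA in tables)."""


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass
class MetricsRow:
    source_id: str
    n_stomata: int
    precision: float
    recall: float
    fscore: float


@dataclass
class PoreAccuracyRow:
    """One source image's pore-estimation outcome counts.

    Invariants: ``available = total - no_detections``,
    ``correct = available - incorrect`` and
    ``pct_correct = 100 * correct / available``.
    """

    source_id: str
    total: int
    no_detections: int
    incorrect: int

    @property
    def available(self) -> int:
        return self.total - self.no_detections

    @property
    def correct(self) -> int:
        return self.available - self.incorrect

    @property
    def pct_correct(self) -> float:
        if self.available == 0:
            raise UndefinedMetricError("no available estimates")
        return round(100.0 * self.correct / self.available, 2)


def discretize_mask(mask: np.ndarray, cell_size: int) -> np.ndarray:
    """Reduce a binary mask to a cell grid with the >= 50% occupancy rule.

    Partial cells at the right/bottom edges use their actual pixel count
    as the denominator.
    """
    if cell_size < 1:
        raise ValueError("cell_size must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    nr, nc = math.ceil(h / cell_size), math.ceil(w / cell_size)
    out = np.zeros((nr, nc), dtype=bool)
    for i in range(nr):
        for j in range(nc):
            cell = mask[i * cell_size : (i + 1) * cell_size, j * cell_size : (j + 1) * cell_size]
            out[i, j] = cell.sum() * 2 >= cell.size
    return out


def discretize_compare(
    manual_mask: np.ndarray, auto_mask: np.ndarray, cell_size: int
) -> ConfusionCounts:
    """Cell-wise confusion counts between manual and automatic labels."""
    manual_mask = np.asarray(manual_mask)
    auto_mask = np.asarray(auto_mask)
    if manual_mask.shape != auto_mask.shape:
        raise ValueError(
            f"mask shapes differ: {manual_mask.shape} vs {auto_mask.shape}"
        )
    m = discretize_mask(manual_mask, cell_size)
    a = discretize_mask(auto_mask, cell_size)
    return ConfusionCounts(
        tp=int(np.sum(m & a)),
        fp=int(np.sum(~m & a)),
        fn=int(np.sum(m & ~a)),
        tn=int(np.sum(~m & ~a)),
    )


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    if c.tp + c.fp == 0 or c.tp + c.fn == 0:
        raise UndefinedMetricError("precision/recall undefined: empty prediction or truth")
    return c.tp / (c.tp + c.fp), c.tp / (c.tp + c.fn)


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        raise UndefinedMetricError("F-score undefined when precision = recall = 0")
    return 2.0 * precision * recall / (precision + recall)


def aggregate_metrics(rows: Sequence[MetricsRow]) -> tuple[float, float, float]:
    """Unweighted per-image means of precision, recall and F-score.

    Rounded to 3 decimals for reporting.
    """
    if not rows:
        raise ValueError("cannot aggregate zero rows")
    return (
        round(float(np.mean([r.precision for r in rows])), 3),
        round(float(np.mean([r.recall for r in rows])), 3),
        round(float(np.mean([r.fscore for r in rows])), 3),
    )


def pore_accuracy_table(
    grouped: dict[str, Iterable[tuple[str, bool | None]]]
) -> list[PoreAccuracyRow]:
    """Build per-source accuracy rows from (status, correct-flag) pairs.

    Each pair carries a pore estimate's status and, when the estimate is
    available (status != "no_detection"), a correctness flag — on
    synthetic data IoU >= 0.5 against the true pore mask, on real data a
    manual-review column.  A missing flag on an available estimate is a
    data error.
    """
    rows = []
    for source_id, pairs in grouped.items():
        total = no_det = incorrect = 0
        for status, flag in pairs:
            total += 1
            if status == "no_detection":
                no_det += 1
                continue
            if flag is None:
                raise ValueError(
                    f"{source_id}: available estimate lacks a correctness flag"
                )
            if not flag:
                incorrect += 1
        rows.append(PoreAccuracyRow(source_id, total, no_det, incorrect))
    return rows


def pore_accuracy_summary(rows: Sequence[PoreAccuracyRow]) -> dict[str, float]:
    """Pooled and per-row-mean accuracies plus column totals.

    The pooled figure is total-correct / total-available; the row mean
    averages the per-source percentages.  The two differ whenever sources
    contribute unequal counts, so both are reported.
    """
    total = sum(r.total for r in rows)
    available = sum(r.available for r in rows)
    correct = sum(r.correct for r in rows)
    return {
        "total": total,
        "no_detections": sum(r.no_detections for r in rows),
        "available": available,
        "incorrect": sum(r.incorrect for r in rows),
        "correct": correct,
        "pct_correct_pooled": round(100.0 * correct / available, 2) if available else float("nan"),
        "pct_correct_mean": round(float(np.mean([r.pct_correct for r in rows])), 2),
    }


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------

def metrics_to_frame(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    """Per-image detection metrics with a final AVERAGE row."""
    df = pd.DataFrame(
        [
            {
                "source_id": r.source_id,
                "n_stomata": r.n_stomata,
                "precision": r.precision,
                "recall": r.recall,
                "fscore": round(r.fscore, 5),
            }
            for r in rows
        ]
    )
    mp, mr, mf = aggregate_metrics(rows)
    avg = pd.DataFrame(
        [
            {
                "source_id": "AVERAGE",
                "n_stomata": int(df["n_stomata"].sum()),
                "precision": mp,
                "recall": mr,
                "fscore": mf,
            }
        ]
    )
    return pd.concat([df, avg], ignore_index=True)


def pore_accuracy_to_frame(rows: Sequence[PoreAccuracyRow]) -> pd.DataFrame:
    """Per-image pore-accuracy counts with a final AVERAGE row."""
    df = pd.DataFrame(
        [
            {
                "source_id": r.source_id,
                "total": r.total,
                "no_detections": r.no_detections,
                "available": r.available,
                "incorrect": r.incorrect,
                "correct": r.correct,
                "pct_correct": r.pct_correct,
            }
            for r in rows
        ]
    )
    s = pore_accuracy_summary(rows)
    avg = pd.DataFrame(
        [
            {
                "source_id": "AVERAGE",
                "total": s["total"],
                "no_detections": s["no_detections"],
                "available": s["available"],
                "incorrect": s["incorrect"],
                "correct": s["correct"],
                "pct_correct": s["pct_correct_pooled"],
            }
        ]
    )
    return pd.concat([df, avg], ignore_index=True)
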