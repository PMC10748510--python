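"""Evaluation metrics and report-table arithmetic.

Percentages are carried at full precision internally and rounded half-up
to two decimals only at report time.  Averaging over the two classes is
macro by default; the row F1 is the harmonic mean of the macro precision
and macro recall, so the F1 identity ``F1 = 2PR/(P+R)`` holds on every
row by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "MetricsRow", "ComparisonRow", "classification_metrics", "f1_gap",
    "infusion_gain", "total_importance", "round2", "render_markdown_table",
]


def round2(x: float) -> float:
    """Half-up rounding to two decimals (report-time only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MetricsRow:
    model_label: str
    condition: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    zero_division_flag: bool = False

    def __post_init__(self):
        for name in ("accuracy", "precision", "recall", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")

    def rounded(self) -> dict[str, float]:
        return {k: round2(getattr(self, k))
                for k in ("accuracy", "precision", "recall", "f1")}


@dataclass
class ComparisonRow:
    condition: str
    best_interpretable_f1: float
    reference_f1: float

    @property
    def delta(self) -> float:
        return self.best_interpretable_f1 - self.reference_f1


def classification_metrics(gold, pred, model_label: str = "model",
                           condition: str = "condition",
                           averaging: str = "macro") -> MetricsRow:
    """Accuracy / precision / recall / F1 in percent.

    ``averaging`` is ``macro`` (mean over the two classes) or
    ``positive`` (positive class only).  Zero-division cells are reported
    as 0 and flagged.
    """
    gold = np.asarray(gold, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if gold.shape != pred.shape or gold.size == 0:
        raise ValueError("gold and pred must be equal-length non-empty vectors")
    if averaging not in ("macro", "positive"):
        raise ValueError("averaging must be 'macro' or 'positive'")
    accuracy = float((gold == pred).mean())
    flag = False
    precisions, recalls = [], []
    classes = (0, 1) if averaging == "macro" else (1,)
    for cls in classes:
        tp = int(((pred == cls) & (gold == cls)).sum())
        fp = int(((pred == cls) & (gold != cls)).sum())
        fn = int(((pred != cls) & (gold == cls)).sum())
        if tp + fp == 0 or tp + fn == 0:
            flag = True
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
    precision = float(np.mean(precisions))
    recall = float(np.mean(recalls))
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsRow(
        model_label=model_label, condition=condition,
        accuracy=100 * accuracy, precision=100 * precision,
        recall=100 * recall, f1=100 * f1, zero_division_flag=flag,
    )


def f1_gap(rows: list[MetricsRow], condition: str,
           reference_label: str) -> float:
    """Best interpretable-model F1 minus the reference model's F1 for one
    condition (signed; negative when the reference wins)."""
    cond_rows = [r for r in rows if r.condition == condition]
    reference = [r for r in cond_rows if r.model_label == reference_label]
    interpretable = [r for r in cond_rows if r.model_label != reference_label]
    if len(reference) != 1 or not interpretable:
        raise ValueError(
            f"need >=1 interpretable row and exactly 1 reference row for "
            f"{condition!r}; got {len(interpretable)} and {len(reference)}")
    return max(r.f1 for r in interpretable) - reference[0].f1


def infusion_gain(fusion_value: float, baseline_value: float) -> float:
    """Signed accuracy (or F1) delta of an information-infused model over
    its single-task baseline."""
    for v in (fusion_value, baseline_value):
        if not np.isfinite(v):
            raise ValueError("metric values must be finite")
    return fusion_value - baseline_value


def total_importance(per_condition_scores) -> float:
    """Total importance score of one feature group: arithmetic sum of its
    five per-condition normalized importances, reported to 2 decimals."""
    scores = list(per_condition_scores)
    if len(scores) != 5:
        raise ValueError(f"expected one score per condition (5), got {len(scores)}")
    for v in scores:
        if not np.isfinite(v):
            raise ValueError("scores must be finite")
    return round2(float(np.sum(scores)))


def render_markdown_table(header: list[str], rows: list[list]) -> str:
    lines = ["| " + " | ".join(str(c) for c in header) + " |",
             "|" + "---|" * len(header)]
    for row in rows:
        cells = [f"{c:.2f}" if isinstance(c, float) else str(c) for c in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
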