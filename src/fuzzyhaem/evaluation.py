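"""Top-N multiclass evaluation: confusion counts, the four classical metrics,
per-disease sweeps over N, and recurrence proportions.

The multiclass extension is one-vs-rest on nested top-N prediction lists: a
record counts as a true positive for disease ``d`` at level ``N`` when its
ground-truth label is ``d`` and ``d`` appears among the N highest-scoring
predictions.  Because top-N lists are nested, recall is non-decreasing in N
for every disease; precision need not be (false positives grow with N too).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .engine import RankedDiagnosis
from .errors import EvaluationError
from .labels import ALL_DISEASES, DiseaseLabel
from .records import LabeledRecord


@dataclass(frozen=True)
class ConfusionMatrix:
    """Two-class confusion counts with the standard marginal identities."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def actual_positive(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negative(self) -> int:
        return self.fp + self.tn

    @property
    def predicted_positive(self) -> int:
        return self.tp + self.fp

    @property
    def predicted_negative(self) -> int:
        return self.fn + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    #: True when any denominator was zero and the metric was guarded to 0.
    guarded: bool = False


def metrics_from_confusion(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision, recall and F-measure; zero denominators guard to 0."""
    if cm.total == 0:
        raise EvaluationError("cannot compute metrics on an empty confusion matrix")
    guarded = False
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.predicted_positive:
        precision = cm.tp / cm.predicted_positive
    else:
        precision, guarded = 0.0, True
    if cm.actual_positive:
        recall = cm.tp / cm.actual_positive
    else:
        recall, guarded = 0.0, True
    if precision + recall:
        f_measure = 2.0 * precision * recall / (precision + recall)
    else:
        f_measure, guarded = 0.0, True
    return Metrics(accuracy, precision, recall, f_measure, guarded)


TruthSelector = str  # 'first' | 'any' | 'further' | 'later'


def _truth_matches(record: LabeledRecord, disease: DiseaseLabel, truth: TruthSelector) -> bool:
    if truth == "any":
        return disease in record.professional
    return record.truth(truth) is disease


def topn_confusion(
    records: Sequence[LabeledRecord],
    predictions: Sequence[RankedDiagnosis],
    disease: DiseaseLabel,
    n: int,
    truth: TruthSelector = "first",
) -> ConfusionMatrix:
    """One-vs-rest confusion counts for one disease at top-N level."""
    if len(records) != len(predictions):
        raise EvaluationError(
            f"{len(records)} records vs {len(predictions)} predictions"
        )
    if n < 1:
        raise EvaluationError(f"n must be >= 1, got {n}")
    tp = fp = fn = tn = 0
    for rec, pred in zip(records, predictions):
        is_true = _truth_matches(rec, disease, truth)
        is_pred = disease in pred.top(n)
        if is_true and is_pred:
            tp += 1
        elif is_true:
            fn += 1
        elif is_pred:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


@dataclass
class MetricsReport:
    """Per-disease, per-N confusion counts and metrics, plus macro averages."""

    table: pd.DataFrame  # columns: disease, n, tp, fp, fn, tn, accuracy, ...
    truth: TruthSelector

    def metrics(self, disease: DiseaseLabel, n: int) -> Metrics:
        row = self.table[
            (self.table.disease == disease.value) & (self.table.n == n)
        ].iloc[0]
        return Metrics(
            row.accuracy, row.precision, row.recall, row.f_measure, bool(row.guarded)
        )

    def confusion(self, disease: DiseaseLabel, n: int) -> ConfusionMatrix:
        row = self.table[
            (self.table.disease == disease.value) & (self.table.n == n)
        ].iloc[0]
        return ConfusionMatrix(int(row.tp), int(row.fp), int(row.fn), int(row.tn))

    def macro(self, n: int) -> Metrics:
        """Unweighted mean over diseases with at least one actual positive."""
        sub = self.table[(self.table.n == n) & (self.table.tp + self.table.fn > 0)]
        return Metrics(
            sub.accuracy.mean(),
            sub.precision.mean(),
            sub.recall.mean(),
            sub.f_measure.mean(),
        )


def metrics_sweep(
    records: Sequence[LabeledRecord],
    predictions: Sequence[RankedDiagnosis],
    n_values: Iterable[int],
    truth: TruthSelector = "first",
) -> MetricsReport:
    """Per-disease metrics for each N (deduplicated, sorted ascending)."""
    ns = sorted(set(n_values))
    if not ns or ns[0] < 1:
        raise EvaluationError("n_values must be non-empty positive integers")
    rows = []
    for n in ns:
        for disease in ALL_DISEASES:
            cm = topn_confusion(records, predictions, disease, n, truth)
            m = metrics_from_confusion(cm)
            rows.append(
                {
                    "disease": disease.value,
                    "n": n,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "fn": cm.fn,
                    "tn": cm.tn,
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f_measure": m.f_measure,
                    "guarded": m.guarded,
                }
            )
    return MetricsReport(pd.DataFrame(rows), truth=truth)


def recurrence_probability(
    records: Sequence[LabeledRecord],
    predictions: Sequence[RankedDiagnosis],
    n: int,
    horizon: str = "further",
) -> dict[DiseaseLabel, float]:
    """Proportion of records with horizon label ``d`` whose top-N list hit ``d``.

    ``horizon`` selects the clinical follow-up field: 'further' (further
    diagnostic work-up) or 'later' (disease appearing later in the record).
    Diseases that never occur as a horizon label are omitted.
    """
    if horizon not in ("further", "later"):
        raise ValueError(f"horizon must be 'further' or 'later', got {horizon!r}")
    if len(records) != len(predictions):
        raise EvaluationError(
            f"{len(records)} records vs {len(predictions)} predictions"
        )
    hits: dict[DiseaseLabel, int] = {}
    totals: dict[DiseaseLabel, int] = {}
    for rec, pred in zip(records, predictions):
        label = rec.truth(horizon)
        totals[label] = totals.get(label, 0) + 1
        if label in pred.top(n):
            hits[label] = hits.get(label, 0) + 1
    return {d: hits.get(d, 0) / total for d, total in totals.items()}
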