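"""Residue-level evaluation: confusion counts, A/R/P/F scores, ROC-AUC.

Positions labelled U in either the prediction or the truth are excluded from
counting (they carry no decision). Any score whose denominator is zero is
flagged undefined rather than coerced to 0 or 1 — with heavily skewed
domain/linker distributions those denominators do vanish in practice, and a
silent 0 would masquerade as a measured value.

Dataset-level results are aggregated two ways, both reported: *pooled* (sum
the confusion counts over proteins, then score) and *macro* (score each
protein, then average the defined scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotations import LABEL_UNKNOWN, ResidueAnnotation
from .errors import EvaluationError

METRIC_NAMES = ("accuracy", "recall", "precision", "f_measure")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    excluded: int = 0  # positions skipped because pred or truth was U

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.excluded + other.excluded,
        )


@dataclass(frozen=True)
class MetricReport:
    """A/R/P/F with undefined entries flagged (value None)."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    f_measure: float | None
    counts: ConfusionCounts
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "excluded": self.counts.excluded,
            "undefined": sorted(self.undefined),
        }


def confusion(
    pred: ResidueAnnotation | str,
    truth: ResidueAnnotation | str,
    positive_label: str = "D",
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over positions where both tracks are decided."""
    pred_s = pred.labels if isinstance(pred, ResidueAnnotation) else pred
    truth_s = truth.labels if isinstance(truth, ResidueAnnotation) else truth
    if len(pred_s) != len(truth_s):
        raise EvaluationError(
            f"prediction length {len(pred_s)} != truth length {len(truth_s)}"
        )
    p = np.frombuffer(pred_s.encode(), dtype="S1")
    t = np.frombuffer(truth_s.encode(), dtype="S1")
    unknown = (p == LABEL_UNKNOWN.encode()) | (t == LABEL_UNKNOWN.encode())
    pos = positive_label.encode()
    pp, tp_ = p[~unknown] == pos, t[~unknown] == pos
    return ConfusionCounts(
        tp=int(np.sum(pp & tp_)),
        fp=int(np.sum(pp & ~tp_)),
        tn=int(np.sum(~pp & ~tp_)),
        fn=int(np.sum(~pp & tp_)),
        excluded=int(np.sum(unknown)),
    )


def scores(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, recall, precision and F-measure from confusion counts."""
    undefined = set()
    values: dict[str, float | None] = {}

    def ratio(name: str, num: int, den: int) -> float | None:
        if den == 0:
            undefined.add(name)
            return None
        return num / den

    values["accuracy"] = ratio("accuracy", counts.tp + counts.tn, counts.total)
    r = ratio("recall", counts.tp, counts.tp + counts.fn)
    p = ratio("precision", counts.tp, counts.tp + counts.fp)
    values["recall"], values["precision"] = r, p
    if r is None or p is None or r + p == 0:
        undefined.add("f_measure")
        values["f_measure"] = None
    else:
        values["f_measure"] = 2 * r * p / (r + p)
    return MetricReport(
        accuracy=values["accuracy"],
        recall=values["recall"],
        precision=values["precision"],
        f_measure=values["f_measure"],
        counts=counts,
        undefined=frozenset(undefined),
    )


def roc_auc(score_per_position: Sequence[float], truth: Sequence[bool]) -> float | None:
    """Rank-based ROC-AUC with averaged ties; None when truth is single-class.

    Equals the Mann–Whitney U statistic scaled by n_pos * n_neg: the
    probability that a random positive outscores a random negative, counting
    ties as one half.
    """
    s = np.asarray(score_per_position, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise EvaluationError("scores and truth must have equal length")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    return float((ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class DatasetEvaluation:
    """Per-protein reports plus pooled and macro-averaged summaries."""

    per_protein: dict[str, MetricReport]
    pooled: MetricReport
    macro: dict[str, float | None]
    macro_n_defined: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, rep in self.per_protein.items():
            rows.append({"protein": pid, **{k: v for k, v in rep.as_dict().items() if k != "undefined"}})
        rows.append({"protein": "POOLED", **{k: v for k, v in self.pooled.as_dict().items() if k != "undefined"}})
        macro_row = {"protein": "MACRO"}
        macro_row.update({m: self.macro[m] for m in METRIC_NAMES})
        rows.append(macro_row)
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        return {
            "pooled": self.pooled.as_dict(),
            "macro": {
                m: {"value": self.macro[m], "n_proteins_defined": self.macro_n_defined[m]}
                for m in METRIC_NAMES
            },
            "per_protein": {pid: rep.as_dict() for pid, rep in self.per_protein.items()},
        }


def evaluate_dataset(
    predictions: Mapping[str, ResidueAnnotation],
    truths: Mapping[str, ResidueAnnotation],
    positive_label: str = "D",
) -> DatasetEvaluation:
    """Score a set of predictions against ground truth, per protein and summary."""
    if set(predictions) != set(truths):
        missing = set(predictions) ^ set(truths)
        raise EvaluationError(f"prediction/truth id sets differ: {sorted(missing)[:5]}")
    per_protein = {}
    pooled_counts = ConfusionCounts()
    for pid in sorted(predictions):
        counts = confusion(predictions[pid], truths[pid], positive_label)
        per_protein[pid] = scores(counts)
        pooled_counts = pooled_counts + counts
    macro: dict[str, float | None] = {}
    macro_n: dict[str, int] = {}
    for m in METRIC_NAMES:
        vals = [getattr(rep, m) for rep in per_protein.values() if getattr(rep, m) is not None]
        macro[m] = float(np.mean(vals)) if vals else None
        macro_n[m] = len(vals)
    return DatasetEvaluation(
        per_protein=per_protein,
        pooled=scores(pooled_counts),
        macro=macro,
        macro_n_defined=macro_n,
    )
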