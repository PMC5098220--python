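"""Multi-label performance metrics.

Evaluation uses the binary label-vector formulation: with label set
L = {1..d}, instance *i* has a true d-vector y^i and a predicted d-vector
ŷ^i whose components mark label membership. On these:

* exact match ratio — fraction of instances whose predicted vector equals
  the true vector component-for-component (full label-set agreement);
* per-label precision/recall/F from the label's TP/FP/FN counts;
* macro-average F — unweighted mean of per-label F-measures;
* micro-average F — F computed on TP/FP/FN pooled across labels.

A 0/0 ratio (a label with empty denominator) is defined as 0 and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class LabelMatrix:
    """Aligned true and predicted binary membership matrices (n × d)."""

    labels: tuple[str, ...]
    Y: np.ndarray
    Yhat: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.Y = np.asarray(self.Y, dtype=int)
        self.Yhat = np.asarray(self.Yhat, dtype=int)
        if self.Y.shape != self.Yhat.shape:
            raise ValueError(
                f"shape mismatch: true {self.Y.shape} vs predicted {self.Yhat.shape}"
            )
        if self.Y.ndim != 2 or self.Y.shape[1] != len(self.labels):
            raise ValueError(
                f"expected shape (n, {len(self.labels)}), got {self.Y.shape}"
            )
        for M, name in ((self.Y, "Y"), (self.Yhat, "Yhat")):
            if not np.isin(M, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
        if self.Y.shape[0] and not self.Y.any(axis=1).all():
            raise ValueError("every instance must have at least one true label")

    @classmethod
    def from_label_sets(
        cls,
        labels: Sequence[str],
        true_sets: Iterable[Iterable[str]],
        pred_sets: Iterable[Iterable[str]],
    ) -> "LabelMatrix":
        """Build the matrices from per-instance label sets.

        Labels outside *labels* are ignored, which restricts evaluation to
        the stated label list (e.g. only the labels present in a test set).
        """
        labels = tuple(labels)
        idx = {lab: j for j, lab in enumerate(labels)}
        true_sets = [set(s) for s in true_sets]
        pred_sets = [set(s) for s in pred_sets]
        if len(true_sets) != len(pred_sets):
            raise ValueError("true and predicted lists differ in length")
        Y = np.zeros((len(true_sets), len(labels)), dtype=int)
        Yhat = np.zeros_like(Y)
        for i, s in enumerate(true_sets):
            for lab in s:
                if lab in idx:
                    Y[i, idx[lab]] = 1
        for i, s in enumerate(pred_sets):
            for lab in s:
                if lab in idx:
                    Yhat[i, idx[lab]] = 1
        return cls(labels=labels, Y=Y, Yhat=Yhat)

    @property
    def n_instances(self) -> int:
        return self.Y.shape[0]


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.debug("0/0 in %s defined as 0", what)
        return 0.0
    return num / den


def exact_match_ratio(M: LabelMatrix) -> float:
    """Fraction of instances with full label-set agreement."""
    if M.n_instances == 0:
        raise ValueError("exact match ratio undefined for zero instances")
    return float(np.mean((M.Y == M.Yhat).all(axis=1)))


def _confusion(M: LabelMatrix, j: int) -> tuple[int, int, int]:
    y, yh = M.Y[:, j], M.Yhat[:, j]
    tp = int(np.sum((y == 1) & (yh == 1)))
    fp = int(np.sum((y == 0) & (yh == 1)))
    fn = int(np.sum((y == 1) & (yh == 0)))
    return tp, fp, fn


def label_prf(M: LabelMatrix, label: str) -> tuple[float, float, float]:
    """Precision, recall and F-measure for one label."""
    j = M.labels.index(label)
    tp, fp, fn = _confusion(M, j)
    p = _safe_ratio(tp, tp + fp, f"precision({label})")
    r = _safe_ratio(tp, tp + fn, f"recall({label})")
    f = _safe_ratio(2 * p * r, p + r, f"F({label})")
    return p, r, f


def macro_f(M: LabelMatrix) -> float:
    """Unweighted mean of per-label F-measures."""
    return float(np.mean([label_prf(M, lab)[2] for lab in M.labels]))


def micro_f(M: LabelMatrix) -> float:
    """F-measure on TP/FP/FN counts pooled across all labels."""
    tp = fp = fn = 0
    for j in range(len(M.labels)):
        t, p_, n_ = _confusion(M, j)
        tp, fp, fn = tp + t, fp + p_, fn + n_
    p = _safe_ratio(tp, tp + fp, "micro precision")
    r = _safe_ratio(tp, tp + fn, "micro recall")
    return _safe_ratio(2 * p * r, p + r, "micro F")


@dataclass
class MultiLabelReport:
    """Assembled evaluation: overall and per-label metrics plus raw counts."""

    labels: tuple[str, ...]
    n_instances: int
    exact_match_ratio: float
    per_label: dict[str, tuple[float, float, float]]  # label -> (P, R, F)
    macro_f: float
    micro_f: float
    confusion_counts: dict[str, tuple[int, int, int]]  # label -> (TP, FP, FN)

    def to_dict(self) -> dict:
        return {
            "n_instances": self.n_instances,
            "exact_match_ratio": self.exact_match_ratio,
            "macro_f": self.macro_f,
            "micro_f": self.micro_f,
            "per_label": {
                lab: {"precision": p, "recall": r, "f": f}
                for lab, (p, r, f) in self.per_label.items()
            },
            "confusion_counts": {
                lab: {"tp": tp, "fp": fp, "fn": fn}
                for lab, (tp, fp, fn) in self.confusion_counts.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        """One row per label plus summary rows."""
        lines = ["row\tprecision\trecall\tf\ttp\tfp\tfn"]
        for lab in self.labels:
            p, r, f = self.per_label[lab]
            tp, fp, fn = self.confusion_counts[lab]
            lines.append(f"{lab}\t{p:.4f}\t{r:.4f}\t{f:.4f}\t{tp}\t{fp}\t{fn}")
        lines.append(f"exact_match_ratio\t{self.exact_match_ratio:.4f}\t\t\t\t\t")
        lines.append(f"macro_f\t\t\t{self.macro_f:.4f}\t\t\t")
        lines.append(f"micro_f\t\t\t{self.micro_f:.4f}\t\t\t")
        return "\n".join(lines) + "\n"


def empty_report(labels: Sequence[str]) -> MultiLabelReport:
    """An all-zero report for an evaluation with no scored instances
    (e.g. every instance of one kind was null and abstained)."""
    labels = tuple(labels)
    zero3 = {lab: (0.0, 0.0, 0.0) for lab in labels}
    return MultiLabelReport(
        labels=labels,
        n_instances=0,
        exact_match_ratio=0.0,
        per_label=zero3,
        macro_f=0.0,
        micro_f=0.0,
        confusion_counts={lab: (0, 0, 0) for lab in labels},
    )


def per_class_report(M: LabelMatrix) -> MultiLabelReport:
    """Compute every metric on one label matrix."""
    per_label = {lab: label_prf(M, lab) for lab in M.labels}
    confusion = {
        lab: _confusion(M, j) for j, lab in enumerate(M.labels)
    }
    return MultiLabelReport(
        labels=M.labels,
        n_instances=M.n_instances,
        exact_match_ratio=exact_match_ratio(M),
        per_label=per_label,
        macro_f=macro_f(M),
        micro_f=micro_f(M),
        confusion_counts=confusion,
    )
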