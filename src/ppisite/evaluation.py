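"""Performance measures for binary interface-residue prediction.

A prediction run is summarised by a confusion matrix over surface residues
(positive class = interface residue) and by six derived measures: accuracy,
sensitivity (recall on interface residues), precision, specificity,
F-measure (harmonic mean of precision and sensitivity), and the Matthews
correlation coefficient (MCC).

Degenerate denominators (e.g. a fold with no predicted positives) yield a
sentinel value of 0.0 and are recorded in ``MetricSet.flags`` instead of
raising, so a single degenerate cross-validation fold cannot abort a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricSet", "compute_metrics", "metrics_report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary classification outcome.

    tp: interface residues predicted as interface.
    tn: non-interface residues predicted as non-interface.
    fp: non-interface residues predicted as interface.
    fn: interface residues predicted as non-interface.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        """Actual positives (interface residues)."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Actual negatives (non-interface residues)."""
        return self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same shape")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


@dataclass
class MetricSet:
    """The six measures; ``flags`` names measures whose denominator was zero."""

    acc: float
    sen: float
    pre: float
    spe: float
    f_measure: float
    mcc: float
    flags: set = field(default_factory=set)

    def as_dict(self, ndigits: int | None = None) -> dict:
        d = {
            "acc": self.acc,
            "sen": self.sen,
            "pre": self.pre,
            "spe": self.spe,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
        }
        if ndigits is not None:
            d = {k: round(v, ndigits) for k, v in d.items()}
        d["flags"] = sorted(self.flags)
        return d


def _ratio(num: float, den: float, name: str, flags: set) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Six measures from a confusion matrix.

    Acc = (TP+TN)/(TP+FP+TN+FN); Sen = TP/(TP+FN); Pre = TP/(TP+FP);
    Spe = TN/(FP+TN); F = 2*Pre*Sen/(Pre+Sen);
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Raises ValueError on the all-zero matrix; any individual zero
    denominator produces a 0.0 sentinel plus a flag.
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics for an all-zero confusion matrix")
    flags: set = set()
    tp, tn, fp, fn = float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn)
    acc = (tp + tn) / cm.total
    sen = _ratio(tp, tp + fn, "sen", flags)
    pre = _ratio(tp, tp + fp, "pre", flags)
    spe = _ratio(tn, fp + tn, "spe", flags)
    f = _ratio(2.0 * pre * sen, pre + sen, "f_measure", flags)
    mcc_den_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den_sq == 0:
        flags.add("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den_sq)
    return MetricSet(acc=acc, sen=sen, pre=pre, spe=spe, f_measure=f, mcc=mcc, flags=flags)


def metrics_report(
    pooled: ConfusionMatrix,
    per_fold: list[ConfusionMatrix] | None = None,
    extra: dict | None = None,
) -> dict:
    """JSON-ready report: pooled matrix + metrics (full precision and
    3-decimal rounding), per-fold matrices and their metrics, and the mean
    of per-fold metrics alongside the pooled values."""
    report: dict = {
        "pooled_confusion_matrix": pooled.as_dict(),
        "pooled_metrics": compute_metrics(pooled).as_dict(),
        "pooled_metrics_rounded": compute_metrics(pooled).as_dict(ndigits=3),
    }
    if per_fold:
        fold_metrics = [compute_metrics(cm) for cm in per_fold]
        report["per_fold"] = [
            {"confusion_matrix": cm.as_dict(), "metrics": m.as_dict()}
            for cm, m in zip(per_fold, fold_metrics)
        ]
        keys = ("acc", "sen", "pre", "spe", "f_measure", "mcc")
        report["fold_mean_metrics"] = {
            k: float(np.mean([getattr(m, k) for m in fold_metrics])) for k in keys
        }
    if extra:
        report.update(extra)
    return report
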