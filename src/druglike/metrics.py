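"""The five evaluation indexes: ACC, SE, SP, MCC and AUC.

All models are scored from the binary confusion matrix at a probability
threshold (default 0.5, ties counted positive) plus the rank-based AUC:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SE  = TP / (TP + FN)            (sensitivity, true-positive rate)
    SP  = TN / (TN + FP)            (specificity, true-negative rate)
    MCC = (TP·TN − FP·FN) / √((FP+TN)(FP+TP)(FN+TN)(FN+TP))

MCC uses the convention MCC = 0 when any factor of the denominator is
zero.  SE is *undefined* (reported as None, with a warning) when no
positives were evaluated — distinct from an SE of 0.  AUC is the
Mann–Whitney statistic: the probability that a random positive scores
above a random negative, ties counting one half.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import DataError


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Five-index evaluation of one model on one dataset."""

    confusion: ConfusionCounts
    acc: float
    se: float | None
    sp: float | None
    mcc: float
    auc: float | None
    threshold: float = 0.5

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = asdict(self.confusion)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN calling positive iff probability >= threshold."""
    y = np.asarray(labels)
    a = np.asarray(probabilities, dtype=float)
    if y.shape != a.shape:
        raise DataError(f"labels and predictions have different lengths ({y.shape} vs {a.shape})")
    if not np.isin(y, [0, 1]).all():
        raise DataError("labels must be binary (0/1)")
    pred = a >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def score(counts: ConfusionCounts) -> tuple[float, float | None, float | None, float]:
    """Return (ACC, SE, SP, MCC) from confusion counts.

    SE (resp. SP) is None with a warning when the evaluated set contains
    no positives (resp. negatives).  MCC is computed in log space so that
    the four denominator factors cannot overflow on very large counts.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total <= 0:
        raise DataError("empty confusion table")
    acc = (tp + tn) / total
    if tp + fn == 0:
        warnings.warn("no positive samples evaluated: SE undefined", stacklevel=2)
        se = None
    else:
        se = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative samples evaluated: SP undefined", stacklevel=2)
        sp = None
    else:
        sp = tn / (tn + fp)
    factors = [fp + tn, fp + tp, fn + tn, fn + tp]
    if any(f == 0 for f in factors):
        mcc = 0.0
    else:
        num = tp * tn - fp * fn  # exact integer arithmetic
        log_den = 0.5 * sum(math.log(f) for f in factors)
        mcc = 0.0 if num == 0 else math.copysign(
            math.exp(math.log(abs(num)) - log_den), num
        )
    return acc, se, sp, mcc


def auc(labels, probabilities) -> float:
    """Rank-based (Mann–Whitney) AUC; both classes must be present."""
    y = np.asarray(labels)
    a = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise DataError("AUC requires both classes in the evaluated labels")
    return float(roc_auc_score(y, a))


def evaluate(labels, probabilities, threshold: float = 0.5) -> EvalReport:
    """Full five-index report for one set of probabilistic predictions."""
    counts = confusion(labels, probabilities, threshold)
    acc, se, sp, mcc = score(counts)
    y = np.asarray(labels)
    area = auc(labels, probabilities) if len(np.unique(y)) == 2 else None
    return EvalReport(counts, acc, se, sp, mcc, area, threshold)


def mean_report(reports: list[EvalReport]) -> dict:
    """Arithmetic mean of the five indexes across reports (None skipped)."""
    out = {}
    for key in ("acc", "se", "sp", "mcc", "auc"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out
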