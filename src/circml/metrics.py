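"""Binary-classification evaluation: confusion counts, the six threshold
metrics (SE, SP, PRE, F1, ACC, MCC) and ROC AUC.

Every 0/0 case is defined as 0 so that degenerate cross-validation folds
(e.g. a fold whose test split contains one class) never crash a run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    SE: float
    SP: float
    PRE: float
    F1: float
    ACC: float
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {"SE": self.SE, "SP": self.SP, "PRE": self.PRE, "F1": self.F1,
               "ACC": self.ACC, "MCC": self.MCC}
        if self.AUC is not None:
            out["AUC"] = self.AUC
        return out


def confusion(labels, predictions) -> ConfusionCounts:
    """Confusion counts with positive class = 1."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FP=int(np.sum((y == 0) & (p == 1))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """SE, SP, PRE, F1, ACC and MCC from confusion counts.

    SE = TP/(TP+FN), SP = TN/(TN+FP), PRE = TP/(TP+FP),
    F1 = 2*SE*PRE/(SE+PRE), ACC = (TP+TN)/total and
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)),
    with every undefined (0/0) case set to 0.
    """
    se = _ratio(c.TP, c.TP + c.FN)
    sp = _ratio(c.TN, c.TN + c.FP)
    pre = _ratio(c.TP, c.TP + c.FP)
    f1 = _ratio(2.0 * se * pre, se + pre)
    acc = _ratio(c.TP + c.TN, c.total)
    denom = (c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN)
    mcc = 0.0 if denom == 0 else (c.TP * c.TN - c.FN * c.FP) / math.sqrt(denom)
    if denom == 0 and c.total > 0:
        logger.debug("degenerate confusion matrix; MCC set to 0")
    return MetricReport(SE=se, SP=sp, PRE=pre, F1=f1, ACC=acc, MCC=mcc)


def evaluate_predictions(labels, predictions, scores=None) -> MetricReport:
    """Full report from hard predictions (and AUC when scores are given)."""
    report = compute_metrics(confusion(labels, predictions))
    if scores is not None:
        report.AUC = roc_auc(labels, scores)
    return report


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve (rank/trapezoid formulation, midrank ties)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both classes to be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))
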