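"""Binary-classification metrics: SN, SP, ACC, MCC and rank-based AUC.

SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/(TP+TN+FP+FN),
MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)), with MCC
defined as 0 when its denominator vanishes.  AUC uses the Mann-Whitney
rank formulation with ties counted as one half.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {"SN": self.sn, "SP": self.sp, "ACC": self.acc,
                "MCC": self.mcc, "AUC": self.auc}


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from two equal-length binary label vectors."""
    y = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size and (not np.isin(y, (0, 1)).all() or not np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def auc_score(labels_true, scores) -> float:
    """Mann-Whitney AUC: mean rank of positives, ties at one half."""
    y = np.asarray(labels_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def report(counts: ConfusionCounts, scores=None, labels_true=None) -> MetricReport:
    """Compute SN/SP/ACC/MCC from counts and AUC from scores.

    ``scores`` and ``labels_true`` may be omitted; AUC is then nan.
    Ratios with an empty denominator (no positives for SN, no negatives
    for SP) are 0; a vanishing MCC denominator gives MCC = 0.
    """
    if counts.total == 0:
        raise ValueError("empty input: no evaluated samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    auc = float("nan")
    if scores is not None:
        if labels_true is None:
            raise ValueError("labels_true required to compute AUC from scores")
        auc = auc_score(labels_true, scores)
    return MetricReport(sn=sn, sp=sp, acc=acc, mcc=mcc, auc=auc)


def evaluate(labels_true, labels_pred, scores=None) -> MetricReport:
    """Convenience wrapper: confusion + report in one call."""
    counts = confusion(labels_true, labels_pred)
    return report(counts, scores=scores, labels_true=labels_true)


def write_report_json(rep: MetricReport, counts: ConfusionCounts, path) -> None:
    payload = rep.as_dict() | {
        "TP": counts.tp, "TN": counts.tn, "FP": counts.fp, "FN": counts.fn,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
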