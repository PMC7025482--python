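"""Train/test splitting, confusion matrices and ROC/AUC.

The ROC sweeps thresholds over the distinct predicted scores (descending),
grouping tied scores into a single vertex; the AUC is the trapezoidal area,
which then coincides exactly with the Mann-Whitney U statistic with half
credit for ties.  The single reported (sensitivity, specificity) pair is
taken at the Youden-J-optimal vertex by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "ROCResult", "split_train_test", "confusion", "roc_curve"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    sensitivity = tpr

    @property
    def specificity(self) -> float:
        return 1.0 - self.fpr

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "sensitivity": self.tpr, "specificity": self.specificity}


@dataclass
class ROCResult:
    points: list            # [(fpr, tpr)] from (0,0) to (1,1)
    thresholds: list        # score cutoff per point (inf sentinel first)
    auc: float
    operating_point: tuple  # (threshold, sensitivity, specificity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": [p[0] for p in self.points],
                             "tpr": [p[1] for p in self.points]})


def split_train_test(frame: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0):
    """Seeded simple random split: floor(f*n) training rows, rest test;
    disjoint and exhaustive."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(frame)
    n_train = int(np.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"split of {n} rows at {train_fraction} leaves an empty side")
    perm = np.random.default_rng(seed).permutation(n)
    return (frame.iloc[np.sort(perm[:n_train])].reset_index(drop=True),
            frame.iloc[np.sort(perm[n_train:])].reset_index(drop=True))


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionMatrix:
    """Counts at one operating threshold; predicted responder iff
    score > threshold (strictly)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(labels) == 0:
        raise ValueError("empty input")
    pred = scores > threshold
    pos = labels == 1
    return ConfusionMatrix(tp=int((pred & pos).sum()), tn=int((~pred & ~pos).sum()),
                           fp=int((pred & ~pos).sum()), fn=int((~pred & pos).sum()))


def roc_curve(labels, scores) -> ROCResult:
    """ROC over distinct-score thresholds with trapezoidal AUC.

    Requires both classes present.  The operating point maximizes Youden's
    J = sensitivity + specificity - 1 (ties: the vertex with the smaller
    false-positive rate).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC undefined for single-class labels")

    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.flatnonzero(np.diff(s) != 0)
    cut = np.concatenate([distinct, [len(s) - 1]])  # last index of each tie group
    cum_tp = np.cumsum(y)[cut]
    cum_fp = (cut + 1) - cum_tp
    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    thresholds = [float("inf")] + s[cut].tolist()

    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    near_max = np.flatnonzero(j >= j.max() - 1e-12)  # tie tolerance: float dust
    best = int(near_max[np.argmin(fpr[near_max])])
    op = (thresholds[best], float(tpr[best]), float(1.0 - fpr[best]))
    return ROCResult(points=list(zip(fpr.tolist(), tpr.tolist())),
                     thresholds=thresholds, auc=auc, operating_point=op)
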