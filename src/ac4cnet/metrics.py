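"""Binary-classification metrics: SEN, SPE, ACC, MCC and AUROC.

MCC's denominator can vanish when a row or column of the confusion table is
empty; the conventional value 0 is returned there.  AUROC is computed as the
rank statistic P(score_pos > score_neg) + 0.5 * P(tie) over all
positive/negative pairs, which equals the trapezoidal area under the
empirical ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class FoldMetrics:
    """SEN/SPE/ACC/MCC/AUROC for one validation fold or test set."""

    SEN: float
    SPE: float
    ACC: float
    MCC: float
    AUROC: float

    def as_dict(self) -> dict[str, float]:
        return {"SEN": self.SEN, "SPE": self.SPE, "ACC": self.ACC,
                "MCC": self.MCC, "AUROC": self.AUROC}


def confusion_from_scores(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = (s >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(((pred == 1) & (y == 1)).sum()),
        TN=int(((pred == 0) & (y == 0)).sum()),
        FP=int(((pred == 1) & (y == 0)).sum()),
        FN=int(((pred == 0) & (y == 1)).sum()),
    )


def mcc(counts: ConfusionCounts) -> float:
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Pairwise rank AUROC with half credit for ties.

    Uses midranks, so the result equals the mean over all pos/neg pairs of
    1[s_p > s_n] + 0.5 * 1[s_p == s_n] without the O(n^2) loop.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(s)  # midranks
    r_pos = ranks[y == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(
    counts: ConfusionCounts,
    scores: Sequence[float] | None = None,
    labels: Sequence[int] | None = None,
) -> FoldMetrics:
    """All five metrics from a confusion table plus scored examples."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    sen = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    spe = counts.TN / (counts.TN + counts.FP) if counts.TN + counts.FP else 0.0
    acc = (counts.TP + counts.TN) / counts.total
    if scores is None:
        auc = float("nan")
    else:
        auc = auroc(scores, labels)
    return FoldMetrics(SEN=sen, SPE=spe, ACC=acc, MCC=mcc(counts), AUROC=auc)


def evaluate_scores(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> FoldMetrics:
    counts = confusion_from_scores(scores, labels, threshold)
    return compute_metrics(counts, scores, labels)


def summarize(folds: Sequence[FoldMetrics]) -> dict[str, tuple[float, float]]:
    """Per-metric (mean, population std) across folds."""
    out = {}
    for key in ("SEN", "SPE", "ACC", "MCC", "AUROC"):
        vals = np.array([getattr(f, key) for f in folds], dtype=float)
        out[key] = (float(vals.mean()), float(vals.std()))
    return out
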