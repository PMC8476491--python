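"""Binary-classification metrics for variant effect prediction.

The report contains nine quantities: ROC-AUC and PR-AUC computed from the
continuous scores (lower z = more deleterious, so ranking uses -z), and
seven confusion-matrix metrics computed from the predicted labels by the
standard formulas:

    accuracy    = (TP + TN) / (TP + FN + TN + FP)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    precision   = TP / (TP + FP)
    specificity = TN / (FP + TN)
    sensitivity = TP / (TP + FN)            (recall)
    F-score     = 2 * precision*recall / (precision + recall)
    NPV         = TN / (TN + FN)

Degenerate denominators fall back to 0 so a report is always total.
ROC-AUC uses the rank (Mann-Whitney U) definition with ties counting half;
PR-AUC is average precision (a step-function integral of the
precision-recall sweep, with no linear interpolation).

``reconstruct_confusion`` inverts rounded published rates back to the
unique integer confusion matrix on known class sizes, enabling exact
consistency checks of printed metric tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

DELETERIOUS = "deleterious"

# Composition of the balanced human-variant benchmark the method is
# evaluated on: (deleterious, benign) counts per subset.
BENCHMARK_SUBSETS = {
    "HumVar": (1230, 1230),
    "UniFun": (25, 25),
    "BRCA1-DMS": (41, 41),
    "TP53-TA": (413, 413),
}


class ReconstructionError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    roc_auc: float
    pr_auc: float
    accuracy: float
    mcc: float
    precision: float
    specificity: float
    sensitivity: float
    f_score: float
    npv: float

    COLUMNS = (
        "roc_auc", "pr_auc", "accuracy", "mcc", "precision",
        "specificity", "sensitivity", "f_score", "npv",
    )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.COLUMNS) + "\n")
            fh.write(
                "\t".join(f"{getattr(self, c):.3f}" for c in self.COLUMNS) + "\n"
            )


def confusion(truth, predicted) -> ConfusionCounts:
    """Count TP/TN/FP/FN; 'deleterious' (or truthy) is the positive class."""
    t = _as_bool(truth)
    p = _as_bool(predicted)
    if t.shape != p.shape:
        raise ValueError("label vectors have different lengths")
    return ConfusionCounts(
        tp=int((t & p).sum()),
        tn=int((~t & ~p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
    )


def _as_bool(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        return arr == DELETERIOUS
    if arr.dtype == object:
        return np.array(
            [x == DELETERIOUS if isinstance(x, str) else bool(x) for x in arr]
        )
    return arr.astype(bool)


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def point_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The seven label-based metrics from a confusion matrix."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    return {
        "accuracy": _ratio(tp + tn, c.n),
        "mcc": (tp * tn - fp * fn) / mcc_den if mcc_den else 0.0,
        "precision": precision,
        "specificity": _ratio(tn, fp + tn),
        "sensitivity": sensitivity,
        "f_score": _ratio(2 * precision * sensitivity, precision + sensitivity),
        "npv": _ratio(tn, tn + fn),
    }


def roc_auc(scores, truth) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2).

    ``scores`` are deleteriousness scores: higher means more deleterious.
    Computed as the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    s = np.asarray(scores, dtype=float)
    t = _as_bool(truth)
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes")
    ranks = rankdata(s)
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_auc(scores, truth) -> float:
    """Average precision over the score-sorted precision-recall sweep.

    Thresholds descend through the distinct score values; each recall
    increment contributes the precision at that threshold (step integral,
    no interpolation).
    """
    s = np.asarray(scores, dtype=float)
    t = _as_bool(truth)
    n_pos = int(t.sum())
    if n_pos == 0:
        raise ValueError("PR-AUC needs positive examples")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    tp_cum = np.cumsum(t_sorted)
    n_cum = np.arange(1, len(s) + 1)
    # evaluate only at the last index of each tied-score block
    block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp_b = tp_cum[block_end]
    n_b = n_cum[block_end]
    precision = tp_b / n_b
    recall = tp_b / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(((recall - prev_recall) * precision).sum())


def full_report(z_scores, predicted_labels, truth) -> MetricsReport:
    """All nine metrics: rank metrics from -z, label metrics from predictions."""
    scores = -np.asarray(z_scores, dtype=float)
    c = confusion(truth, predicted_labels)
    pm = point_metrics(c)
    return MetricsReport(
        roc_auc=roc_auc(scores, truth), pr_auc=pr_auc(scores, truth), **pm
    )


# --- inversion of printed rates ------------------------------------------


def round_half_up(x: float, digits: int = 3) -> float:
    """Round half away from zero at a fixed number of decimals."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-digits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def reconstruct_confusion(
    sensitivity: float,
    specificity: float,
    precision: float,
    npv: float,
    n_pos: int,
    n_neg: int,
    digits: int = 3,
) -> ConfusionCounts:
    """Invert four rates rounded to ``digits`` decimals into integer counts.

    Searches all integer matrices with TP+FN = n_pos and TN+FP = n_neg whose
    sensitivity, specificity, precision and NPV round (half-up) back to the
    inputs.  Exactly one solution must exist; zero or several raise
    :class:`ReconstructionError` listing the candidates found.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp_candidates = [
        tp for tp in range(n_pos + 1)
        if round_half_up(tp / n_pos, digits) == sensitivity
    ]
    tn_candidates = [
        tn for tn in range(n_neg + 1)
        if round_half_up(tn / n_neg, digits) == specificity
    ]
    solutions = []
    for tp in tp_candidates:
        fn = n_pos - tp
        for tn in tn_candidates:
            fp = n_neg - tn
            if tp + fp == 0 or tn + fn == 0:
                continue
            if round_half_up(tp / (tp + fp), digits) != precision:
                continue
            if round_half_up(tn / (tn + fn), digits) != npv:
                continue
            solutions.append(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    if len(solutions) != 1:
        raise ReconstructionError(
            f"expected exactly one consistent confusion matrix, found "
            f"{len(solutions)}: {solutions}"
        )
    return solutions[0]
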