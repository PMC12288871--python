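"""Rank-based binary classification metrics shared by the GAE and classifier."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auroc_rank", "average_precision"]


def auroc_rank(labels, scores) -> float:
    """AUROC via the Mann-Whitney rank statistic (ties get midranks)."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes to be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def average_precision(labels, scores) -> float:
    """Average precision as precision-weighted recall increments.

    AP = sum_k (R_k - R_{k-1}) * P_k over descending-score thresholds.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("average precision requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, y.size + 1)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))
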