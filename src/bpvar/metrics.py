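"""Ranking metrics and fold construction for the model comparison."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold


def auc_rank(y, scores) -> float:
    """AUC-ROC via the rank (Mann-Whitney) method, with midrank ties.

    Equals the proportion of concordant (positive, negative) pairs, counting
    ties as half.
    """
    y = np.asarray(y, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def average_precision(y, scores) -> float:
    """Area under the precision-recall curve by step integration.

    Thresholds are the distinct score values in decreasing order; AP is the
    recall-weighted sum of precisions at each threshold.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_pos = y.sum()
    if n_pos == 0:
        raise ValueError("AP requires at least one positive")
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    last_of_group = np.r_[ss[1:] != ss[:-1], True]
    tp = np.cumsum(ys)[last_of_group]
    n_seen = np.flatnonzero(last_of_group) + 1.0
    precision = tp / n_seen
    recall = tp / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def stratified_folds(y, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled stratified k-fold test-index sets.

    Depends only on the label vector and the seed (never on features), so
    the same folds can be reused across feature sources.
    """
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros((y.size, 1)), y)]
    for f in folds:
        if len(np.unique(y[f])) < 2:
            raise ValueError("stratification produced a single-class fold")
    return folds
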