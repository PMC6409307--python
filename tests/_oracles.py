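"""Independent brute-force oracles used only by the test suite.

These deliberately use plain dict/loop implementations, sharing nothing with
the package's vectorized code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def mdr_fold_oracle(factors: pd.DataFrame, y: np.ndarray, fold_ids: np.ndarray,
                    threshold: float = 1.0):
    """Per-fold (train_accuracy, test_accuracy) and per-fold cell labels by
    direct enumeration."""
    n_folds = int(fold_ids.max()) + 1
    keys = [tuple(row) for row in factors.itertuples(index=False)]
    per_fold = []
    fold_labels = []
    for f in range(n_folds):
        counts: dict[tuple, list[int]] = {}
        for i in range(len(y)):
            if fold_ids[i] != f:
                c = counts.setdefault(keys[i], [0, 0])
                c[int(y[i])] += 1
        labels = {k: (c[1] > threshold * c[0]) for k, c in counts.items()}
        tr_hit = tr_n = te_hit = te_n = 0
        for i in range(len(y)):
            pred = labels.get(keys[i], False)  # unseen cells are low risk
            hit = int(pred == bool(y[i]))
            if fold_ids[i] != f:
                tr_hit, tr_n = tr_hit + hit, tr_n + 1
            else:
                te_hit, te_n = te_hit + hit, te_n + 1
        per_fold.append((tr_hit / tr_n, te_hit / te_n))
        fold_labels.append(labels)
    return per_fold, fold_labels


def mdr_cvc_oracle(data: pd.DataFrame, y: np.ndarray, pool, order: int,
                   fold_ids: np.ndarray, threshold: float = 1.0) -> dict[tuple, int]:
    """Cross-validation consistency per factor set: per fold, the set with the
    highest training accuracy wins (first in sorted order on ties)."""
    sets = list(itertools.combinations(sorted(pool), order))
    train = {
        s: [a[0] for a in mdr_fold_oracle(data[list(s)], y, fold_ids, threshold)[0]]
        for s in sets
    }
    cvc = {s: 0 for s in sets}
    n_folds = int(fold_ids.max()) + 1
    for f in range(n_folds):
        best, best_acc = None, -1.0
        for s in sets:  # sorted order; strict > keeps the first on ties
            if train[s][f] > best_acc:
                best, best_acc = s, train[s][f]
        cvc[best] += 1
    return cvc


def bh_fdr_oracle(p: list[float]) -> list[float]:
    """Step-up Benjamini-Hochberg q-values by the textbook definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [min(1.0, min(m * p[order[j]] / (j + 1) for j in range(i, m)))
                for i in range(m)]
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def ridge_logistic_oracle(y: np.ndarray, X: np.ndarray, lam: float,
                          penalty_mask: np.ndarray) -> np.ndarray:
    """Penalized-likelihood maximizer via a generic numerical optimizer."""
    from scipy.optimize import minimize

    def neg_pen_loglik(beta):
        eta = X @ beta
        ll = y @ eta - np.logaddexp(0.0, eta).sum()
        return -(ll - 0.5 * lam * (penalty_mask * beta**2).sum())

    res = minimize(neg_pen_loglik, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x
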