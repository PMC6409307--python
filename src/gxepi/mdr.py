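"""Multifactor dimensionality reduction (MDR).

MDR pools the cells of a multilocus contingency table (SNP genotypes 0/1/2
and/or exposure quartiles 1-4) into high- and low-risk classes by the
case/control ratio observed in training data, then scores the resulting
one-dimensional classifier by 10-fold cross-validation.  For each order k the
engine enumerates every k-subset of the factor pool; the cross-validation
consistency (CVC) of a set is the number of folds in which it is the
training-best set of its order, and the reported best set maximizes CVC with
ties broken by average testing accuracy, then by factor ids.

A model is called valid when its average testing accuracy clears 55% and its
CVC is at least 7/10 (both configurable).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ACCURACY_BAR = 0.55
MIN_CVC = 7


@dataclass
class RiskMap:
    """High/low-risk labeling of the cells of one factor combination."""

    factors: tuple[str, ...]
    levels: tuple[tuple, ...]  # observed levels per factor, sorted
    cases: np.ndarray  # per-cell case counts, shape = level counts
    controls: np.ndarray
    high: np.ndarray  # boolean, same shape

    def cell(self, *level_values) -> tuple[int, int, bool]:
        idx = tuple(self.levels[i].index(v) for i, v in enumerate(level_values))
        return int(self.cases[idx]), int(self.controls[idx]), bool(self.high[idx])


@dataclass
class MdrModel:
    factors: tuple[str, ...]
    per_fold: list[tuple[float, float]]  # (train_accuracy, test_accuracy)
    avg_test_accuracy: float
    cv_consistency: int
    risk_map_full: RiskMap
    valid: bool
    n_folds: int = 10
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def label_cells(cases: np.ndarray, controls: np.ndarray,
                threshold: float = 1.0) -> np.ndarray:
    """High-risk iff cases/controls strictly exceeds ``threshold``.

    A cell with controls = 0 and cases > 0 is high; an exact ratio tie and an
    empty cell are low (conservative default).
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    return cases > threshold * controls


def assign_folds(y: np.ndarray, n_folds: int, seed: int,
                 max_retries: int = 5) -> np.ndarray:
    """Stratified fold ids: each class shuffled then dealt round-robin.

    If some fold ends up with a single class (possible only when a class has
    fewer members than folds), the assignment is rebuilt with a fresh seed up
    to ``max_retries`` times, with a log entry.
    """
    y = np.asarray(y)
    rng_seed = seed
    for attempt in range(max_retries + 1):
        rng = np.random.default_rng(rng_seed)
        fold = np.empty(len(y), dtype=np.int64)
        for cls in (0, 1):
            idx = rng.permutation(np.flatnonzero(y == cls))
            fold[idx] = np.arange(len(idx)) % n_folds
        counts = np.zeros((n_folds, 2), dtype=int)
        np.add.at(counts, (fold, y.astype(int)), 1)
        if (counts > 0).all():
            return fold
        log.warning("fold with a single class (attempt %d); rebuilding", attempt + 1)
        rng_seed = rng_seed * 69069 + 1 & 0x7FFFFFFF
    return fold


def _factor_codes(data: pd.DataFrame, factors: tuple[str, ...]):
    """Integer cell codes for complete-case rows of the factor columns."""
    sub = data[list(factors)]
    ok = ~sub.isna().any(axis=1).to_numpy()
    levels = []
    codes = []
    for f in factors:
        vals = sub[f].to_numpy()[ok]
        lev = sorted(pd.unique(vals))
        lookup = {v: i for i, v in enumerate(lev)}
        codes.append(np.fromiter((lookup[v] for v in vals), dtype=np.int64,
                                 count=len(vals)))
        levels.append(tuple(lev))
    dims = tuple(len(lv) for lv in levels)
    idx = np.ravel_multi_index(codes, dims)
    return ok, idx, dims, tuple(levels)


def _fold_accuracies(idx: np.ndarray, y: np.ndarray, fold: np.ndarray,
                     ncells: int, n_folds: int, threshold: float,
                     accuracy: str, unseen: str):
    """Per-fold (train, test) accuracies for one factor set; vectorized."""
    case_cf = np.zeros((ncells, n_folds))
    ctrl_cf = np.zeros((ncells, n_folds))
    np.add.at(case_cf, (idx[y == 1], fold[y == 1]), 1.0)
    np.add.at(ctrl_cf, (idx[y == 0], fold[y == 0]), 1.0)
    tot_case = case_cf.sum(axis=1, keepdims=True)
    tot_ctrl = ctrl_cf.sum(axis=1, keepdims=True)
    tr_case = tot_case - case_cf  # training counts when fold f is held out
    tr_ctrl = tot_ctrl - ctrl_cf
    high = tr_case > threshold * tr_ctrl
    seen = (tr_case + tr_ctrl) > 0

    def acc(case_hit, case_all, ctrl_hit, ctrl_all):
        if accuracy == "balanced":
            with np.errstate(invalid="ignore", divide="ignore"):
                sens = case_hit / case_all
                spec = ctrl_hit / ctrl_all
            return (sens + spec) / 2
        denom = case_all + ctrl_all
        with np.errstate(invalid="ignore", divide="ignore"):
            return (case_hit + ctrl_hit) / denom

    train_acc = acc(np.where(high, tr_case, 0).sum(0), tr_case.sum(0),
                    np.where(~high, tr_ctrl, 0).sum(0), tr_ctrl.sum(0))
    if unseen == "drop":
        te_case, te_ctrl = case_cf * seen, ctrl_cf * seen
    else:  # unseen cells labeled low
        te_case, te_ctrl = case_cf, ctrl_cf
    test_acc = acc(np.where(high, te_case, 0).sum(0), te_case.sum(0),
                   np.where(~high, te_ctrl, 0).sum(0), te_ctrl.sum(0))
    return train_acc, test_acc


def _full_risk_map(factors, idx, y, dims, levels, threshold) -> RiskMap:
    ncells = int(np.prod(dims))
    cases = np.bincount(idx[y == 1], minlength=ncells).reshape(dims)
    controls = np.bincount(idx[y == 0], minlength=ncells).reshape(dims)
    return RiskMap(factors=factors, levels=levels, cases=cases,
                   controls=controls, high=label_cells(cases, controls, threshold))


def evaluate_model(factors, data: pd.DataFrame, y: pd.Series | np.ndarray,
                   n_folds: int = 10, seed: int = 0, threshold: float = 1.0,
                   accuracy: str = "plain", unseen: str = "low",
                   accuracy_bar: float = ACCURACY_BAR, min_cvc: int = MIN_CVC,
                   fold_ids: np.ndarray | None = None) -> MdrModel:
    """Cross-validate one factor combination.

    As the sole candidate its CVC is the full fold count; within a
    :func:`search` CVC is reassigned against the whole pool.
    ``fold_ids`` overrides the seeded stratified assignment (used by tests).
    """
    factors = tuple(factors)
    if len(set(factors)) != len(factors):
        raise ValueError("factor ids must be distinct")
    yarr = np.asarray(y, dtype=int)
    ok, idx, dims, levels = _factor_codes(data, factors)
    if any(d < 2 for d in dims):
        raise ValueError("every factor needs at least 2 observed levels")
    ysub = yarr[ok]
    if fold_ids is None:
        fold = assign_folds(ysub, n_folds, seed)
    else:
        fold = np.asarray(fold_ids)[ok]
    train_acc, test_acc = _fold_accuracies(
        idx, ysub, fold, int(np.prod(dims)), n_folds, threshold, accuracy, unseen)
    avg = float(np.nanmean(test_acc))
    model = MdrModel(
        factors=factors,
        per_fold=list(zip(train_acc.tolist(), test_acc.tolist())),
        avg_test_accuracy=avg,
        cv_consistency=n_folds,
        risk_map_full=_full_risk_map(factors, idx, ysub, dims, levels, threshold),
        valid=avg >= accuracy_bar and n_folds >= min_cvc,
        n_folds=n_folds, seed=seed,
    )
    return model


def search(data: pd.DataFrame, y: pd.Series | np.ndarray, pool,
           orders=(2, 3), n_folds: int = 10, seed: int = 0,
           threshold: float = 1.0, accuracy: str = "plain",
           unseen: str = "low", accuracy_bar: float = ACCURACY_BAR,
           min_cvc: int = MIN_CVC, must_include_any=None) -> dict[int, MdrModel]:
    """Exhaustive MDR search: best factor set per interaction order.

    ``must_include_any`` restricts candidate sets to those containing at least
    one of the given ids (e.g. the exposure quartiles, for a gene-environment
    search over a mixed pool).
    """
    pool = sorted(pool)
    yarr = np.asarray(y, dtype=int)
    results: dict[int, MdrModel] = {}
    for order in orders:
        if len(pool) < order:
            raise ValueError(f"pool of {len(pool)} factors cannot support order {order}")
        sets = [s for s in itertools.combinations(pool, order)
                if not must_include_any or set(s) & set(must_include_any)]
        if not sets:
            continue
        train_mat = np.full((len(sets), n_folds), -np.inf)
        test_mat = np.full((len(sets), n_folds), np.nan)
        cache = {}
        for i, s in enumerate(sets):
            try:
                ok, idx, dims, levels = _factor_codes(data, s)
            except (KeyError, ValueError):
                continue
            if any(d < 2 for d in dims):
                continue
            ysub = yarr[ok]
            fold = assign_folds(ysub, n_folds, seed)
            tr, te = _fold_accuracies(idx, ysub, fold, int(np.prod(dims)),
                                      n_folds, threshold, accuracy, unseen)
            train_mat[i], test_mat[i] = tr, te
            cache[i] = (ok, idx, dims, levels, ysub)
        # CVC: per fold, the set with the best training accuracy
        best_per_fold = np.argmax(train_mat, axis=0)  # first occurrence = lexicographic
        cvc = np.bincount(best_per_fold, minlength=len(sets))
        avg_test = np.nanmean(test_mat, axis=1)
        ranked = sorted(
            (i for i in cache),
            key=lambda i: (-cvc[i], -avg_test[i], sets[i]))
        best = ranked[0]
        ok, idx, dims, levels, ysub = cache[best]
        model = MdrModel(
            factors=sets[best],
            per_fold=list(zip(train_mat[best].tolist(), test_mat[best].tolist())),
            avg_test_accuracy=float(avg_test[best]),
            cv_consistency=int(cvc[best]),
            risk_map_full=_full_risk_map(sets[best], idx, ysub, dims, levels, threshold),
            valid=bool(avg_test[best] >= accuracy_bar and cvc[best] >= min_cvc),
            n_folds=n_folds, seed=seed,
            extras={"n_candidate_sets": len(sets)},
        )
        results[order] = model
    return results


def render_grid(model: MdrModel) -> str:
    """Text contingency grid of the full-data risk map.

    Two factors give one grid (rows = first factor's levels); three factors
    give one panel per level of the third factor, mirroring the usual MDR
    figure layout.  Each cell shows cases/controls and H (high risk, the
    shaded cells of the figures) or L.
    """
    rm = model.risk_map_full
    k = len(rm.factors)
    if k not in (1, 2, 3):
        raise ValueError("grid rendering supports 1-3 factors")

    def one_grid(cases, controls, high, rows, cols, rname, cname):
        width = max(
            [len(f"{int(cases[i, j])}/{int(controls[i, j])}H")
             for i in range(len(rows)) for j in range(len(cols))] + [6])
        head = " " * 8 + "".join(f"{cname}={c!s:<{width + 2}}" for c in cols)
        lines = [head]
        for i, r in enumerate(rows):
            cells = "".join(
                f"{f'{int(cases[i, j])}/{int(controls[i, j])}' + ('H' if high[i, j] else 'L'):<{width + 2 + len(cname) + 1}}"
                for j in range(len(cols)))
            lines.append(f"{rname}={r!s:<5} " + cells)
        return "\n".join(lines)

    if k == 1:
        cases = rm.cases[None, :]
        return one_grid(cases, rm.controls[None, :], rm.high[None, :],
                        ["-"], list(rm.levels[0]), "", rm.factors[0])
    if k == 2:
        return (f"{model.factors[0]} x {model.factors[1]} "
                f"(avg test acc {model.avg_test_accuracy:.3f}, CVC {model.cv_consistency}/{model.n_folds})\n"
                + one_grid(rm.cases, rm.controls, rm.high,
                           list(rm.levels[0]), list(rm.levels[1]),
                           rm.factors[0], rm.factors[1]))
    panels = []
    for m, lev in enumerate(rm.levels[2]):
        panels.append(f"[{rm.factors[2]} = {lev}]\n"
                      + one_grid(rm.cases[:, :, m], rm.controls[:, :, m],
                                 rm.high[:, :, m], list(rm.levels[0]),
                                 list(rm.levels[1]), rm.factors[0], rm.factors[1]))
    header = (f"{' x '.join(model.factors)} (avg test acc "
              f"{model.avg_test_accuracy:.3f}, CVC {model.cv_consistency}/{model.n_folds})")
    return header + "\n" + "\n\n".join(panels)


def render_grid_figure(model: MdrModel, path: str | None = None):
    """Matplotlib rendering of the contingency grid: shaded high-risk cells
    with case/control bars, one panel per third-factor level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rm = model.risk_map_full
    k = len(rm.factors)
    n_panels = 1 if k == 2 else len(rm.levels[2])
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 4), squeeze=False)
    for m in range(n_panels):
        ax = axes[0, m]
        if k == 2:
            cases, controls, high = rm.cases, rm.controls, rm.high
        else:
            cases, controls, high = rm.cases[:, :, m], rm.controls[:, :, m], rm.high[:, :, m]
        peak = max(cases.max(), controls.max(), 1)
        for i in range(cases.shape[0]):
            for j in range(cases.shape[1]):
                color = "0.55" if high[i, j] else "0.9"
                ax.add_patch(plt.Rectangle((j, i), 1, 1, facecolor=color,
                                           edgecolor="black"))
                for off, cnt, bar_c in ((0.25, cases[i, j], "black"),
                                        (0.55, controls[i, j], "white")):
                    h = 0.8 * cnt / peak
                    ax.add_patch(plt.Rectangle((j + off, i + 0.1), 0.2, h,
                                               facecolor=bar_c, edgecolor="black"))
        ax.set_xlim(0, cases.shape[1])
        ax.set_ylim(cases.shape[0], 0)
        ax.set_xticks(np.arange(cases.shape[1]) + 0.5)
        ax.set_xticklabels(rm.levels[1])
        ax.set_yticks(np.arange(cases.shape[0]) + 0.5)
        ax.set_yticklabels(rm.levels[0])
        ax.set_xlabel(rm.factors[1])
        ax.set_ylabel(rm.factors[0])
        if k == 3:
            ax.set_title(f"{rm.factors[2]} = {rm.levels[2][m]}")
    fig.suptitle(" x ".join(rm.factors))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
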