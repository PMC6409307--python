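"""Forward-stepwise L2-penalized logistic regression (PLR).

The engine fits ridge-penalized logistic models by IRLS with the intercept and
covariates unpenalized, scores each model by C = deviance + cp * df where df
is the effective degrees of freedom trace[(X'WX + L)^-1 X'WX] and cp defaults
to 2 (so at lambda = 0 the score equals AIC), and selects terms greedily:
starting from the covariates-only model, at each step the admissible term
(main effects always; interactions only once a parent main is in the model,
when the hierarchy rule is on) whose addition most decreases C is accepted,
until no addition decreases C.  Factors enter as dummy-coded blocks - SNPs as
3-level genotype factors (reference: homozygous common), exposures as quartile
factors (reference: first quartile) - and a term's whole block is added and
scored jointly.

The ridge penalty keeps models with sparse factor cells estimable where
unpenalized maximum likelihood would separate; that is the method's point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logistic import LogisticFit, fit_logistic

log = logging.getLogger(__name__)

DEFAULT_LAMBDA = 1e-4
DEFAULT_CP = 2.0


@dataclass(frozen=True)
class Term:
    kind: str  # main / interaction
    factors: tuple[str, ...]
    columns: tuple[str, ...]  # dummy-column names within the design

    def __str__(self) -> str:
        return ":".join(self.factors)


@dataclass
class PlrModel:
    terms: list[Term]
    lam: float
    cp: float
    coefficients: pd.Series
    deviance: float
    edf: float
    score_c: float
    path: list[dict] = field(default_factory=list)
    fit: LogisticFit | None = None

    def to_dict(self) -> dict:
        return {
            "terms": [str(t) for t in self.terms],
            "lambda": self.lam,
            "cp": self.cp,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "deviance": float(self.deviance),
            "edf": float(self.edf),
            "score_c": float(self.score_c),
            "path": self.path,
        }


def score_c(deviance: float, edf: float, cp: float = DEFAULT_CP) -> float:
    """Model-selection score C = deviance + cp * df."""
    return float(deviance + cp * edf)


def dummy_block(values: pd.Series, name: str) -> pd.DataFrame:
    """Reference-drop dummy coding of a discrete factor.

    The reference is the smallest observed level (homozygous common for SNPs,
    quartile 1 for exposures).  Levels unobserved in the data yield no column.
    """
    levels = sorted(pd.unique(values.dropna()))
    cols = {
        f"{name}[{lv}]": (values == lv).astype(float).to_numpy()
        for lv in levels[1:]
    }
    return pd.DataFrame(cols, index=values.index)


def build_terms(data: pd.DataFrame, candidates, interactions: bool = True
                ) -> tuple[pd.DataFrame, list[Term]]:
    """Dummy design columns and the candidate term list (mains + pairwise
    interactions).  Constant factors are skipped with a log entry."""
    blocks: dict[str, pd.DataFrame] = {}
    usable = []
    for f in candidates:
        blk = dummy_block(data[f], f)
        if blk.shape[1] == 0:
            log.warning("candidate %s is constant; skipped", f)
            continue
        blocks[f] = blk
        usable.append(f)
    design = pd.concat(blocks.values(), axis=1) if blocks else pd.DataFrame(index=data.index)
    terms = [Term("main", (f,), tuple(blocks[f].columns)) for f in usable]
    if interactions:
        import itertools

        inter_cols = {}
        for a, b in itertools.combinations(usable, 2):
            cols = []
            for ca in blocks[a].columns:
                for cb in blocks[b].columns:
                    cname = f"{ca}:{cb}"
                    prod = blocks[a][ca] * blocks[b][cb]
                    if prod.abs().sum() == 0:
                        continue  # empty cell: no observations carry this product
                    inter_cols[cname] = prod
                    cols.append(cname)
            if cols:
                terms.append(Term("interaction", (a, b), tuple(cols)))
        if inter_cols:
            design = pd.concat([design, pd.DataFrame(inter_cols, index=data.index)], axis=1)
    return design, terms


def fit_ridge_logistic(y: np.ndarray, X: np.ndarray, lam: float,
                       penalty_mask: np.ndarray | None = None) -> LogisticFit:
    """Ridge-penalized logistic fit (thin wrapper over the IRLS core)."""
    return fit_logistic(y, X, lam=lam, penalty_mask=penalty_mask)


def forward_stepwise(y: pd.Series | np.ndarray, data: pd.DataFrame,
                     candidates, covariates: pd.DataFrame | None = None,
                     lam: float = DEFAULT_LAMBDA, cp: float = DEFAULT_CP,
                     hierarchy: bool = True, interactions: bool = True,
                     max_terms: int | None = None) -> PlrModel:
    """Greedy forward selection of factor terms by the score C.

    ``covariates`` (with an intercept column first; one is prepended if
    absent) stay in every model and are never penalized.  Rows with a missing
    outcome, covariate, or candidate factor are dropped complete-case.
    """
    yarr = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    elif "intercept" not in covariates.columns:
        covariates = covariates.copy()
        covariates.insert(0, "intercept", 1.0)
    design, terms = build_terms(data, candidates, interactions=interactions)
    full = pd.concat([covariates, design], axis=1)
    ok = ~(np.isnan(yarr) | full.isna().any(axis=1).to_numpy())
    yv = yarr[ok]
    full = full.loc[ok]
    n_cov = covariates.shape[1]

    def fit_cols(colnames: list[str]) -> LogisticFit:
        X = full[list(covariates.columns) + colnames].to_numpy()
        mask = np.r_[np.zeros(n_cov), np.ones(len(colnames))]
        return fit_logistic(yv, X, lam=lam, penalty_mask=mask)

    selected: list[Term] = []
    sel_cols: list[str] = []
    current = fit_cols([])
    current_c = score_c(current.deviance, current.edf, cp)
    path = [{"step": 0, "term": None, "score_c": current_c,
             "deviance": current.deviance, "edf": current.edf}]
    remaining = list(terms)
    while remaining:
        if max_terms is not None and len(selected) >= max_terms:
            break
        in_model = {f for t in selected for f in t.factors}
        admissible = [
            t for t in remaining
            if t.kind == "main" or not hierarchy or set(t.factors) & in_model
        ]
        best_t, best_fit, best_c = None, None, current_c
        for t in admissible:
            trial = fit_cols(sel_cols + list(t.columns))
            if not trial.converged:
                continue
            c = score_c(trial.deviance, trial.edf, cp)
            if c < best_c - 1e-10:
                best_t, best_fit, best_c = t, trial, c
        if best_t is None:
            break
        selected.append(best_t)
        sel_cols.extend(best_t.columns)
        remaining.remove(best_t)
        current, current_c = best_fit, best_c
        path.append({"step": len(selected), "term": str(best_t),
                     "score_c": current_c, "deviance": current.deviance,
                     "edf": current.edf})

    names = list(covariates.columns) + sel_cols
    return PlrModel(
        terms=selected, lam=lam, cp=cp,
        coefficients=pd.Series(current.beta, index=names),
        deviance=current.deviance, edf=current.edf, score_c=current_c,
        path=path, fit=current,
    )


def approximate_wald_p(model: PlrModel) -> pd.Series:
    """Approximate Wald p-values from the ridge sandwich covariance.

    Caveat: penalized coefficients are shrunken and these p-values inherit
    that bias; they are descriptive only and should not be read as calibrated
    tests.
    """
    from scipy import stats

    fit = model.fit
    if fit is None or fit.cov is None:
        return pd.Series(dtype=float)
    se = np.sqrt(np.diag(fit.cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = fit.beta / se
    return pd.Series(2 * stats.norm.sf(np.abs(z)), index=model.coefficients.index)
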