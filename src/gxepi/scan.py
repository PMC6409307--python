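"""Logistic interaction scan with Benjamini-Hochberg FDR.

One model per factor pair: intercept + covariates + both main effects + their
product, Wald-testing the product term.  Gene-gene scans use additive-coded
SNPs adjusted for age, sex and ethnocultural group; gene-environment scans use
continuous energy-adjusted nutrient residuals adjusted for age, physical
activity, group and sex.  q-values are computed within one
(outcome x scan-type) family.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .logistic import fit_logistic

log = logging.getLogger(__name__)

GXG_COVARIATES = ("age", "sex", "group")
GXE_COVARIATES = ("age", "mets", "group", "sex")


def covariate_design(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    """Intercept + covariate columns; group as indicators (Caucasian
    reference), sex as a single male indicator."""
    cols = {"intercept": np.ones(len(cohort))}
    for c in covariates:
        if c == "sex":
            cols["sex_M"] = (cohort["sex"] == "M").astype(float).to_numpy()
        elif c == "group":
            for g in ("EastAsian", "SouthAsian", "Other"):
                cols[f"group_{g}"] = (cohort["group"] == g).astype(float).to_numpy()
        else:
            cols[c] = cohort[c].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index)


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values stay NaN and are
    excluded from the family size."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _fit_pair(y, Xcov, x1, x2, id1, id2, outcome):
    ok = ~(np.isnan(x1) | np.isnan(x2) | np.isnan(y))
    X = np.column_stack([Xcov[ok], x1[ok], x2[ok], (x1 * x2)[ok]])
    row = {"outcome": outcome, "term1": id1, "term2": id2,
           "n_used": int(ok.sum()), "beta": np.nan, "se": np.nan,
           "wald_p": np.nan, "converged": False}
    try:
        fit = fit_logistic(y[ok], X)
    except (ValueError, np.linalg.LinAlgError) as exc:
        log.warning("scan model %s x %s failed: %s", id1, id2, exc)
        return row
    j = X.shape[1] - 1
    row["converged"] = bool(fit.converged)
    if fit.converged and fit.cov is not None:
        row["beta"] = float(fit.beta[j])
        row["se"] = float(np.sqrt(fit.cov[j, j]))
        row["wald_p"] = fit.wald_p(j)
    return row


def scan_gxg(labels: pd.Series, geno: pd.DataFrame, cohort: pd.DataFrame,
             snp_genes: dict[str, str], cross_gene_only: bool = True,
             outcome: str = "bmi") -> pd.DataFrame:
    """All twofold SNP x SNP interaction models for one outcome.

    By default only cross-gene pairs are fitted (pathway epistasis is the
    scientific question); ``cross_gene_only=False`` scans every pair.
    """
    Xcov = covariate_design(cohort, GXG_COVARIATES).to_numpy()
    y = labels.to_numpy(dtype=float)
    rows = []
    snps = sorted(geno.columns)
    for a, b in itertools.combinations(snps, 2):
        if cross_gene_only and snp_genes.get(a) == snp_genes.get(b):
            continue
        rows.append(_fit_pair(y, Xcov, geno[a].to_numpy(dtype=float),
                              geno[b].to_numpy(dtype=float), a, b, outcome))
    out = pd.DataFrame(rows)
    if len(out):
        n_bad = int((~out["converged"]).sum())
        if n_bad:
            log.info("%d non-converged models excluded from FDR family", n_bad)
        out["fdr_q"] = bh_fdr(out["wald_p"])
    return out


def scan_gxe(labels: pd.Series, geno: pd.DataFrame, exposures: pd.DataFrame,
             cohort: pd.DataFrame, outcome: str = "bmi") -> pd.DataFrame:
    """All SNP x nutrient-residual interaction models for one outcome.

    Exposures are the continuous energy-adjusted residuals (one column per
    nutrient); degenerate all-zero exposures are skipped.
    """
    Xcov = covariate_design(cohort, GXE_COVARIATES).to_numpy()
    y = labels.to_numpy(dtype=float)
    rows = []
    for snp in sorted(geno.columns):
        g = geno[snp].to_numpy(dtype=float)
        for nut in exposures.columns:
            e = exposures[nut].to_numpy(dtype=float)
            if np.nanstd(e) == 0:
                log.warning("exposure %s has zero variance; skipped", nut)
                continue
            rows.append(_fit_pair(y, Xcov, g, e, snp, nut, outcome))
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_q"] = bh_fdr(out["wald_p"])
    return out
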