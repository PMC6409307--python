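"""Genotype quality control: MAF, Hardy-Weinberg test, LD r^2, and the
HWE -> MAF -> LD pruning cascade, plus genotype encodings.

The cascade order matches standard candidate-gene practice: SNPs out of HWE
(chi-square p <= 0.01) go first, then minor allele frequency < 5%, then greedy
pruning of pairs with genotypic r^2 > 0.8 among the survivors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"hwe_p": 0.01, "maf": 0.05, "r2": 0.8}


def genotype_counts(column: np.ndarray | pd.Series) -> tuple[int, int, int]:
    """(n_AA, n_Aa, n_aa) over non-missing entries of a 0/1/2 column."""
    g = np.asarray(column, dtype=float)
    g = g[~np.isnan(g)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def compute_maf(column: np.ndarray | pd.Series) -> float:
    """Minor allele frequency of a 0/1/2 column, folded to <= 0.5.

    The coded allele is assumed minor; if its frequency exceeds 0.5 the value
    is folded and the fold is logged.
    """
    g = np.asarray(column, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError("all genotypes missing")
    freq = g.sum() / (2 * g.size)
    if freq > 0.5:
        log.info("coded allele is major (freq %.3f); folding MAF", freq)
        freq = 1.0 - freq
    return float(freq)


def hwe_test(counts: tuple[int, int, int], method: str = "chisq") -> float:
    """Hardy-Weinberg goodness-of-fit p-value from (n_AA, n_Aa, n_aa).

    ``chisq`` is the 1-df chi-square test against expected counts at the
    sample allele frequency; ``exact`` is the conditional exact test summing
    heterozygote-count probabilities no larger than the observed one.
    Monomorphic columns return p = 1 by convention.
    """
    n_aa_, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa_ + n_ab + n_bb
    if n < 1:
        raise ValueError("empty genotype counts")
    n_b = n_ab + 2 * n_bb
    n_a = 2 * n - n_b
    if n_a == 0 or n_b == 0:
        log.info("monomorphic SNP; HWE p set to 1")
        return 1.0
    if method == "chisq":
        q = n_b / (2 * n)
        expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
        observed = np.array([n_aa_, n_ab, n_bb], dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n_ab, n_a, n_b)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_het: int, n_a: int, n_b: int) -> float:
    """Conditional exact HWE test (sum of P(het count) <= P(observed))."""
    rare, common = min(n_a, n_b), max(n_a, n_b)
    n = (n_a + n_b) // 2
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def logp(h):
        # Levene conditional distribution, up to a constant normalized away
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (h * np.log(2) - gammaln(h + 1)
                - gammaln(hom_r + 1) - gammaln(hom_c + 1))

    lp = np.array([logp(int(h)) for h in hets])
    p = np.exp(lp - lp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def ld_r2(col_a: np.ndarray | pd.Series, col_b: np.ndarray | pd.Series) -> float:
    """Genotypic r^2: squared Pearson correlation of minor-allele counts over
    pairwise-complete observations."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("fewer than 2 complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a genotype column")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class SnpQc:
    rsid: str
    gene: str
    maf: float
    hwe_p: float
    qc_status: str  # pass / fail_hwe / fail_maf / fail_ld
    ld_partner: str | None = None


def qc_pipeline(geno: pd.DataFrame, info: pd.DataFrame,
                thresholds: dict | None = None,
                hwe_method: str = "chisq") -> pd.DataFrame:
    """Run the HWE -> MAF -> LD cascade; returns a per-SNP QC table.

    LD pruning is greedy: among SNPs surviving HWE and MAF, repeatedly take
    the highest-r^2 pair above the threshold and drop its lower-MAF member
    (ties broken by keeping the lexicographically smaller rsid).  The result
    is idempotent: rerunning on the surviving panel changes nothing.
    """
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    gene_of = dict(zip(info["rsid"], info["gene"]))
    records: dict[str, SnpQc] = {}
    for rsid in info["rsid"]:
        col = geno[rsid]
        maf = compute_maf(col)
        hwe_p = hwe_test(genotype_counts(col), method=hwe_method)
        records[rsid] = SnpQc(rsid=rsid, gene=gene_of[rsid], maf=maf,
                              hwe_p=hwe_p, qc_status="pass")
    for r in records.values():
        if r.hwe_p <= thr["hwe_p"]:
            r.qc_status = "fail_hwe"
    for r in records.values():
        if r.qc_status == "pass" and r.maf < thr["maf"]:
            r.qc_status = "fail_maf"

    survivors = [r.rsid for r in records.values() if r.qc_status == "pass"]
    pair_r2: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(sorted(survivors), 2):
        try:
            pair_r2[(a, b)] = ld_r2(geno[a], geno[b])
        except ValueError:
            continue
    alive = set(survivors)
    while True:
        live = [(r2, pair) for pair, r2 in pair_r2.items()
                if r2 > thr["r2"] and pair[0] in alive and pair[1] in alive]
        if not live:
            break
        live.sort(key=lambda t: (-t[0], t[1]))
        _, (a, b) = live[0]
        if records[a].maf != records[b].maf:
            drop = a if records[a].maf < records[b].maf else b
        else:
            drop = max(a, b)  # keep the lexicographically smaller rsid
        keep = b if drop == a else a
        records[drop].qc_status = "fail_ld"
        records[drop].ld_partner = keep
        alive.discard(drop)

    out = pd.DataFrame([vars(r) for r in (records[rs] for rs in info["rsid"])])
    counts = out[out.qc_status == "pass"].groupby("gene").size().to_dict()
    log.info("QC survivors per gene: %s", counts)
    return out


def encode(geno: pd.DataFrame, scheme: str = "additive") -> pd.DataFrame:
    """Encode QC-passed genotype columns for modelling.

    additive: numeric minor-allele counts (logistic regression);
    categorical: 3-level string factors (MDR / PLR).  Missing genotypes stay
    missing and are removed complete-case per fitted model downstream.
    """
    if scheme == "additive":
        return geno.astype(float)
    if scheme == "categorical":
        return geno.map(lambda v: v if pd.isna(v) else str(int(v)))
    raise ValueError(f"unknown encoding scheme {scheme!r}")
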