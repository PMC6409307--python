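"""Synthetic cohort generator.

Generates a multiethnic young-adult cohort with FFQ-style intakes, a tag-SNP
panel under Hardy-Weinberg equilibrium with configurable MAF and LD structure,
dietary misreporters and missing outcomes, and dichotomous adiposity outcomes
drawn from a logistic liability model (or a two-locus penetrance table for
pure-epistasis designs).  Continuous BMI and waist circumference are drawn
conditional on the latent binary liability so downstream dichotomization
recovers the planted labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    ENERGY_LOWER,
    ENERGY_UPPER,
    GROUPS,
    NUTRIENTS,
    OutcomeEffects,
    SimulationConfig,
    SnpSpec,
    default_snp_panel,
)

COHORT_COLUMNS = [
    "participant_id", "sex", "age", "group", "smoking", "mets",
    "energy_total", "carb", "fat", "protein", "alcohol", "bmi", "wc",
    "flag", "bmi_case_latent", "wc_case_latent",
]


def plant_xor_penetrance(high_p: float, low_p: float) -> np.ndarray:
    """3x3 penetrance table where cells with odd total minor-allele count get
    ``high_p`` and the rest ``low_p``.

    With both MAFs at 0.5 under HWE this is a purely epistatic model: each
    single-locus marginal penetrance equals ``(high_p + low_p) / 2``.
    """
    if not (0.0 <= low_p <= high_p <= 1.0):
        raise ValueError("require 0 <= low_p <= high_p <= 1")
    g1, g2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    return np.where((g1 + g2) % 2 == 1, high_p, low_p).astype(float)


def _allocate_groups(n: int, proportions, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of group labels, then a random permutation."""
    names = list(GROUPS)
    p = np.array([proportions[g] for g in names])
    base = np.floor(n * p).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(n * p - base))
    base[order[:rem]] += 1
    labels = np.repeat(names, base)
    return rng.permutation(labels)


def _truncated_lognormal(n, mean, sd, lower, upper, rng) -> np.ndarray:
    """Log-normal with given arithmetic mean/sd, truncated to [lower, upper]."""
    cv2 = (sd / mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(mean) - sigma**2 / 2
    a = (np.log(lower) - mu) / sigma
    b = (np.log(upper) - mu) / sigma
    u = rng.random(n)
    z = stats.truncnorm.ppf(u, a, b)
    return np.exp(mu + sigma * z)


def _hwe_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    q = maf
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    return rng.choice(3, size=n, p=probs)


def _simulate_genotypes(config: SimulationConfig, groups: np.ndarray,
                        rng: np.random.Generator) -> pd.DataFrame:
    n = len(groups)
    cols: dict[str, np.ndarray] = {}
    plain = [s for s in config.snps if s.ld_partner is None]
    dups = [s for s in config.snps if s.ld_partner is not None]
    specs = {s.rsid: s for s in config.snps}
    for s in plain:
        g = np.empty(n, dtype=np.int64)
        for name in GROUPS:
            idx = np.flatnonzero(groups == name)
            g[idx] = _hwe_genotypes(len(idx), s.maf_for(name), rng)
        cols[s.rsid] = g
    for s in dups:
        if s.target_r2 is None or s.target_r2 > 1.0:
            raise ValueError(f"{s.rsid}: infeasible LD target r2 {s.target_r2}")
        partner = specs[s.ld_partner]
        # copy-with-redraw: P(redraw) = 1 - sqrt(r2) gives E[r^2] = target
        f = 1.0 - np.sqrt(s.target_r2)
        g = cols[s.ld_partner].copy()
        redraw = rng.random(n) < f
        for name in GROUPS:
            idx = np.flatnonzero((groups == name) & redraw)
            g[idx] = _hwe_genotypes(len(idx), partner.maf_for(name), rng)
        cols[s.rsid] = g
    geno = pd.DataFrame({s.rsid: cols[s.rsid].astype(float) for s in config.snps})
    if config.genotype_missing_rate > 0:
        mask = rng.random(geno.shape) < config.genotype_missing_rate
        geno = geno.mask(mask)
    return geno


def _liability_probability(effects: OutcomeEffects, cohort: pd.DataFrame,
                           geno: pd.DataFrame) -> np.ndarray:
    n = len(cohort)
    if effects.penetrance:
        if len(effects.penetrance) > 1:
            raise ValueError("at most one penetrance table per outcome")
        (pair, table), = effects.penetrance.items()
        table = np.asarray(table, dtype=float)
        g1 = geno[pair[0]].to_numpy().astype(int)
        g2 = geno[pair[1]].to_numpy().astype(int)
        return table[g1, g2]

    logit = np.array([effects.baseline_for(g) for g in cohort["group"]], dtype=float)

    def code(factor: str) -> np.ndarray:
        if factor in geno.columns:
            return geno[factor].to_numpy()
        x = cohort[factor].to_numpy(dtype=float)
        return x - x.mean()

    for factor, odds in effects.main_or.items():
        logit += np.log(odds) * code(factor)
    for (f1, f2), odds in effects.interaction_or.items():
        logit += np.log(odds) * code(f1) * code(f2)
    return 1.0 / (1.0 + np.exp(-logit))


def _continuous_bmi(case: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(case)
    lo, hi, m, s = 16.0, 25.0, 22.0, 2.5
    a, b = (lo - m) / s, (hi - m) / s
    controls = m + s * stats.truncnorm.ppf(rng.random(n), a, b)
    cases = hi + rng.gamma(2.0, 2.0, size=n)
    return np.where(case, cases, controls)


def _continuous_wc(case: np.ndarray, sex: np.ndarray, thresholds,
                   rng: np.random.Generator) -> np.ndarray:
    n = len(case)
    out = np.empty(n)
    for sx in ("F", "M"):
        idx = np.flatnonzero(sex == sx)
        thr = float(thresholds[sx])
        m, s = thr - 8.0, 5.0
        a, b = (thr - 30.0 - m) / s, (thr - m) / s
        controls = m + s * stats.truncnorm.ppf(rng.random(len(idx)), a, b)
        cases = thr + rng.gamma(2.0, 2.5, size=len(idx))
        out[idx] = np.where(case[idx], cases, controls)
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cohort table, genotype matrix) for a configuration.

    The cohort carries a provenance ``flag`` column
    (ok / under_report / over_report / missing_outcome) and the latent binary
    liabilities ``bmi_case_latent`` / ``wc_case_latent`` for test assertions.
    Identical configurations (including seed) produce identical output.
    """
    config.validate()
    n = config.n_recruited
    ss = np.random.SeedSequence(config.seed)
    r_demo, r_intake, r_geno, r_outcome, r_flags = (
        np.random.default_rng(s) for s in ss.spawn(5))

    groups = _allocate_groups(n, config.group_proportions, r_demo)
    sex = np.where(r_demo.random(n) < config.female_fraction, "F", "M")
    lo, hi = config.age_range
    age = np.round(lo + (hi - lo) * r_demo.random(n), 1)
    smoking = np.where(r_demo.random(n) < config.smoking_rate, "yes", "no")
    mets = np.clip(r_demo.normal(config.mets_mean, config.mets_sd, n), 0.1, None)

    im = config.intake_model
    energy = np.empty(n)
    for sx in ("F", "M"):
        idx = np.flatnonzero(sex == sx)
        energy[idx] = _truncated_lognormal(
            len(idx), im.energy_mean, im.energy_sd,
            ENERGY_LOWER, ENERGY_UPPER[sx], r_intake)
    weights = np.column_stack([
        im.shares[nut] * np.exp(r_intake.normal(0.0, im.share_noise_sd, n))
        for nut in NUTRIENTS
    ])
    weights /= weights.sum(axis=1, keepdims=True)
    components = weights * energy[:, None]

    geno = _simulate_genotypes(config, groups, r_geno)

    cohort = pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(1, n + 1)],
        "sex": sex, "age": age, "group": groups, "smoking": smoking,
        "mets": np.round(mets, 2),
        "energy_total": energy,
        **{nut: components[:, j] for j, nut in enumerate(NUTRIENTS)},
    })

    p_bmi = _liability_probability(config.bmi_effects, cohort, geno)
    p_wc = _liability_probability(config.wc_effects, cohort, geno)
    bmi_case = r_outcome.random(n) < p_bmi
    wc_case = r_outcome.random(n) < p_wc
    cohort["bmi"] = np.round(_continuous_bmi(bmi_case, r_outcome), 2)
    cohort["wc"] = np.round(_continuous_wc(wc_case, sex, config.wc_thresholds, r_outcome), 2)

    flag = np.array(["ok"] * n, dtype=object)
    mis = config.misreporters
    f_idx = r_flags.permutation(np.flatnonzero(sex == "F"))
    m_idx = r_flags.permutation(np.flatnonzero(sex == "M"))
    wanted = {"F": mis.under_f + mis.over_f, "M": mis.under_m + mis.over_m}
    for sx, idx in (("F", f_idx), ("M", m_idx)):
        if len(idx) < wanted[sx]:
            raise ValueError(f"not enough {sx} rows for configured misreporters")
    under = np.concatenate([f_idx[:mis.under_f], m_idx[:mis.under_m]])
    over_f = f_idx[mis.under_f:mis.under_f + mis.over_f]
    over_m = m_idx[mis.under_m:mis.under_m + mis.over_m]
    scale = np.ones(n)
    new_energy = cohort["energy_total"].to_numpy().copy()
    new_energy[under] = r_flags.uniform(350.0, 795.0, len(under))
    new_energy[over_f] = r_flags.uniform(3550.0, 4600.0, len(over_f))
    new_energy[over_m] = r_flags.uniform(4050.0, 5100.0, len(over_m))
    touched = np.concatenate([under, over_f, over_m])
    scale[touched] = new_energy[touched] / cohort["energy_total"].to_numpy()[touched]
    cohort["energy_total"] = new_energy
    for nut in NUTRIENTS:
        cohort[nut] = cohort[nut].to_numpy() * scale
    flag[under] = "under_report"
    flag[np.concatenate([over_f, over_m])] = "over_report"

    untouched = np.setdiff1d(np.arange(n), touched)
    miss = r_flags.permutation(untouched)[:config.n_missing_outcome]
    cohort.loc[miss, ["bmi", "wc"]] = np.nan
    flag[miss] = "missing_outcome"

    cohort["flag"] = flag
    cohort["bmi_case_latent"] = bmi_case.astype(int)
    cohort["wc_case_latent"] = wc_case.astype(int)
    for nut in ("energy_total", *NUTRIENTS):
        cohort[nut] = np.round(cohort[nut], 1)
    geno.index = cohort["participant_id"]
    return cohort[COHORT_COLUMNS], geno


def snp_qc_fixture(n: int = 1512, panel: list[SnpSpec] | None = None,
                   swap_fraction: float = 0.03) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic deterministic genotype matrix for the QC worked example.

    Each non-duplicate SNP column holds genotype counts at exact (rounded)
    Hardy-Weinberg proportions for its configured MAF, independently shuffled,
    so every SNP passes the HWE test by construction.  LD-duplicate columns are
    copies of their partner with a small fraction of entries re-shuffled among
    themselves (genotype counts, hence MAF, preserved exactly; genotypic r^2
    stays far above the pruning threshold).

    Returns (genotype matrix, SNP info frame with rsid and gene).
    """
    panel = list(panel) if panel is not None else default_snp_panel()
    cols: dict[str, np.ndarray] = {}
    for j, s in enumerate(panel):
        rng = np.random.default_rng(np.random.SeedSequence([7919, j]))
        if s.ld_partner is None:
            q = s.maf_for(GROUPS[0])
            n2 = int(round(n * q * q))
            n1 = int(round(n * 2 * q * (1 - q)))
            n0 = n - n1 - n2
            col = np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2.0)])
            cols[s.rsid] = rng.permutation(col)
        else:
            col = cols[s.ld_partner].copy()
            k = max(2, int(round(swap_fraction * n)))
            pos = rng.choice(n, size=k, replace=False)
            col[pos] = col[rng.permutation(pos)]
            cols[s.rsid] = col
    geno = pd.DataFrame(cols, index=[f"P{i:05d}" for i in range(1, n + 1)])
    info = pd.DataFrame({"rsid": [s.rsid for s in panel],
                         "gene": [s.gene for s in panel]})
    return geno, info
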