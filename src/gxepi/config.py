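"""Simulation configuration for the synthetic multiethnic cohort.

The generator emulates the structure of a young-adult nutrigenomics cohort:
four ethnocultural groups, FFQ-style correlated macronutrient intakes, a tag-SNP
panel in three inflammation-pathway genes (NFKB1, IKBKB, SOCS3) with a
configurable MAF/LD/HWE structure, dietary misreporters, missing outcomes, and
dichotomous adiposity outcomes (high BMI, high waist circumference) drawn from a
logistic liability model with optional planted interactions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

GROUPS = ("Caucasian", "EastAsian", "SouthAsian", "Other")
GENES = ("NFKB1", "IKBKB", "SOCS3")
NUTRIENTS = ("carb", "fat", "protein", "alcohol")

#: dietary plausibility bounds, kcal/day (exclusion is strict: <800, >upper)
ENERGY_LOWER = 800.0
ENERGY_UPPER = {"F": 3500.0, "M": 4000.0}


@dataclass(frozen=True)
class SnpSpec:
    """One SNP of the simulated panel.

    ``maf`` may be a single fraction (shared across groups) or a mapping
    group -> fraction for population structure.  ``ld_partner`` marks the SNP
    as a high-LD copy of another panel member, generated by copying the
    partner's genotypes and re-drawing each with a small probability calibrated
    so the expected genotypic r^2 equals ``target_r2``.
    """

    rsid: str
    gene: str
    maf: float | Mapping[str, float] = 0.25
    ld_partner: str | None = None
    target_r2: float | None = None

    def maf_for(self, group: str) -> float:
        if isinstance(self.maf, Mapping):
            return float(self.maf[group])
        return float(self.maf)


@dataclass
class IntakeModel:
    """Log-normal total energy plus noisy energy shares for the components.

    Components are renormalized so carbohydrate + fat + protein + alcohol
    kcal sum exactly to total energy, giving the positive nutrient-energy
    correlation the residual energy-adjustment method requires.
    Default shares correspond to a typical young-adult FFQ profile
    (~52% carbohydrate, ~30% fat, ~17% protein, ~2% alcohol of energy).
    """

    energy_mean: float = 1970.0  # kcal/day
    energy_sd: float = 650.0
    shares: Mapping[str, float] = field(
        default_factory=lambda: {"carb": 0.52, "fat": 0.295, "protein": 0.17, "alcohol": 0.015}
    )
    share_noise_sd: float = 0.25  # lognormal sd on each share weight


@dataclass
class Misreporters:
    """Counts of rows overwritten post hoc with implausible energy intakes."""

    under_f: int = 40
    under_m: int = 20
    over_f: int = 40
    over_m: int = 24

    @property
    def total(self) -> int:
        return self.under_f + self.under_m + self.over_f + self.over_m


@dataclass
class OutcomeEffects:
    """Logistic liability model for one dichotomous outcome.

    ``baseline_logit`` is either a scalar or a per-group mapping.  Main-effect
    odds ratios apply per minor allele (SNPs, additive coding) or per kcal/day
    of mean-centred intake (nutrients).  Interaction ORs multiply onto the
    product of the two component codes.  A penetrance table for a SNP pair
    overrides the liability model entirely for pure-epistasis designs.
    """

    baseline_logit: float | Mapping[str, float] = 0.0
    main_or: Mapping[str, float] = field(default_factory=dict)
    interaction_or: Mapping[tuple[str, str], float] = field(default_factory=dict)
    penetrance: Mapping[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def baseline_for(self, group: str) -> float:
        if isinstance(self.baseline_logit, Mapping):
            return float(self.baseline_logit[group])
        return float(self.baseline_logit)

    def referenced_factors(self) -> set[str]:
        out: set[str] = set(self.main_or)
        for pair in self.interaction_or:
            out.update(pair)
        for pair in self.penetrance:
            out.update(pair)
        return out


def default_group_proportions() -> dict[str, float]:
    # 733 / 509 / 160 / 110 of the 1,512 retained after exclusions
    return {
        "Caucasian": 733 / 1512,
        "EastAsian": 509 / 1512,
        "SouthAsian": 160 / 1512,
        "Other": 110 / 1512,
    }


def default_bmi_baselines() -> dict[str, float]:
    # group-specific high-BMI prevalences ~25% / 12% / 29% / 34%
    def logit(p: float) -> float:
        return float(np.log(p / (1 - p)))

    return {
        "Caucasian": logit(0.25),
        "EastAsian": logit(0.12),
        "SouthAsian": logit(0.29),
        "Other": logit(0.34),
    }


def default_snp_panel() -> list[SnpSpec]:
    """54-SNP tag panel: SOCS3 27, NFKB1 18, IKBKB 9.

    24 common SNPs drawn under HWE (8 SOCS3 + 9 NFKB1 + 3 IKBKB survive QC),
    30 below the 5% MAF filter (17 SOCS3, 8 NFKB1, 5 IKBKB) and 4 high-LD
    copies of retained SNPs (2 SOCS3, 1 NFKB1, 1 IKBKB).  rsids of SNPs the
    study's final panel is known to contain are used where available; the rest
    are synthetic placeholders.
    """
    common = {
        "SOCS3": ["rs6501199", "rs4969172", "rs4436839", "rs12944581", "rs9914220",
                  "rs9500001", "rs9500002", "rs9500003"],
        "NFKB1": ["rs3774932", "rs1599961", "rs3774956", "rs11722146", "rs4698863",
                  "rs1609798", "rs3774968", "rs7674640", "rs9600001"],
        "IKBKB": ["rs3747811", "rs9700001", "rs9700002"],
    }
    # deterministic, spread-out common MAFs in [0.10, 0.45]
    mafs = {
        "SOCS3": [0.32, 0.28, 0.41, 0.22, 0.18, 0.36, 0.12, 0.45],
        "NFKB1": [0.38, 0.30, 0.25, 0.20, 0.34, 0.42, 0.15, 0.27, 0.10],
        "IKBKB": [0.33, 0.21, 0.40],
    }
    low_counts = {"SOCS3": 17, "NFKB1": 8, "IKBKB": 5}
    ld_partners = {
        "SOCS3": ["rs6501199", "rs4969172"],
        "NFKB1": ["rs3774932"],
        "IKBKB": ["rs3747811"],
    }
    panel: list[SnpSpec] = []
    for gene in ("SOCS3", "NFKB1", "IKBKB"):
        for rsid, maf in zip(common[gene], mafs[gene]):
            panel.append(SnpSpec(rsid=rsid, gene=gene, maf=maf))
        for j in range(low_counts[gene]):
            maf = 0.005 + 0.04 * (j + 0.5) / low_counts[gene]  # all < 0.05
            panel.append(SnpSpec(rsid=f"rs{gene[:2].lower()}low{j:02d}", gene=gene, maf=maf))
        for j, partner in enumerate(ld_partners[gene]):
            panel.append(
                SnpSpec(rsid=f"rs{gene[:2].lower()}dup{j:02d}", gene=gene,
                        ld_partner=partner, target_r2=0.95)
            )
    assert len(panel) == 54
    return panel


@dataclass
class SimulationConfig:
    seed: int = 0
    n_recruited: int = 1639
    group_proportions: Mapping[str, float] = field(default_factory=default_group_proportions)
    female_fraction: float = 1033 / 1512
    age_range: tuple[float, float] = (20.0, 29.0)
    smoking_rate: float = 0.065
    mets_mean: float = 6.2
    mets_sd: float = 2.5
    snps: Sequence[SnpSpec] = field(default_factory=default_snp_panel)
    genotype_missing_rate: float = 0.0
    intake_model: IntakeModel = field(default_factory=IntakeModel)
    misreporters: Misreporters = field(default_factory=Misreporters)
    n_missing_outcome: int = 3
    bmi_effects: OutcomeEffects = field(default_factory=lambda: OutcomeEffects(
        baseline_logit=default_bmi_baselines()))
    wc_effects: OutcomeEffects = field(default_factory=lambda: OutcomeEffects(
        baseline_logit=float(np.log(0.25 / 0.75))))
    # continuous-anthropometry generation, conditional on the binary liability
    wc_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"M": 85.25, "F": 74.73})

    @property
    def n_low_maf(self) -> int:
        return sum(
            1 for s in self.snps
            if s.ld_partner is None and all(s.maf_for(g) < 0.05 for g in GROUPS)
        )

    @property
    def n_ld_duplicates(self) -> int:
        return sum(1 for s in self.snps if s.ld_partner is not None)

    def validate(self) -> None:
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions sum to {total}, expected 1")
        if set(self.group_proportions) != set(GROUPS):
            raise ValueError(f"group proportions must cover exactly {GROUPS}")
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsid in SNP panel")
        known = set(rsids)
        for s in self.snps:
            for g in GROUPS:
                m = s.maf_for(g)
                if not (0.0 < m <= 0.5) and s.ld_partner is None:
                    raise ValueError(f"{s.rsid}: MAF {m} outside (0, 0.5]")
            if s.ld_partner is not None:
                if s.ld_partner not in known:
                    raise ValueError(f"{s.rsid}: unknown LD partner {s.ld_partner}")
                if s.target_r2 is None or not (0.0 < s.target_r2 <= 1.0):
                    raise ValueError(f"{s.rsid}: infeasible LD target r2 {s.target_r2}")
        for name, eff in (("bmi", self.bmi_effects), ("wc", self.wc_effects)):
            unknown = eff.referenced_factors() - known - set(NUTRIENTS)
            if unknown:
                raise ValueError(f"{name} effects reference unknown factors: {sorted(unknown)}")
        counts = {
            "misreporters": self.misreporters.total,
            "n_missing_outcome": self.n_missing_outcome,
        }
        for label, c in counts.items():
            if c < 0 or c > self.n_recruited:
                raise ValueError(f"{label} count {c} outside [0, n_recruited]")
        if self.misreporters.total + self.n_missing_outcome > self.n_recruited:
            raise ValueError("flagged rows exceed cohort size")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction outside [0, 1]")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {("|".join(k) if isinstance(k, tuple) else k): _to_plain(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_yaml(config: SimulationConfig) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=True)


def _parse_effects(d: Mapping) -> OutcomeEffects:
    base = d.get("baseline_logit", 0.0)
    inter = {tuple(k.split("|")): float(v) for k, v in d.get("interaction_or", {}).items()}
    pen = {tuple(k.split("|")): np.asarray(v, dtype=float)
           for k, v in d.get("penetrance", {}).items()}
    return OutcomeEffects(
        baseline_logit=base if not isinstance(base, Mapping) else dict(base),
        main_or=dict(d.get("main_or", {})),
        interaction_or=inter,
        penetrance=pen,
    )


def config_from_yaml(text: str) -> SimulationConfig:
    d = yaml.safe_load(text) or {}
    kwargs = dict(d)
    if "snps" in d:
        kwargs["snps"] = [SnpSpec(**{**s, "target_r2": s.get("target_r2")}) for s in d["snps"]]
    if "intake_model" in d:
        kwargs["intake_model"] = IntakeModel(**d["intake_model"])
    if "misreporters" in d:
        kwargs["misreporters"] = Misreporters(**d["misreporters"])
    for key, attr in (("bmi_effects", "bmi_effects"), ("wc_effects", "wc_effects")):
        if key in d:
            kwargs[attr] = _parse_effects(d[key])
    if "age_range" in d:
        kwargs["age_range"] = tuple(d["age_range"])
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg
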