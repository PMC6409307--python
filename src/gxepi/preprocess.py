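"""Cohort preprocessing: exclusions, outcome dichotomization, energy-adjusted
nutrient residuals, and stratified quartile exposure categories.

Exclusion semantics follow the study protocol exactly: daily energy strictly
below 800 kcal, or strictly above 3,500 kcal (women) / 4,000 kcal (men), is
implausible and excluded first; rows with a missing outcome (BMI or waist
circumference) are excluded second.  Boundary values are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ENERGY_LOWER, ENERGY_UPPER, GROUPS

log = logging.getLogger(__name__)

ASIAN_GROUPS = ("EastAsian", "SouthAsian")


@dataclass
class ExclusionReport:
    n_input: int
    n_excluded_under: int
    n_excluded_over: int
    n_excluded_missing_outcome: int
    n_retained: int
    reasons: pd.Series = field(repr=False)  # per input row: retained/under/over/missing_outcome

    def __post_init__(self) -> None:
        total = (self.n_retained + self.n_excluded_under
                 + self.n_excluded_over + self.n_excluded_missing_outcome)
        if total != self.n_input:
            raise ValueError("exclusion counts do not conserve the input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_under": self.n_excluded_under,
            "n_excluded_over": self.n_excluded_over,
            "n_excluded_missing_outcome": self.n_excluded_missing_outcome,
            "n_excluded_implausible_energy": self.n_excluded_under + self.n_excluded_over,
            "n_retained": self.n_retained,
        }


@dataclass
class PhenotypeLabels:
    """Dichotomous adiposity labels for the retained sample."""

    bmi_high: pd.Series
    alt_bmi_high: pd.Series
    wc_high: pd.Series
    wc_thresholds: dict[str, float]

    def outcome(self, name: str) -> pd.Series:
        return {"bmi": self.bmi_high, "alt_bmi": self.alt_bmi_high,
                "wc": self.wc_high}[name]


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop dietary misreporters, then rows with missing BMI or WC.

    Reasons are mutually exclusive with precedence under > over > missing.
    """
    if cohort["sex"].isna().any():
        raise ValueError("sex is required for the sex-specific energy bounds")
    energy = cohort["energy_total"].to_numpy(dtype=float)
    upper = cohort["sex"].map(ENERGY_UPPER).to_numpy(dtype=float)
    under = energy < ENERGY_LOWER
    over = (~under) & (energy > upper)
    missing = (~under) & (~over) & (cohort["bmi"].isna() | cohort["wc"].isna()).to_numpy()
    reasons = pd.Series(
        np.select([under, over, missing], ["under", "over", "missing_outcome"],
                  default="retained"),
        index=cohort.index, name="exclusion_reason")
    retained = cohort.loc[reasons == "retained"].copy()
    report = ExclusionReport(
        n_input=len(cohort),
        n_excluded_under=int(under.sum()),
        n_excluded_over=int(over.sum()),
        n_excluded_missing_outcome=int(missing.sum()),
        n_retained=len(retained),
        reasons=reasons,
    )
    return retained, report


def dichotomize_bmi(cohort: pd.DataFrame, mode: str = "standard") -> pd.Series:
    """High-BMI label: BMI >= 25 for everyone (standard), or BMI >= 23 for
    East and South Asian participants under the alternative cut-off."""
    unknown = set(cohort["group"].unique()) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    if mode not in ("standard", "alternative"):
        raise ValueError(f"unknown mode {mode!r}")
    bmi = cohort["bmi"].to_numpy(dtype=float)
    cutoff = np.full(len(cohort), 25.0)
    if mode == "alternative":
        cutoff[cohort["group"].isin(ASIAN_GROUPS).to_numpy()] = 23.0
    return pd.Series((bmi >= cutoff).astype(int), index=cohort.index, name=f"{mode}_bmi_high")


def dichotomize_wc(cohort: pd.DataFrame) -> tuple[pd.Series, dict[str, float]]:
    """High-WC label: at or above the sex-specific 75th percentile (type-7
    linear-interpolation quantile) of the retained sample."""
    thresholds: dict[str, float] = {}
    high = np.zeros(len(cohort), dtype=int)
    wc = cohort["wc"].to_numpy(dtype=float)
    for sx in ("F", "M"):
        idx = np.flatnonzero((cohort["sex"] == sx).to_numpy())
        if len(idx) == 0:
            continue
        if len(idx) < 4:
            raise ValueError(f"sex stratum {sx} has fewer than 4 observations")
        thr = float(np.quantile(wc[idx], 0.75, method="linear"))
        thresholds[sx] = thr
        high[idx] = (wc[idx] >= thr).astype(int)
    return pd.Series(high, index=cohort.index, name="wc_high"), thresholds


def make_labels(cohort: pd.DataFrame) -> PhenotypeLabels:
    wc_high, thresholds = dichotomize_wc(cohort)
    return PhenotypeLabels(
        bmi_high=dichotomize_bmi(cohort, "standard"),
        alt_bmi_high=dichotomize_bmi(cohort, "alternative"),
        wc_high=wc_high,
        wc_thresholds=thresholds,
    )


def energy_adjust(cohort: pd.DataFrame, nutrient: str) -> pd.Series:
    """Willett residual energy adjustment: residual of the OLS regression of
    the nutrient (kcal/day) on total energy intake, over the pooled sample."""
    x = cohort["energy_total"].to_numpy(dtype=float)
    y = cohort[nutrient].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("energy_total has zero variance; cannot adjust")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=cohort.index, name=f"{nutrient}_resid")


def quartile_categorize(values: pd.Series, strata: pd.Series,
                        min_stratum: int = 4) -> pd.Series:
    """Map residuals to quartile categories 1-4 within each stratum.

    Boundaries are the type-7 25/50/75th percentiles; a value exactly on a
    boundary goes to the lower category.  Strata smaller than ``min_stratum``
    are flagged with a warning and left missing (dropped from G-E analysis);
    a degenerate stratum (all values tied) maps everyone to category 1.
    """
    out = pd.Series(np.nan, index=values.index, name=f"{values.name}_q")
    for name, idx in values.groupby(strata, observed=True).groups.items():
        v = values.loc[idx].to_numpy(dtype=float)
        if len(v) < min_stratum:
            warnings.warn(f"stratum {name} has {len(v)} < {min_stratum} observations; "
                          "dropped from quartile categorization")
            continue
        bounds = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
        if np.ptp(v) == 0:
            warnings.warn(f"stratum {name}: all residuals identical; single category")
        cat = 1 + (v[:, None] > bounds[None, :]).sum(axis=1)
        out.loc[idx] = cat
    return out


def exposure_quartiles(cohort: pd.DataFrame, nutrients=("carb", "fat", "protein", "alcohol"),
                       stratify_by=("group", "sex")) -> pd.DataFrame:
    """Energy-adjusted residuals and their stratified quartile categories.

    Returns a frame with ``<nutrient>_resid`` (continuous, for regression) and
    ``<nutrient>_q`` (1-4, for MDR) per nutrient.
    """
    strata = cohort[list(stratify_by)].astype(str).agg("|".join, axis=1)
    out = {}
    for nut in nutrients:
        resid = energy_adjust(cohort, nut)
        out[resid.name] = resid
        q = quartile_categorize(resid, strata)
        out[f"{nut}_q"] = q
    return pd.DataFrame(out, index=cohort.index)
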