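"""Pipeline orchestration and descriptive reporting.

``run_pipeline`` executes simulate/ingest -> exclusions -> dichotomization ->
energy adjustment -> SNP QC -> {logistic scan, MDR, PLR} for each outcome
(bmi, alt_bmi, wc) and stratum (pooled plus per-ethnocultural-group), writing
a descriptives table, scan TSVs, MDR model tables with text grids, PLR JSON,
and a run manifest that ties every output to the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as gio
from . import mdr, plr, preprocess, scan, snp_qc
from .config import NUTRIENTS, SimulationConfig, config_to_yaml
from .simulate import simulate_cohort

log = logging.getLogger(__name__)

OUTCOMES = ("bmi", "alt_bmi", "wc")
STRATA = ("pooled", "Caucasian", "EastAsian", "SouthAsian")


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    input_digests: dict[str, str]
    package_version: str
    stage_counts: dict[str, int]
    outputs: list[str]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt_count(k: int, n: int) -> str:
    return f"{k} ({100 * k / n:.1f})" if n else "0 (0.0)"


def _fmt_mean(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ({np.std(x, ddof=1):.1f})"


def describe_groups(cohort: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Descriptive table comparing the high and low outcome groups.

    Categorical rows show count (%) with a continuity-corrected chi-square
    p-value (2x2) or plain chi-square for the 4-level group variable;
    continuous rows show mean (SD) with a Welch t-test p-value.  Degenerate
    rows (constant variable) carry a note instead of a p-value.
    """
    hi = labels.astype(bool).to_numpy()
    a, b = cohort.loc[hi], cohort.loc[~hi]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty outcome group")
    rows = []

    def cat_row(name, mask_series):
        ka, kb = int(mask_series[hi].sum()), int(mask_series[~hi].sum())
        table = np.array([[ka, len(a) - ka], [kb, len(b) - kb]])
        if (table.sum(axis=0) == 0).any():
            p, note = np.nan, "degenerate"
        else:
            p = stats.chi2_contingency(table, correction=True)[1]
            note = ""
        rows.append({"variable": name, "high": _fmt_count(ka, len(a)),
                     "low": _fmt_count(kb, len(b)), "p_value": p, "note": note})

    def cont_row(name, col):
        xa, xb = a[col].dropna().to_numpy(), b[col].dropna().to_numpy()
        if np.ptp(np.concatenate([xa, xb])) == 0:
            rows.append({"variable": name, "high": _fmt_mean(xa), "low": _fmt_mean(xb),
                         "p_value": np.nan, "note": "constant; t-test skipped"})
            return
        p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
        rows.append({"variable": name, "high": _fmt_mean(xa), "low": _fmt_mean(xb),
                     "p_value": p, "note": ""})

    cat_row("Female", cohort["sex"] == "F")
    cont_row("Age (years)", "age")
    cat_row("Smoking", cohort["smoking"] == "yes")
    counts = cohort["group"].groupby(labels.astype(bool)).value_counts().unstack(fill_value=0)
    table = counts.reindex([True, False]).to_numpy()
    p_group = stats.chi2_contingency(table)[1] if (table.sum(axis=0) > 0).all() else np.nan
    rows.append({"variable": "Ethnocultural group", "high": "", "low": "",
                 "p_value": p_group, "note": ""})
    for g in ("Caucasian", "EastAsian", "SouthAsian", "Other"):
        ka = int(((cohort["group"] == g) & hi).sum())
        kb = int(((cohort["group"] == g) & ~hi).sum())
        rows.append({"variable": f"  {g}", "high": _fmt_count(ka, len(a)),
                     "low": _fmt_count(kb, len(b)), "p_value": np.nan, "note": ""})
    cont_row("METS", "mets")
    cont_row("Total calories (kcal/day)", "energy_total")
    cont_row("Carbohydrates (kcal/day)", "carb")
    cont_row("Fats (kcal/day)", "fat")
    cont_row("Proteins (kcal/day)", "protein")
    cont_row("Alcohol (kcal/day)", "alcohol")
    out = pd.DataFrame(rows)
    out.attrs["tests"] = ("chi-square with continuity correction (2x2) / "
                          "chi-square (R x 2); Welch two-sample t")
    return out


def run_pipeline(config: SimulationConfig, out_dir: str | Path,
                 mdr_orders=(2, 3), min_stratum_n: int = 100,
                 do_scan: bool = True, do_mdr: bool = True, do_plr: bool = True,
                 strata=STRATA) -> RunManifest:
    """End-to-end pipeline on a simulated cohort; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage_counts: dict[str, int] = {}

    cohort, geno = simulate_cohort(config)
    cohort_path, geno_path = out / "cohort.tsv", out / "genotypes.tsv"
    gio.write_cohort_tsv(cohort, cohort_path)
    gio.write_genotypes_tsv(geno, geno_path)
    outputs += [str(cohort_path), str(geno_path)]
    stage_counts["n_recruited"] = len(cohort)

    retained, report = preprocess.apply_exclusions(cohort)
    (out / "exclusions.json").write_text(json.dumps(report.to_dict(), indent=2))
    outputs.append(str(out / "exclusions.json"))
    stage_counts.update(report.to_dict())

    labels = preprocess.make_labels(retained)
    log.info("WC thresholds (cm): %s", labels.wc_thresholds)
    exposures = preprocess.exposure_quartiles(retained)
    geno_r = geno.loc[retained["participant_id"]].set_axis(retained.index)

    info = pd.DataFrame({"rsid": [s.rsid for s in config.snps],
                         "gene": [s.gene for s in config.snps]})
    qc = snp_qc.qc_pipeline(geno_r, info)
    qc.to_csv(out / "snp_qc.tsv", sep="\t", index=False)
    outputs.append(str(out / "snp_qc.tsv"))
    passed = qc.loc[qc.qc_status == "pass", "rsid"].tolist()
    stage_counts["n_snps_input"] = len(qc)
    stage_counts["n_snps_pass"] = len(passed)
    snp_genes = dict(zip(qc["rsid"], qc["gene"]))
    geno_pass = geno_r[passed]

    for name in OUTCOMES:
        desc = describe_groups(retained, labels.outcome(name))
        desc.to_csv(out / f"descriptives_{name}.tsv", sep="\t", index=False)
        outputs.append(str(out / f"descriptives_{name}.tsv"))

    resid_cols = [f"{n}_resid" for n in NUTRIENTS]
    quart_cols = [f"{n}_q" for n in NUTRIENTS]
    mdr_rows, plr_models = [], {}
    for stratum in strata:
        mask = (pd.Series(True, index=retained.index) if stratum == "pooled"
                else retained["group"] == stratum)
        n_s = int(mask.sum())
        if n_s < min_stratum_n:
            log.warning("stratum %s has n=%d < %d; skipped", stratum, n_s, min_stratum_n)
            continue
        sub = retained.loc[mask]
        sub_geno = geno_pass.loc[mask]
        # stratified runs recompute exposure quartiles within stratum
        sub_expo = preprocess.exposure_quartiles(sub) if stratum != "pooled" else exposures.loc[mask]
        for name in OUTCOMES:
            y = labels.outcome(name).loc[mask]
            tag = f"{name}_{stratum}"
            if do_scan:
                gg = scan.scan_gxg(y, sub_geno, sub, snp_genes, outcome=name)
                ge = scan.scan_gxe(y, sub_geno, sub_expo[resid_cols], sub, outcome=name)
                gg.to_csv(out / f"scan_gxg_{tag}.tsv", sep="\t", index=False)
                ge.to_csv(out / f"scan_gxe_{tag}.tsv", sep="\t", index=False)
                outputs += [str(out / f"scan_gxg_{tag}.tsv"), str(out / f"scan_gxe_{tag}.tsv")]
            if do_mdr:
                factors = pd.concat([sub_geno, sub_expo[quart_cols]], axis=1)
                res = mdr.search(factors, y, pool=passed, orders=mdr_orders,
                                 seed=config.seed)
                res_ge = mdr.search(factors, y, pool=passed + quart_cols,
                                    orders=mdr_orders, seed=config.seed,
                                    must_include_any=quart_cols)
                for kind, models in (("gxg", res), ("gxe", res_ge)):
                    for order, m in models.items():
                        mdr_rows.append({
                            "population": stratum, "outcome": name, "kind": kind,
                            "model": ", ".join(m.factors),
                            "avg_testing_accuracy": round(m.avg_test_accuracy, 4),
                            "cv_consistency": f"{m.cv_consistency}/{m.n_folds}",
                            "valid": m.valid,
                        })
                        grid_path = out / f"mdr_grid_{kind}_{tag}_order{order}.txt"
                        grid_path.write_text(mdr.render_grid(m) + "\n")
                        outputs.append(str(grid_path))
            if do_plr:
                factors = pd.concat([sub_geno, sub_expo[quart_cols]], axis=1)
                model = plr.forward_stepwise(
                    y.to_numpy(), factors, candidates=passed,
                    covariates=scan.covariate_design(sub, ("age", "sex")))
                plr_models[tag] = model.to_dict()
    if mdr_rows:
        pd.DataFrame(mdr_rows).to_csv(out / "mdr_models.tsv", sep="\t", index=False)
        outputs.append(str(out / "mdr_models.tsv"))
    if plr_models:
        (out / "plr_models.json").write_text(json.dumps(plr_models, indent=2, sort_keys=True))
        outputs.append(str(out / "plr_models.json"))

    try:
        from importlib.metadata import version
        pkg_version = version("gxepi")
    except Exception:
        pkg_version = "unknown"
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_to_yaml(config).encode()).hexdigest(),
        seed=config.seed,
        input_digests={p.name: _sha256(p) for p in (cohort_path, geno_path)},
        package_version=pkg_version,
        stage_counts=stage_counts,
        outputs=sorted(outputs),
    )
    manifest.write(out / "manifest.json")
    return manifest
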