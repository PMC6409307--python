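# Methods

`gxepi` implements the analysis pipeline of a candidate-gene obesity study:
dichotomized adiposity outcomes (high BMI, high waist circumference) are
related to tag SNPs in three inflammation-pathway genes (*NFKB1*, *IKBKB*,
*SOCS3*) and to energy-adjusted macronutrient and alcohol intakes, through
three complementary methods — an adjusted logistic interaction scan with
false-discovery-rate control, multifactor dimensionality reduction (MDR), and
forward-stepwise L2-penalized logistic regression (PLR). Because the real
cohort is private, the package ships a synthetic-cohort generator that
reproduces the study's data structure and lets every stage be exercised with
planted, known signals.

## Synthetic cohort generator

The generator emulates a multiethnic young-adult cohort of 1,639 recruits in
four ethnocultural groups (Caucasian 733, East Asian 509, South Asian 160,
other 110 at the retained-sample proportions), ~68% women, ages 20–29.

**Intakes.** Total energy is log-normal (arithmetic mean 1,970 kcal/day,
SD 650), truncated per sex to the plausible range [800, 3,500/4,000] so that
exclusion counts are controlled exactly by the misreporter mechanism below.
Carbohydrate, fat, protein and alcohol (kcal/day) are noisy energy shares
(defaults ≈ 52/30/17/2% of energy, log-normal share noise with SD 0.25)
renormalized to sum exactly to total energy. This induces the positive
nutrient–energy correlation that makes Willett residual adjustment
non-trivial. The share defaults convert typical young-adult FFQ gram intakes
(≈260 g carbohydrate, 66 g fat, 85 g protein, 5 g alcohol) to kilocalories by
Atwater factors; note that a gram-scale table of such intakes cannot sum to
total energy, which is why the generator works on the kcal share scale.

**Misreporters and missingness.** A configurable number of rows is
overwritten post hoc with implausible energies — defaults 40 F + 20 M
under-reporters (<800 kcal/day) and 40 F + 24 M over-reporters (>3,500 F /
>4,000 M), 124 in total, plus 3 rows with both outcomes deleted. The split by
direction and sex is a package choice (only the total of 124 is a published
quantity). Nutrient components are rescaled with the overwritten energy so
row-level consistency is preserved, and a provenance `flag` column records
every manipulation.

**Genotypes.** Each non-duplicate SNP is drawn under Hardy–Weinberg
equilibrium at its configured MAF, per ethnocultural group (group-specific
MAFs are the population-structure knob; the default is a shared MAF).
High-LD duplicate SNPs copy their partner's genotypes and re-draw each entry
with probability 1 − √r²_target, which gives E[r²] equal to the target. The
default 54-SNP panel mirrors the study's filter outcomes: 24 common SNPs
(8 *SOCS3* + 9 *NFKB1* + 3 *IKBKB* QC survivors), 30 SNPs below 5% MAF
(17/8/5 per gene) and 4 high-LD copies (2/1/1) — the unique per-gene
allocation consistent with initial counts 27/18/9 and final counts 8/9/3.
Known rsids from the study's final panel are used where available; the
remainder are synthetic placeholders.

**Outcomes.** Each outcome has a logistic liability:
logit P = β₀(group) + Σ log(OR_main)·code + Σ log(OR_int)·code₁·code₂, with
SNPs coded additively (0/1/2) and nutrients as mean-centred kcal/day.
Defaults plant no genetic effects; the BMI baseline is group-specific
(prevalences ≈ 25/12/29/34%), the WC baseline gives 25% prevalence (the
top-quartile definition). A 3×3 penetrance table for one SNP pair overrides
the liability entirely — `plant_xor_penetrance(high, low)` builds the
canonical checkerboard model with no marginal effects at MAF 0.5. Continuous
BMI and WC are then drawn *conditional* on the binary liability (controls
from a truncated normal below the cut-off, cases from cut-off + Gamma), so
that downstream dichotomization recovers the planted label exactly for BMI
(cut-off 25) and up to empirical-quantile noise for WC.

What the generator does **not** emulate: FFQ item-level measurement error,
haplotype/coalescent LD structure, BMI–WC correlation beyond their separate
liabilities, and age/secular trends. Passing tests therefore demonstrate
algorithmic correctness and statistical behavior under the stated model, not
robustness to real FFQ error or fine-scale population stratification.

## Preprocessing

Exclusions follow the printed rules with strict inequalities: energy
< 800 kcal/day, or > 3,500 (women) / > 4,000 (men); boundary values are
retained. Energy implausibility takes precedence over missing-outcome
exclusion (matching the published ordering 124 then 3). High BMI is
BMI ≥ 25 kg/m²; the alternative definition uses ≥ 23 for East and South
Asian participants. High WC is at or above the sex-specific 75th percentile
of the retained sample, computed with the type-7 (linear interpolation)
quantile — the original report does not state its quantile rule, so this
common default is declared here and in output metadata. Nutrient residuals
come from OLS of nutrient on total energy over the pooled retained sample
(only the quartile step is stratified, by group × sex); residual quartiles
assign boundary ties to the lower category, and strata with fewer than 4
observations are dropped from quartile-based analyses with a warning.
Quartiles are computed after exclusions; whether the original study computed
them before is unstated.

## SNP quality control

The cascade is HWE (exclude chi-square p ≤ 0.01; Levene/Haldane exact test
available as an option), then MAF < 5%, then greedy LD pruning among
survivors: repeatedly take the highest-r² pair above 0.8 and drop its
lower-MAF member, ties broken by keeping the lexicographically smaller rsid
(the original report does not say which SNP of a correlated pair was
dropped). r² is genotypic (squared Pearson correlation of allele counts over
pairwise-complete rows) because phase is unavailable from a genotype matrix.
Monomorphic SNPs get HWE p = 1 by convention. The cascade is idempotent.

## Logistic interaction scan

One model per pair: intercept + covariates + main₁ + main₂ + product, fitted
by IRLS (deviance tolerance 1e-8, at most 100 iterations, observed-information
covariance), Wald-testing the product term. Gene–gene models adjust for age,
sex, and ethnocultural group (indicator coding, Caucasian reference) and by
default test cross-gene pairs only (pathway epistasis is the question; a flag
scans all pairs). Gene–environment models use the continuous energy-adjusted
residuals — quartiles are reserved for MDR — and adjust for age, physical
activity (MET-h/week), group, and sex. Separated or non-converged models are
flagged, their p-values set missing, and they are excluded from the
Benjamini–Hochberg family, which is formed per outcome × scan type.

## MDR engine

For a candidate factor set, training cells with case/control ratio strictly
greater than 1 are high-risk; ratio ties, empty cells, and cells unseen in
training are low-risk (subjects in unseen cells are classified, not dropped,
keeping denominators stable; both policies are configurable, as is the ratio
threshold — the plain ratio 1 is the default rather than a
prevalence-adjusted threshold). Accuracy is plain 1 − misclassification;
balanced accuracy is available for unbalanced outcomes. Folds are stratified
by case status from a seeded RNG (the fold-construction rule is a package
choice). Cross-validation consistency of a set is the number of folds (of 10)
in which it is the training-best set of its order; the reported best set per
order maximizes CVC, then average testing accuracy, then lexicographic factor
ids. A model is *valid* when average testing accuracy ≥ 55% and CVC ≥ 7/10;
the CVC bar is configurable because the source description wavers between
">6/10" and "≥6/10" (all of its reported models satisfy both readings).
The engine is vectorized (per-set cell×fold contingency tensors via
bincount); tests pin it cell-for-cell and fold-for-fold to an independent
brute-force implementation. Measured on synthetic nulls (20 SNPs, n = 1,000,
balanced outcome), the 55%/7-of-10 validity rule fires in a minority of
pure-noise replicates but not rarely (~10–20%) — a known leniency of MDR
validity criteria without permutation testing, which is why permutation
p-values are offered as an optional extension (off by default, as none were
reported by the study design this mirrors).

## PLR engine

Ridge-logistic fits maximize ℓ(β) − (λ/2)‖β_pen‖² by IRLS with the ridge
added to the normal equations; intercept and covariates are unpenalized.
Effective degrees of freedom are trace[(XᵀWX + Λ)⁻¹XᵀWX], so the selection
score C = deviance + cp·df reduces to AIC at λ = 0 and cp = 2. λ defaults to
1e-4 — small enough that the unpenalized limit is near, large enough to keep
sparse factor cells estimable (λ is not stated by the method's published
description; cross-validated choice is out of scope). SNPs and exposure
quartiles enter as dummy blocks (reference: homozygous common / quartile 1);
an interaction term is the product block of its parents, and a whole block is
added and scored jointly. Forward selection starts from the covariates-only
model, admits interactions only when a parent main is already selected
(hierarchy on by default), accepts the largest C decrease, and stops when no
addition decreases C; there are no backward steps.

**Null behavior and the complexity parameter.** With cp = 2 the acceptance
rule is AIC-strength: under the null each 2-df dummy block is accepted with
probability P(χ²₂ > 4) = e⁻² ≈ 0.135, so with 10 candidates at least one
spurious term enters in ≈ 76% of replicates — confirmed empirically by the
engine. A procedure that "mostly selects the null model" on noise therefore
requires a stronger penalty; with cp = log n (BIC strength, the default of
the standard software implementation of this method) the covariates-only
model is selected in ≈ 95% of null replicates. The package keeps cp = 2 as
the documented default of the score formula and exposes cp everywhere; the
null-calibration checks report both regimes. Approximate Wald p-values from
the ridge sandwich are emitted with an explicit caveat: shrinkage biases
them, and they are descriptive only.

## Reporting

`run_pipeline` chains simulate → exclusions → labels → residuals/quartiles →
SNP QC → scan/MDR/PLR per outcome (bmi, alt_bmi, wc) × stratum (pooled and
per group), recomputing WC and exposure quartiles within stratum, skipping
strata below a configurable minimum n (default 100 — the small South Asian
subsample caveat). Descriptive tables show count (%) and mean (SD) with
continuity-corrected chi-square (2×2), plain chi-square (group), and Welch
t-tests — the test choices are declared in the table metadata since the
original tables do not name theirs. All randomness flows from the single
config seed through spawned child generators; a manifest records the config
hash, seed, input digests and per-stage counts, and identical configs produce
byte-identical outputs.

## Problem sizes in the shipped checks

The automated checks run at deliberately modest sizes chosen to exercise the
statistical behavior they verify: oracle-equivalence batteries at n ≤ 30
(100 datasets), XOR recovery at n = 1,600 with 10 noise SNPs over 20 seeds,
MDR null calibration with 20 SNPs × n = 1,000 over 100 replicates, PLR null
calibration at n = 500 over 20–30 replicates, and parameter recovery at
n = 5,000. These sizes give Monte Carlo error small relative to each
assertion's margin.

## Known limitations

Real-data mode expects pre-computed minor-allele counts; allele folding is
handled, but strand flips are not detectable from counts alone. The MDR
search is exhaustive and single-threaded; order-4+ searches over large panels
are out of scope. PLR p-values are approximate (above). The generator's
liability model is additive on the log-odds scale except where a penetrance
table is planted; threshold-dependence of dichotomized outcomes on covariates
(e.g. sex-specific WC cut-offs interacting with genotype) is not modelled.
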