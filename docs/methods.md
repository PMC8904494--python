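# Methods

This note documents the statistical model behind `exposcan`, the choices
made where the procedure was genuinely open, what the synthetic cohort
does and does not emulate, and the package's numerical conventions.

## Cohort model and harmonization

The pipeline assumes a long-format cohort: one row per participant-visit
with nine cardiometabolic traits, core covariates (age, sex, education,
fasting status, FFQ version, total energy intake), medication and
exclusion flags, and one column per lifestyle exposure. Harmonization
applies, in order:

1. **Participant exclusions** on boolean flags (diagnosed diabetes,
   cardiovascular disease, non-reference origin). The rule is
   participant-level: a flag at any visit removes all of that
   participant's visits, since diagnosis is a property of the person.
2. **Instrument-era conversion** (optional): user-supplied per-trait
   linear maps aligning measurements taken on different instruments.
3. **Medication correction**: published additive constants for
   participants on lipid-lowering (+0.208 mmol/L triglycerides, +1.347
   total cholesterol, −0.060 HDL, +1.290 LDL) or blood-pressure-lowering
   medication (+15 mmHg SBP, +10 mmHg DBP). The correction precedes
   outlier filtering so that an uncorrected-but-plausible value is
   judged on its corrected scale.
4. **Derived traits**: BMI = weight(kg)/height(m)²; LDL by the
   Friedewald formula LDL = TC − HDL − TG/2.2 (mmol/L; only filled in
   where missing unless a recompute flag is set); food intake level
   FIL = TEI/BMR. BMR defaults to the Schofield sex/age/weight
   equations (kcal/day) but a user `bmr` column takes precedence.
5. **Plausibility filtering**: trait values outside configurable
   (low, high) ranges become missing. The default ranges are artifact
   choices spanning physiologically defensible extremes, not a
   published table.
6. **Dietary-quality filtering**: visits with FFQ missingness above 10%,
   any missing portion indication, or FIL in the bottom 5% / top 2.5%
   of the input table's FIL distribution have all dietary variables and
   TEI set missing. "Any portion indication missing" is interpreted as
   *any* of the portion items; the cut-offs are computed on the table
   being harmonized rather than on an external reference.
7. **Dominance filtering**: categorical exposures whose modal level
   holds ≥ 90% (inclusive boundary) of non-missing observations are
   dropped — their contrasts are near-degenerate and their tests
   uninformative.
8. **Inverse-normal transformation** of numeric and ordinal exposures:
   ranks with the Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks
   for ties. The offset is configurable; Blom is the default because it
   is the most common convention in epidemiology. The normal-quantile
   map already yields approximately unit variance, so no second
   standardization pass is applied. Ordinal exposures pass their
   integer codes through the same transform (they are treated as
   continuous). Categorical exposures keep their level codes and are
   expanded per model into k−1 indicators against the lowest observed
   level.

Every rule appends to an exclusion log (rule, unit, count) whose
participant-level counts reconcile exactly with the rows removed.
Missing data are never imputed; every model is complete-case.

## Average associations (random-intercept mixed model)

For each exposure × trait, `y_ij = x_ij'β + u_j + ε_ij` with participant
random intercepts. Estimation is REML with the fixed effects and the
residual variance profiled out, leaving a one-dimensional search over
θ = log(σ²_u/σ²_e) on [−15, 15] (Brent's bounded method, tolerance
1e-8). Each objective evaluation uses the rank-one Woodbury identity
per participant, so a fit costs O(groups × p²) per evaluation and the
full screen scales linearly in exposures × traits. At the solution the
fixed effects are exactly the GLS estimates at the estimated variance
ratio; if the boundary (σ²_u = 0) has a lower restricted deviance than
the interior optimum — or every participant has one visit, making the
ratio unidentifiable — the fit reduces to OLS.

Inference on the exposure term is a two-sided Wald z-test with a normal
reference. No small-sample t correction is applied: at the cohort sizes
this design targets (10³–10⁴ participants) the difference is
negligible. For small synthetic runs the test is mildly liberal; this
is a documented limitation, and the Wald coverage of planted slopes is
verified by simulation at n = 2000.

Covariates follow the model statement in the README: age and age²
(age centered at the sample mean before squaring, to tame the
collinearity between the linear and quadratic terms without changing
the exposure slope), sex, education (ordered integer codes), follow-up
time defined as years since the participant's first visit, plus the
conditional terms (FFQ version and TEI for dietary exposures, BMI
except for the BMI outcome, fasting status for glycaemic and lipid
outcomes). Dietary exposures enter as their energy residuals — the
residual of the exposure regressed on TEI — with TEI itself retained in
the model, the standard energy-residual method.

**Variance explained.** The marginal (fixed-terms) R² is
var(Xβ̂)/(var(Xβ̂) + σ̂²_u + σ̂²_e). A term's variance explained is the
drop in marginal R² when that term's fitted contribution is removed
from Xβ̂ (recomputed variance, floored at 0). The per-variable variance
explained of a screen has no unique definition; this one was chosen
because it is cheap (no refit), respects the fitted model, and reduces
to b²/total for a standardized predictor orthogonal to the covariates.
For a categorical exposure the screen reports each dummy separately and
the ranking stage collapses siblings to the parent variable keeping the
maximum.

## Ten-year change associations

At most one visit pair per participant: the baseline is the first
visit, the follow-up the later visit minimizing |gap − 10 y| within
±2 y (the design's visit spacing implies ~10-year gaps; the tolerance
is a package default, exposed as config). The follow-up trait value is
regressed by OLS (QR decomposition via `numpy.linalg.lstsq`) on the
baseline trait value, baseline age and age² (centered), sex, follow-up
time, meanBMI = (BMI_B + BMI_F)/2 (omitted when the trait is BMI;
missing when either BMI is), fasting status at both visits, baseline
FFQ version and TEI for dietary exposures, and the baseline exposure.
Education is *not* in this covariate set — the change model is
deliberately specified without it, unlike the average model, and the
asymmetry is intentional rather than harmonized away. The exposure
p-value uses the t reference with residual degrees of freedom; the
change-mode variance explained is the exposure's semi-partial R² (R²
drop on removing the exposure column).

## Discovery

- **Tentative signals**: Benjamini–Hochberg step-up adjustment,
  adjusted_(i) = min_{j≥i} m·p_(j)/j capped at 1, one family per
  trait × mode (average and change analyses are corrected separately,
  because signal counts are reported per trait for each analysis);
  flagging uses the strict inequality adjusted p < α, α = 0.05.
- **Ranking**: tentative signals sorted within trait × category by
  variance explained (descending), ties broken by smaller raw p then
  lexicographic name; dummies collapsed to parents first; top 5 kept
  per category per trait.
- **Prioritization**: a variable qualifies when it appears in the top
  sets of ≥ 5 distinct traits ("majority of nine"), i.e. membership in
  the per-category top five of a trait counts, not only rank 1.
  Non-modifiable qualifiers are excluded but reported with their
  reason. Thresholds (top_k, min_traits) are config.
- **Clustering**: agglomerative, average linkage on distance 1 − r
  using signed correlations (positively and negatively associated
  variables may share a target group; clustering on |r| would hide the
  sign structure). Correlations are pairwise-complete Pearson on the
  harmonized values; pairs with < 3 complete observations or zero
  variance are masked and imputed at the mean unmasked distance before
  linkage. The number of target groups is a user parameter — a cut of
  the dendrogram, not an algorithmic output. Linkage and distance are
  config so alternatives can be swapped in.

## Synthetic cohort generator

The generator emulates the design the screens assume: participants aged
30–70 with 1–3 visits at the decade birthdays (ages {30,40,50,60} ± 1 y
jitter, ~10-year spacing), nine traits following the random-intercept
model with per-trait intercept and residual SDs loosely calibrated to a
middle-aged European cohort, deterministic age/sex covariate effects,
medication flags that *lower* observed lipid/BP values by the published
constants (so the correction step restores the generating value),
participant-level exclusion flags, MCAR missingness, and exposures in
the ten categories as equicorrelated latent normals (within-category
correlation ρ via a shared factor). Categorical exposures are built by
thresholding the latent normals — this preserves the block-correlation
structure across types — with a configurable fraction of dominated
categoricals (modal level ≥ 92%). Planted effects are standardized:
slope b moves the trait by b total trait SDs per exposure SD, so the
same number is equally detectable on every trait. Exposures carrying
planted effects are kept numeric so the planted slope is expressible on
the observed scale.

Features of real cohort data the generator does **not** emulate, and
which passing tests therefore say nothing about: within-person exposure
drift over visits (exposure latents are constant per participant),
informative missingness, measurement error in the FFQ, secular
instrument changes, skewed exposure distributions beyond what
thresholding induces, and confounding of exposures by unmodelled common
causes. The p-value panel generator is a separate, minimal fixture for
FDR calibration: null entries are two-sided normal tails (uniform by
construction), non-null entries shift the z mean; the non-null count is
round(frac·m) with ties to nearest even.

## Numerical conventions and degenerate inputs

- REML search tolerance 1e-8 on the log-ratio scale; boundary σ²_u = 0
  taken whenever its restricted deviance is no worse than the interior
  optimum.
- Rank-deficient designs raise immediately (Cholesky failure / rank
  check) rather than silently dropping columns; inside a screen the
  failure is recorded in the result row's status and the screen
  continues.
- Exposures constant on the complete cases of a model, or with a single
  observed level, are reported with a degenerate status.
- The inverse-normal transform refuses constant or all-missing vectors
  (no rank information).
- Screens require a minimum model size (default 30 complete rows plus
  the design width) before fitting.
- All randomness flows through `numpy.random.default_rng` seeded from
  the run seed; equal seeds give byte-identical tables and result CSVs.

## Problem sizes used in the validation suite

The test and calibration runs use deliberately modest sizes chosen to
make Monte-Carlo tolerances meaningful while keeping the suite quick:
FDR calibration on 1000 panels of 286 tests; REML/ANOVA equivalence on
200 random balanced layouts; Wald coverage over 500 replicates of 2000
participants × 2 visits; end-to-end prioritization recovery over 50
replicates of a 2000-participant cohort with 40 exposures (4 per
category) and one exposure planted on 6 of 9 traits at standardized
slope 0.25. These are the package's validation conditions, reported by
the tests themselves.

## Known limitations

- Only random intercepts: no random slopes, crossed effects, or
  non-Gaussian outcomes.
- Wald/normal inference is liberal in very small samples.
- The per-variable variance-explained definition is one of several
  defensible choices; rankings can differ under alternatives (the
  function is exposed so alternatives can be plugged in).
- One visit pair per participant in the change analysis; multi-interval
  trajectories are out of scope.
- The exposure catalog's modifiability flags are user (or generator)
  supplied; the pipeline does not infer modifiability.
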