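"""Synthetic longitudinal cohort generator with planted exposure effects.

The real study population (a Swedish health-survey cohort with clinical
examinations around the 30th, 40th, 50th and 60th birthdays) is not
public, so the screening pipeline is exercised on synthetic cohorts that
reproduce its statistical structure: 1-3 visits roughly ten years apart,
nine correlated cardiometabolic traits driven by participant-level random
intercepts, and a few hundred lifestyle exposures in ten categories with
within-category block correlation.  Ground-truth effect labels are
returned alongside the tables so that recovery of planted signals can be
measured exactly.

Trait values follow the random-intercept model the average screen
assumes::

    y_ij = mu_t + a1*(age_ij - 45) + a2*(age_ij - 45)^2 + s*sex_j
           + sum_k b_kt * x_kj + u_j + e_ij

with ``u_j ~ N(0, sd_u^2)`` per participant and ``e_ij ~ N(0, sd_e^2)``
per visit.  Planted slopes are *standardized*: a slope of ``b`` moves the
trait by ``b`` total trait standard deviations (``sqrt(sd_u^2 + sd_e^2)``)
per standard deviation of the exposure latent, so the same number means
the same detectability on every trait regardless of its units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema
from .schema import CATEGORIES, TRAITS


class ConfigError(ValueError):
    """A generator configuration field failed validation."""


# Per-trait (mean, age slope, quadratic age slope, female offset) of the
# deterministic covariate part, on each trait's natural scale.  Means and
# dispersions are loosely calibrated to a middle-aged European cohort.
_TRAIT_COVARIATE_MODEL: dict[str, tuple[float, float, float, float]] = {
    "bmi": (25.7, 0.08, -0.001, -0.4),
    "sbp": (126.0, 0.55, 0.008, -4.0),
    "dbp": (79.0, 0.25, -0.004, -2.5),
    "fasting_glucose": (5.4, 0.015, 0.0004, -0.12),
    "glucose_2h": (6.6, 0.035, 0.001, 0.1),
    "total_cholesterol": (5.5, 0.03, -0.0008, -0.1),
    "triglycerides": (1.4, 0.012, -0.0003, -0.25),
    "hdl": (1.4, 0.002, 0.0001, 0.25),
    "ldl": (3.9, 0.025, -0.0006, -0.15),
}

_DEFAULT_INTERCEPT_SD = {
    "bmi": 3.2,
    "sbp": 11.0,
    "dbp": 7.5,
    "fasting_glucose": 0.5,
    "glucose_2h": 1.1,
    "total_cholesterol": 0.85,
    "triglycerides": 0.6,
    "hdl": 0.38,
    "ldl": 0.8,
}

_DEFAULT_RESIDUAL_SD = {
    "bmi": 1.5,
    "sbp": 9.0,
    "dbp": 6.0,
    "fasting_glucose": 0.45,
    "glucose_2h": 0.9,
    "total_cholesterol": 0.6,
    "triglycerides": 0.45,
    "hdl": 0.2,
    "ldl": 0.55,
}

#: Additive constants used to *lower* observed values of medicated
#: participants, so that the harmonization step's correction restores the
#: underlying model value.  Same constants as the correction defaults.
_MEDICATION_SHIFT = {
    "triglycerides": 0.208,
    "total_cholesterol": 1.347,
    "hdl": -0.060,
    "ldl": 1.290,
    "sbp": 15.0,
    "dbp": 10.0,
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the source study's design: visits at the decade
    birthdays between 30 and 60, ten-year spacing, ten exposure
    categories with moderate within-category correlation, and a small
    fraction of heavily imbalanced categoricals.
    """

    n_participants: int = 1000
    #: Probability of a participant contributing 1, 2 or 3 visits.
    visit_count_probs: tuple[float, float, float] = (0.35, 0.45, 0.20)
    #: Mean and uniform jitter half-width (years) of the inter-visit gap.
    visit_spacing_years: tuple[float, float] = (10.0, 1.0)
    #: Exposures generated per category.
    n_exposures_per_category: Mapping[str, int] = field(
        default_factory=lambda: {c: 29 if c == "nutrient" else 28 for c in CATEGORIES}
    )
    #: Within-category correlation of exposure latents, in [0, 1).
    exposure_block_correlation: float = 0.3
    #: Fraction of exposures generated as categorical (2-4 levels).
    categorical_fraction: float = 45 / 286
    #: Fraction of categoricals built with a modal level >= 90%.
    dominance_fraction: float = 0.15
    #: Planted (exposure, trait, standardized slope) triples.
    planted_effects: Sequence[tuple[str, str, float]] = ()
    random_intercept_sd_per_trait: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INTERCEPT_SD)
    )
    residual_sd_per_trait: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RESIDUAL_SD)
    )
    #: (lipid-medication, BP-medication) flag prevalences.
    medication_prevalence: tuple[float, float] = (0.05, 0.08)
    #: Per-cell missingness probability on exposures and traits.
    missing_rate: float = 0.02
    #: Participant-level prevalences of the boolean exclusion flags.
    exclusion_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"diabetes": 0.03, "cvd": 0.02, "non_reference_origin": 0.05}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        probs = np.asarray(self.visit_count_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or (probs > 1).any():
            raise ConfigError("visit_count_probs must be 3 probabilities in [0, 1]")
        if not np.isclose(probs.sum(), 1.0):
            raise ConfigError("visit_count_probs must sum to 1")
        if not 0 <= self.exposure_block_correlation < 1:
            raise ConfigError("exposure_block_correlation must lie in [0, 1)")
        for name in ("categorical_fraction", "dominance_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name, cnt in self.n_exposures_per_category.items():
            if name not in CATEGORIES:
                raise ConfigError(f"unknown exposure category {name!r}")
            if cnt < 0:
                raise ConfigError(f"n_exposures_per_category[{name!r}] must be >= 0")
        for mapping, label in (
            (self.random_intercept_sd_per_trait, "random_intercept_sd_per_trait"),
            (self.residual_sd_per_trait, "residual_sd_per_trait"),
        ):
            for trait, sd in mapping.items():
                if trait not in TRAITS:
                    raise ConfigError(f"{label}: unknown trait {trait!r}")
                if sd < 0:
                    raise ConfigError(f"{label}[{trait!r}] must be >= 0")
        for p in self.medication_prevalence:
            if not 0 <= p <= 1:
                raise ConfigError("medication_prevalence entries must lie in [0, 1]")
        exposures = set(_exposure_names(self.n_exposures_per_category))
        for exp, trait, _slope in self.planted_effects:
            if exp not in exposures:
                raise ConfigError(f"planted_effects: exposure {exp!r} not in generated schema")
            if trait not in TRAITS:
                raise ConfigError(f"planted_effects: unknown trait {trait!r}")


@dataclass
class TrueEffects:
    """Ground-truth planted effects of a generated cohort.

    ``effect_matrix`` holds the standardized slope of every exposure on
    every trait (zero for unplanted pairs); ``null_set`` lists exposures
    with an all-zero row, and ``cross_trait_set`` the exposures with
    nonzero effects on at least five traits.
    """

    effect_matrix: pd.DataFrame
    null_set: tuple[str, ...]
    cross_trait_set: tuple[str, ...]

    @classmethod
    def from_matrix(cls, effect_matrix: pd.DataFrame, min_traits: int = 5) -> "TrueEffects":
        nonzero = (effect_matrix != 0).sum(axis=1)
        null_set = tuple(effect_matrix.index[nonzero == 0])
        cross = tuple(effect_matrix.index[nonzero >= min_traits])
        return cls(effect_matrix=effect_matrix, null_set=null_set, cross_trait_set=cross)

    def to_json_dict(self) -> dict:
        return {
            "effect_matrix": {
                exp: {t: float(v) for t, v in row.items() if v != 0}
                for exp, row in self.effect_matrix.iterrows()
            },
            "null_set": list(self.null_set),
            "cross_trait_set": list(self.cross_trait_set),
        }


def trait_total_sd(config: GeneratorConfig, trait: str) -> float:
    """Total (between + within) SD of a trait under the generating model."""
    su = config.random_intercept_sd_per_trait.get(trait, 0.0)
    se = config.residual_sd_per_trait.get(trait, 0.0)
    return float(np.hypot(su, se))


def _exposure_names(counts: Mapping[str, int]) -> list[str]:
    names: list[str] = []
    for cat in CATEGORIES:
        for i in range(counts.get(cat, 0)):
            names.append(f"{cat}_{i + 1:02d}")
    return names


def _schofield_bmr(sex: np.ndarray, age: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Basal metabolic rate (kcal/day) by the Schofield sex/age equations."""
    bmr = np.empty_like(weight, dtype=float)
    male = sex == 0
    young = age < 30
    old = age >= 60
    mid = ~young & ~old
    bmr[male & young] = 15.057 * weight[male & young] + 692.2
    bmr[male & mid] = 11.472 * weight[male & mid] + 873.1
    bmr[male & old] = 11.711 * weight[male & old] + 587.7
    fem = ~male
    bmr[fem & young] = 14.818 * weight[fem & young] + 486.6
    bmr[fem & mid] = 8.126 * weight[fem & mid] + 845.6
    bmr[fem & old] = 9.082 * weight[fem & old] + 658.5
    return bmr


def _categorical_cuts(n_levels: int, dominated: bool, rng: np.random.Generator) -> np.ndarray:
    """Latent-normal thresholds for an ordered categorical exposure.

    Non-dominated variables get roughly balanced levels; dominated ones
    put >= 92% of the mass in the lowest level.
    """
    if dominated:
        # P(z < 1.4) ~ 0.919; push a touch higher for safety at small n.
        first = rng.uniform(1.45, 1.8)
        rest = np.sort(rng.uniform(first + 0.2, 3.0, size=n_levels - 2))
        return np.concatenate([[first], rest])
    qs = np.linspace(0, 1, n_levels + 1)[1:-1]
    jitter = rng.uniform(-0.08, 0.08, size=qs.size)
    from scipy.stats import norm

    return norm.ppf(np.clip(qs + jitter, 0.05, 0.95))


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TrueEffects]:
    """Generate a long-format cohort table, exposure catalog and ground truth.

    Returns
    -------
    cohort : pandas.DataFrame
        One row per participant-visit: ids, visit age/year, sex,
        education, fasting status, FFQ version, anthropometry, total
        energy intake, dietary-quality indicators, medication and
        exclusion flags, the nine traits, and one column per exposure.
    catalog : pandas.DataFrame
        One row per exposure: name, category, type (numeric/ordinal/
        categorical), number of levels and a modifiability flag.
    truth : TrueEffects
        The planted standardized effect matrix and derived label sets.

    The same seed always yields byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    # --- participant-level design -------------------------------------
    sex = rng.integers(0, 2, size=n)  # 0 = male, 1 = female
    education = rng.integers(1, 5, size=n)
    n_visits = rng.choice([1, 2, 3], size=n, p=np.asarray(config.visit_count_probs))
    # First-visit decade chosen so all visits fit inside {30,...,60}.
    max_start = 4 - n_visits  # index into decades (30,40,50,60)
    start_idx = (rng.random(n) * (max_start + 1)).astype(int)
    birth_year = rng.integers(1935, 1976, size=n)

    # --- exposure latents ---------------------------------------------
    exposures = _exposure_names(config.n_exposures_per_category)
    rho = config.exposure_block_correlation
    latents = {}
    cat_of = {}
    for cat in CATEGORIES:
        cnt = config.n_exposures_per_category.get(cat, 0)
        if cnt == 0:
            continue
        shared = rng.standard_normal(n)
        idio = rng.standard_normal((n, cnt))
        block = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * idio
        for i in range(cnt):
            name = f"{cat}_{i + 1:02d}"
            latents[name] = block[:, i]
            cat_of[name] = cat

    # --- catalog: type assignment -------------------------------------
    # Exposures carrying planted effects stay numeric so the planted
    # standardized slope is expressible on the observed scale.
    m = len(exposures)
    planted_names = {e for e, _t, _s in config.planted_effects}
    eligible = np.array([i for i, e in enumerate(exposures) if e not in planted_names])
    n_cat = min(int(round(config.categorical_fraction * m)), eligible.size)
    cat_idx = rng.choice(eligible, size=n_cat, replace=False) if n_cat else np.array([], int)
    is_categorical = np.zeros(m, dtype=bool)
    is_categorical[cat_idx] = True
    n_dom = int(round(config.dominance_fraction * n_cat))
    dom_idx = rng.choice(cat_idx, size=n_dom, replace=False) if n_dom else np.array([], int)
    is_dominated = np.zeros(m, dtype=bool)
    is_dominated[dom_idx.astype(int)] = True
    # ~15% of numeric exposures carry ordinal integer codes.
    is_ordinal = ~is_categorical & (rng.random(m) < 0.15)
    for i, e in enumerate(exposures):
        if e in planted_names:
            is_ordinal[i] = False
    modifiable = rng.random(m) < 0.85

    catalog_rows = []
    observed: dict[str, np.ndarray] = {}
    for k, name in enumerate(exposures):
        z = latents[name]
        if is_categorical[k]:
            n_levels = int(rng.integers(2, 5))
            cuts = _categorical_cuts(n_levels, bool(is_dominated[k]), rng)
            observed[name] = np.searchsorted(cuts, z).astype(float) + 1.0
            etype = "categorical"
        elif is_ordinal[k]:
            n_levels = int(rng.integers(4, 8))
            from scipy.stats import norm

            cuts = norm.ppf(np.linspace(0, 1, n_levels + 1)[1:-1])
            observed[name] = np.searchsorted(cuts, z).astype(float) + 1.0
            etype = "ordinal"
        else:
            n_levels = 0
            observed[name] = z
            etype = "numeric"
        catalog_rows.append(
            {
                "exposure": name,
                "category": cat_of[name],
                "type": etype,
                "n_levels": n_levels,
                "modifiable": bool(modifiable[k]),
            }
        )
    catalog = pd.DataFrame(catalog_rows)

    # --- ground-truth effect matrix -----------------------------------
    effect_matrix = pd.DataFrame(0.0, index=exposures, columns=list(TRAITS))
    for exp, trait, slope in config.planted_effects:
        effect_matrix.loc[exp, trait] += slope
    truth = TrueEffects.from_matrix(effect_matrix)

    # --- participant-level random intercepts and flags ----------------
    intercepts = {
        t: rng.standard_normal(n) * config.random_intercept_sd_per_trait.get(t, 0.0)
        for t in TRAITS
    }
    lipid_prev, bp_prev = config.medication_prevalence
    lipid_med = rng.random(n) < lipid_prev
    bp_med = rng.random(n) < bp_prev
    excl = {
        flag: rng.random(n) < config.exclusion_prevalence.get(flag, 0.0)
        for flag in schema.EXCLUSION_FLAGS
    }
    height = np.where(
        sex == 0, rng.normal(178.0, 6.5, size=n), rng.normal(165.0, 6.0, size=n)
    )

    # Planted linear predictor per trait (participant level).  Slopes are
    # standardized, so scale by the trait's total SD to get trait units.
    planted_lp = {t: np.zeros(n) for t in TRAITS}
    for exp in exposures:
        row = effect_matrix.loc[exp]
        nz = row[row != 0]
        if nz.empty:
            continue
        for trait, slope in nz.items():
            planted_lp[trait] += slope * trait_total_sd(config, trait) * latents[exp]

    # --- visit-level assembly (vectorized over all rows) --------------
    decades = np.array([30.0, 40.0, 50.0, 60.0])
    spacing_mean, spacing_jitter = config.visit_spacing_years
    total = int(n_visits.sum())
    pidx = np.repeat(np.arange(n), n_visits)  # participant index per row
    visit_no = np.concatenate([np.arange(1, k + 1) for k in n_visits])
    base_age = decades[start_idx] + rng.uniform(-1, 1, size=n)
    gaps = spacing_mean + rng.uniform(-spacing_jitter, spacing_jitter, size=total)
    # Age at visit v = base age + sum of the v-1 preceding gaps.
    gaps[visit_no == 1] = 0.0
    first_row = np.concatenate([[0], np.cumsum(n_visits)[:-1]])
    cs = np.cumsum(gaps)
    age = base_age[pidx] + cs - cs[first_row][pidx]  # groupwise cumsum of gaps
    age = np.round(age, 2)  # ages are stored at 2 decimals; use them as-is

    cohort = pd.DataFrame(
        {
            schema.PID: np.array([f"P{j + 1:06d}" for j in range(n)])[pidx],
            schema.VISIT: visit_no,
            schema.AGE: np.round(age, 2),
            "visit_year": (birth_year[pidx] + age).astype(int),
            schema.SEX: sex[pidx],
            schema.EDUCATION: education[pidx],
            schema.FASTING: (rng.random(total) < 0.9).astype(int),
            schema.FFQ_VERSION: (birth_year[pidx] + age >= 1996).astype(int),
            schema.HEIGHT: np.round(height[pidx], 1),
            schema.LIPID_MED: lipid_med[pidx].astype(int),
            schema.BP_MED: bp_med[pidx].astype(int),
            schema.FFQ_MISSING: np.round(rng.beta(1.2, 20.0, size=total), 4),
            schema.PORTION_MISSING: (rng.random(total) < 0.03).astype(int),
        }
    )
    for flag in schema.EXCLUSION_FLAGS:
        cohort[flag] = excl[flag][pidx].astype(int)

    ac = age - 45.0
    for t in TRAITS:
        mu, a1, a2, fem = _TRAIT_COVARIATE_MODEL[t]
        sd_e = config.residual_sd_per_trait.get(t, 0.0)
        val = (
            mu
            + a1 * ac
            + a2 * ac * ac
            + fem * sex[pidx]
            + planted_lp[t][pidx]
            + intercepts[t][pidx]
            + rng.standard_normal(total) * sd_e
        )
        # Medicated participants present lowered observed values; the
        # harmonization correction adds the constants back.
        if t in schema.LIPID_TRAITS:
            val = val - _MEDICATION_SHIFT[t] * lipid_med[pidx]
        if t in schema.BP_TRAITS:
            val = val - _MEDICATION_SHIFT[t] * bp_med[pidx]
        cohort[t] = np.round(val, 4)

    cohort[schema.WEIGHT] = np.round(
        cohort["bmi"].to_numpy() * (height[pidx] / 100.0) ** 2, 2
    )
    bmr = _schofield_bmr(sex[pidx], age, cohort[schema.WEIGHT].to_numpy())
    fil = np.exp(rng.normal(np.log(1.5), 0.18, size=total))
    cohort[schema.TEI] = np.round(bmr * fil, 1)
    cohort = pd.concat(
        [cohort, pd.DataFrame({name: observed[name][pidx] for name in exposures})],
        axis=1,
    )

    # --- missingness (MCAR on exposures and traits) -------------------
    if config.missing_rate > 0:
        cols = list(TRAITS) + exposures
        mask = rng.random((len(cohort), len(cols))) < config.missing_rate
        vals = cohort[cols].to_numpy(dtype=float)
        vals[mask] = np.nan
        cohort[cols] = vals

    return cohort, catalog, truth


def generate_pvalue_panel(
    m: int, frac_nonnull: float, nonnull_mean_z: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a panel of two-sided p-values with known null labels.

    Null entries are two-sided tail probabilities of ``z ~ N(0, 1)`` and
    are therefore uniform on (0, 1); non-null entries come from
    ``z ~ N(nonnull_mean_z, 1)``.  The number of non-null tests is
    ``round(frac_nonnull * m)`` (ties to nearest even).

    Returns ``(pvalues, is_null)`` arrays of length ``m``.
    """
    if m < 1:
        raise ConfigError("m must be >= 1")
    if not 0 <= frac_nonnull <= 1:
        raise ConfigError("frac_nonnull must lie in [0, 1]")
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    n_nonnull = int(np.round(frac_nonnull * m))
    is_null = np.ones(m, dtype=bool)
    if n_nonnull:
        idx = rng.choice(m, size=n_nonnull, replace=False)
        is_null[idx] = False
    z = rng.standard_normal(m)
    z[~is_null] += nonnull_mean_z
    p = 2.0 * norm.sf(np.abs(z))
    return p, is_null
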