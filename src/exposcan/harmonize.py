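"""Cohort cleaning, correction, transformation and encoding rules.

This module turns a raw long-format cohort table into the analysis-ready
table the screens consume.  The rules mirror standard practice in
cardiometabolic epidemiology:

* participant-level exclusion on diagnosed-disease / non-reference flags;
* additive correction of lipid and blood-pressure values for participants
  on lowering medication (published constants);
* derived traits: BMI from weight/height, LDL by the Friedewald formula,
  food intake level (FIL) as total energy intake over basal metabolic rate;
* plausibility filtering of trait values and dietary-quality filtering of
  food-frequency questionnaire (FFQ) records;
* rank-based inverse-normal transformation of numeric exposures;
* dummy encoding of categoricals with the lowest level as reference;
* exclusion of categoricals dominated by a single level;
* energy-residual adjustment of dietary variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import schema


class HarmonizeError(ValueError):
    """Raised when a cleaning rule cannot be applied to the given table."""


#: Published additive correction constants for participants on
#: lipid-lowering (first four) and blood-pressure-lowering medication.
DEFAULT_MEDICATION_CONSTANTS: dict[str, float] = {
    "triglycerides": 0.208,  # mmol/L
    "total_cholesterol": 1.347,  # mmol/L
    "hdl": -0.060,  # mmol/L
    "ldl": 1.290,  # mmol/L
    "sbp": 15.0,  # mmHg
    "dbp": 10.0,  # mmHg
}

#: Default plausibility bounds per trait (artifact choices emulating the
#: data-manager ranges of a health survey; not a published table).
DEFAULT_NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "bmi": (12.0, 60.0),
    "sbp": (70.0, 250.0),
    "dbp": (40.0, 150.0),
    "fasting_glucose": (2.0, 20.0),
    "glucose_2h": (2.0, 25.0),
    "total_cholesterol": (1.5, 12.0),
    "triglycerides": (0.2, 10.0),
    "hdl": (0.3, 4.0),
    "ldl": (0.5, 9.0),
}


@dataclass
class HarmonizeConfig:
    """Thresholds and constants of the harmonization stage."""

    medication_constants: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDICATION_CONSTANTS)
    )
    trait_normal_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NORMAL_RANGES)
    )
    #: FFQ records with more than this fraction of items missing are dropped.
    ffq_missing_limit: float = 0.10
    #: Lower FIL percentile excluded (implausibly low energy reporting).
    fil_lower_pct: float = 5.0
    #: Upper FIL percentile excluded, counted from the top.
    fil_upper_pct: float = 2.5
    #: Categoricals with a modal level at or above this share are dropped.
    dominance_threshold: float = 0.90
    exclusion_flags: Sequence[str] = schema.EXCLUSION_FLAGS
    #: Optional per-trait (slope, intercept) maps aligning instrument eras.
    conversion_maps: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    #: Offset of the rank-based inverse-normal transform (Blom).
    rankit_offset: float = 3.0 / 8.0

    def validate(self) -> None:
        if not 0 < self.ffq_missing_limit < 1:
            raise HarmonizeError("ffq_missing_limit must lie in (0, 1)")
        for name in ("fil_lower_pct", "fil_upper_pct"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise HarmonizeError(f"{name} must lie in (0, 100)")
        if not 0.5 < self.dominance_threshold <= 1:
            raise HarmonizeError("dominance_threshold must lie in (0.5, 1]")
        for trait, (lo, hi) in self.trait_normal_ranges.items():
            if not lo < hi:
                raise HarmonizeError(f"trait_normal_ranges[{trait!r}]: low must be < high")


@dataclass
class ExclusionLog:
    """Ordered record of what each cleaning rule removed.

    Each entry is ``(rule, unit, count)`` where ``unit`` is one of
    ``participant``, ``visit`` or ``cell``.  ``reasons`` optionally maps a
    rule to the identifiers it removed.
    """

    entries: list[tuple[str, str, int]] = field(default_factory=list)
    reasons: dict[str, list] = field(default_factory=dict)

    def add(self, rule: str, unit: str, count: int, ids: Iterable | None = None) -> None:
        if count < 0:
            raise HarmonizeError("exclusion counts must be non-negative")
        self.entries.append((rule, unit, int(count)))
        if ids is not None:
            self.reasons[rule] = list(ids)

    def count(self, rule: str) -> int:
        return sum(c for r, _u, c in self.entries if r == rule)

    def to_json_dict(self) -> dict:
        return {
            "entries": [
                {"rule": r, "unit": u, "count": c} for r, u, c in self.entries
            ],
            "reasons": {k: [str(x) for x in v] for k, v in self.reasons.items()},
        }

    def to_text(self) -> str:
        lines = [f"{r:<30s} {u:<12s} {c:>8d}" for r, u, c in self.entries]
        return "\n".join(lines)


def apply_exclusions(
    table: pd.DataFrame, config: HarmonizeConfig
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove every visit of participants with a true exclusion flag.

    A participant flagged at *any* visit is removed entirely: diagnosed
    disease or non-reference origin is treated as a property of the
    participant, not the visit.  Rules are applied in the configured
    order and each log entry counts participants newly removed by that
    rule.
    """
    log = ExclusionLog()
    missing = [c for c in config.exclusion_flags if c not in table.columns]
    if missing:
        raise HarmonizeError(f"exclusion flag column(s) not in table: {missing}")
    keep = table
    for flag in config.exclusion_flags:
        flagged = keep.loc[keep[flag].fillna(0).astype(bool), schema.PID].unique()
        log.add(flag, "participant", len(flagged), ids=flagged)
        if len(flagged):
            keep = keep[~keep[schema.PID].isin(flagged)]
    return keep.copy(), log


def correct_medication(
    table: pd.DataFrame, constants: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Add published constants to medicated participants' trait values.

    Lipid traits are shifted for rows with the lipid-medication flag,
    blood-pressure traits for rows with the BP-medication flag.  The
    correction is applied exactly once; rows without flags are untouched.
    """
    constants = dict(DEFAULT_MEDICATION_CONSTANTS if constants is None else constants)
    known = set(schema.LIPID_TRAITS) | set(schema.BP_TRAITS)
    unknown = set(constants) - known
    if unknown:
        raise HarmonizeError(f"unknown trait key(s) in medication constants: {sorted(unknown)}")
    out = table.copy()
    lipid_rows = out[schema.LIPID_MED].fillna(0).astype(bool)
    bp_rows = out[schema.BP_MED].fillna(0).astype(bool)
    for trait, const in constants.items():
        if trait not in out.columns:
            continue
        rows = lipid_rows if trait in schema.LIPID_TRAITS else bp_rows
        out.loc[rows, trait] = out.loc[rows, trait] + const
    return out


def friedewald_ldl(tc: np.ndarray, hdl: np.ndarray, tg: np.ndarray) -> np.ndarray:
    """LDL cholesterol by the Friedewald formula, mmol/L convention.

    LDL = TC - HDL - TG / 2.2.
    """
    return np.asarray(tc, float) - np.asarray(hdl, float) - np.asarray(tg, float) / 2.2


def derive_traits(table: pd.DataFrame, recompute_ldl: bool = False) -> pd.DataFrame:
    """Compute BMI, Friedewald LDL and food intake level where absent.

    BMI = weight (kg) / height (m)^2; FIL = TEI / BMR with BMR by the
    Schofield sex/age/weight equations unless a ``bmr`` column is
    supplied.  Existing LDL values are only overwritten when
    ``recompute_ldl`` is set.  Non-positive heights or BMRs yield missing
    derived values.
    """
    out = table.copy()
    if schema.WEIGHT in out.columns and schema.HEIGHT in out.columns:
        h = out[schema.HEIGHT].to_numpy(dtype=float) / 100.0
        w = out[schema.WEIGHT].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            bmi = w / (h * h)
        bmi[~(h > 0)] = np.nan
        if "bmi" not in out.columns:
            out["bmi"] = bmi
        else:
            out["bmi"] = out["bmi"].fillna(pd.Series(bmi, index=out.index))
    if {"total_cholesterol", "hdl", "triglycerides"} <= set(out.columns):
        ldl = friedewald_ldl(
            out["total_cholesterol"].to_numpy(float),
            out["hdl"].to_numpy(float),
            out["triglycerides"].to_numpy(float),
        )
        if "ldl" not in out.columns:
            out["ldl"] = ldl
        elif recompute_ldl:
            out["ldl"] = ldl
        else:
            out["ldl"] = out["ldl"].fillna(pd.Series(ldl, index=out.index))
    if schema.TEI in out.columns:
        if schema.BMR in out.columns:
            bmr = out[schema.BMR].to_numpy(dtype=float)
        else:
            from .synthetic import _schofield_bmr

            bmr = _schofield_bmr(
                out[schema.SEX].to_numpy(),
                out[schema.AGE].to_numpy(dtype=float),
                out[schema.WEIGHT].to_numpy(dtype=float),
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            fil = out[schema.TEI].to_numpy(dtype=float) / bmr
        fil[~(bmr > 0)] = np.nan
        out[schema.FIL] = fil
    return out


def filter_records(
    table: pd.DataFrame,
    config: HarmonizeConfig,
    dietary_columns: Sequence[str] = (),
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply trait plausibility bounds and dietary-quality rules.

    Trait values outside their (low, high) range become missing
    (cell-level exclusion).  Visits failing any dietary-quality rule —
    FFQ missingness above the limit, a missing portion indication, or a
    food intake level in the implausible tails of the input FIL
    distribution — have all dietary variables (and TEI) set missing.
    """
    out = table.copy()
    log = ExclusionLog()
    for trait, (lo, hi) in config.trait_normal_ranges.items():
        if trait not in out.columns:
            continue
        vals = out[trait]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        log.add(f"outlier:{trait}", "cell", int(bad.sum()))
        out.loc[bad, trait] = np.nan

    bad_visit = pd.Series(False, index=out.index)
    if schema.FFQ_MISSING in out.columns:
        f = out[schema.FFQ_MISSING]
        hit = f.notna() & (f > config.ffq_missing_limit)
        log.add("ffq_missingness", "visit", int(hit.sum()))
        bad_visit |= hit
    if schema.PORTION_MISSING in out.columns:
        hit = out[schema.PORTION_MISSING].fillna(0).astype(bool)
        log.add("portion_missing", "visit", int(hit.sum()))
        bad_visit |= hit
    if schema.FIL in out.columns and out[schema.FIL].notna().any():
        fil = out[schema.FIL]
        lo = np.nanpercentile(fil, config.fil_lower_pct)
        hi = np.nanpercentile(fil, 100.0 - config.fil_upper_pct)
        hit = fil.notna() & ((fil < lo) | (fil > hi))
        log.add("implausible_fil", "visit", int(hit.sum()))
        bad_visit |= hit
    diet_cols = [c for c in dietary_columns if c in out.columns]
    if schema.TEI in out.columns:
        diet_cols = diet_cols + [schema.TEI]
    if diet_cols and bad_visit.any():
        out.loc[bad_visit, diet_cols] = np.nan
    return out, log


def inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with a Blom offset.

    Non-missing entries are mapped to standard-normal quantiles of
    ``(rank - offset) / (n + 1 - 2*offset)`` with average ranks for ties,
    so tied inputs get equal outputs and the output preserves the input's
    rank order.  Missing entries stay missing.  The result has
    (approximately) zero mean and unit variance, which also delivers the
    cross-variable comparability scaling.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 2:
        raise HarmonizeError("inverse_normal needs at least 2 non-missing values")
    v = x[obs]
    if np.nanmax(v) == np.nanmin(v):
        raise HarmonizeError("inverse_normal undefined for a constant vector")
    ranks = stats.rankdata(v, method="average")
    out = np.full_like(x, np.nan)
    out[obs] = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    return out


def encode_categorical(
    values, levels: Sequence | None = None, name: str = "var"
) -> pd.DataFrame:
    """Expand a categorical vector into k-1 reference-coded indicators.

    Levels are ordered low to high and the lowest observed level is the
    reference.  Each indicator column is named ``name::level`` so it can
    be traced back to its parent variable.  Missing input propagates to
    missing indicators.
    """
    s = pd.Series(values)
    observed = sorted(s.dropna().unique())
    if levels is not None:
        observed = [lv for lv in levels if lv in set(observed)]
    if len(observed) < 2:
        raise HarmonizeError(f"categorical {name!r} has fewer than 2 observed levels")
    out = {}
    for level in observed[1:]:
        col = np.where(s.isna(), np.nan, (s == level).astype(float))
        out[schema.dummy_name(name, level)] = col
    return pd.DataFrame(out, index=s.index)


def drop_dominated(
    catalog: pd.DataFrame, table: pd.DataFrame, threshold: float = 0.90
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop categorical exposures dominated by a single level.

    A categorical whose modal level holds at least ``threshold`` of the
    non-missing observations is removed from the catalog (its indicator
    contrasts would be near-degenerate).  Numeric and ordinal exposures
    are never dropped here.
    """
    if not 0.5 < threshold <= 1:
        raise HarmonizeError("dominance threshold must lie in (0.5, 1]")
    log = ExclusionLog()
    dropped = []
    for _, row in catalog.iterrows():
        if row["type"] != "categorical":
            continue
        name = row["exposure"]
        if name not in table.columns:
            continue
        counts = table[name].value_counts(dropna=True)
        if counts.empty:
            continue
        if counts.iloc[0] / counts.sum() >= threshold:
            dropped.append(name)
    log.add("dominated_categorical", "exposure", len(dropped), ids=dropped)
    kept = catalog[~catalog["exposure"].isin(dropped)].reset_index(drop=True)
    return kept, log


def energy_adjust(dietary, tei) -> np.ndarray:
    """Residuals of the dietary variable regressed on total energy intake.

    Implements the energy-residual method: the returned vector is the
    least-squares residual of ``dietary ~ 1 + tei`` over pairwise
    complete observations, hence mean-zero and uncorrelated with TEI.
    Rows where either input is missing stay missing.
    """
    d = np.asarray(dietary, dtype=float)
    t = np.asarray(tei, dtype=float)
    obs = ~np.isnan(d) & ~np.isnan(t)
    if obs.sum() < 3:
        raise HarmonizeError("energy_adjust needs >= 3 paired non-missing observations")
    tv = t[obs]
    if np.ptp(tv) == 0:
        raise HarmonizeError("energy_adjust undefined for constant TEI")
    X = np.column_stack([np.ones(obs.sum()), tv])
    beta, *_ = np.linalg.lstsq(X, d[obs], rcond=None)
    out = np.full_like(d, np.nan)
    out[obs] = d[obs] - X @ beta
    return out


def harmonize_table(
    table: pd.DataFrame,
    catalog: pd.DataFrame,
    config: HarmonizeConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Run the full harmonization pipeline on a raw cohort table.

    Order of operations: participant exclusions, instrument-era
    conversion (if configured), medication correction, trait derivation,
    plausibility and dietary-quality filtering, dominance filtering of
    categoricals, then inverse-normal transformation of numeric/ordinal
    exposures.  Categorical exposures keep their level codes (the screens
    expand them to dummies per model).  Returns the analysis table, the
    filtered catalog and the merged exclusion log.
    """
    config = config or HarmonizeConfig()
    config.validate()
    log = ExclusionLog()

    out, exlog = apply_exclusions(table, config)
    log.entries += exlog.entries
    log.reasons.update(exlog.reasons)

    for trait, (slope, intercept) in config.conversion_maps.items():
        if trait in out.columns:
            out[trait] = slope * out[trait] + intercept

    out = correct_medication(out, config.medication_constants)
    out = derive_traits(out)

    diet_cols = [
        c
        for c in catalog.loc[
            catalog["category"].isin(schema.DIETARY_CATEGORIES), "exposure"
        ]
        if c in out.columns
    ]
    out, flog = filter_records(out, config, dietary_columns=diet_cols)
    log.entries += flog.entries

    catalog, dlog = drop_dominated(catalog, out, config.dominance_threshold)
    log.entries += dlog.entries
    log.reasons.update(dlog.reasons)

    # Follow-up time: years since the participant's first visit.
    first_age = out.groupby(schema.PID)[schema.AGE].transform("min")
    out[schema.FOLLOWUP] = out[schema.AGE] - first_age

    for _, row in catalog.iterrows():
        name = row["exposure"]
        if name not in out.columns or row["type"] == "categorical":
            continue
        vals = out[name].to_numpy(dtype=float)
        if (~np.isnan(vals)).sum() < 2 or np.nanmax(vals) == np.nanmin(vals):
            continue  # left untransformed; the screen will skip degenerate columns
        out[name] = inverse_normal(vals, offset=config.rankit_offset)

    return out, catalog, log
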