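"""Shared column names, trait definitions and exposure-category vocabulary.

The pipeline screens lifestyle exposures against nine cardiometabolic
traits measured repeatedly in a population cohort.  Everything downstream
(harmonization, the mixed-model screen, the change screen, discovery)
agrees on the vocabulary defined here.
"""

from __future__ import annotations

#: The nine cardiometabolic outcome traits, in canonical order.
TRAITS = (
    "bmi",
    "sbp",
    "dbp",
    "fasting_glucose",
    "glucose_2h",
    "total_cholesterol",
    "triglycerides",
    "hdl",
    "ldl",
)

#: Lipid traits corrected when the lipid-lowering medication flag is set.
LIPID_TRAITS = ("triglycerides", "total_cholesterol", "hdl", "ldl")

#: Blood-pressure traits corrected when the BP medication flag is set.
BP_TRAITS = ("sbp", "dbp")

#: Traits whose models adjust for fasting status (glycaemic and lipid).
FASTING_ADJUSTED_TRAITS = (
    "fasting_glucose",
    "glucose_2h",
    "total_cholesterol",
    "triglycerides",
    "hdl",
    "ldl",
)

#: The ten lifestyle exposure categories.
CATEGORIES = (
    "alcohol",
    "beverage",
    "food",
    "nutrient",
    "general_health",
    "physical_activity",
    "psychosocial",
    "sleep",
    "social",
    "tobacco",
)

#: Categories whose exposures receive dietary adjustments (energy
#: residuals, TEI and FFQ-version covariates).
DIETARY_CATEGORIES = frozenset({"alcohol", "beverage", "food", "nutrient"})

# Core column names of the long-format cohort table.
PID = "pid"
VISIT = "visit"
AGE = "age"
SEX = "sex"
EDUCATION = "education"
FASTING = "fasting_status"
FFQ_VERSION = "ffq_version"
TEI = "tei"
BMR = "bmr"
HEIGHT = "height_cm"
WEIGHT = "weight_kg"
LIPID_MED = "lipid_med"
BP_MED = "bp_med"
FFQ_MISSING = "ffq_missing_frac"
PORTION_MISSING = "portion_missing"
FIL = "fil"
FOLLOWUP = "followup_time"

#: Boolean participant-level exclusion flags (diagnosed disease and a
#: generic non-reference-population flag).
EXCLUSION_FLAGS = ("diabetes", "cvd", "non_reference_origin")

#: Separator used when expanding a categorical exposure into dummy columns.
DUMMY_SEP = "::"


def dummy_name(variable: str, level: object) -> str:
    """Name of the indicator column for ``level`` of ``variable``."""
    return f"{variable}{DUMMY_SEP}{level}"


def parent_variable(column: str) -> str:
    """Parent exposure of a (possibly dummy-expanded) result column."""
    return column.split(DUMMY_SEP, 1)[0]
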