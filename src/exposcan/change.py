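"""Ten-year change analysis: baseline/follow-up pairing and regression.

Long-term associations are assessed by regressing the follow-up value of
a trait on its baseline value, the baseline exposure and covariates:

    y_F = a + b1*age_B + b2*age_B^2 + b3*sex + b4*followup_time
          + b6*y_B + b7*ffq_version_B + b8*tei_B + b9*meanBMI
          + b10*fasting_B + b11*fasting_F + b12*exposure_B + e

where meanBMI averages the baseline and follow-up BMI.  FFQ version and
TEI enter only for dietary exposures and meanBMI is omitted when the
trait is BMI.  Education is deliberately not part of this covariate set
(unlike the average model); the difference is documented rather than
harmonized away.  Each participant contributes at most one pair, built
from their first visit and the later visit closest to the target gap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import schema
from .harmonize import encode_categorical, energy_adjust
from .mixedmodel import RESULT_COLUMNS, FitError, _failure_row


def build_pairs(
    clean: pd.DataFrame,
    target_years: float = 10.0,
    tolerance_years: float = 2.0,
    exposure_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Build at most one baseline/follow-up visit pair per participant.

    The baseline is the participant's first visit; the follow-up is the
    later visit whose gap is closest to ``target_years`` and within
    ``target_years +/- tolerance_years``.  Baseline values of the
    covariates and exposures are kept with suffix ``_B``; the traits are
    kept at both ends (``_B``/``_F``).  ``meanBMI`` averages the two BMI
    values and is missing whenever either is.  Deterministic and
    invariant to input row order.
    """
    df = clean.sort_values([schema.PID, schema.AGE], kind="stable")
    exposure_columns = exposure_columns or []
    rows = []
    for pid, grp in df.groupby(schema.PID, sort=True):
        if len(grp) < 2:
            continue
        base = grp.iloc[0]
        gaps = grp[schema.AGE].to_numpy(dtype=float) - float(base[schema.AGE])
        cand = np.flatnonzero(
            (gaps > 0) & (np.abs(gaps - target_years) <= tolerance_years)
        )
        if cand.size == 0:
            continue
        best = cand[np.argmin(np.abs(gaps[cand] - target_years))]
        fu = grp.iloc[best]
        rec = {
            schema.PID: pid,
            "age_B": float(base[schema.AGE]),
            schema.SEX: base[schema.SEX],
            "followup_years": float(gaps[best]),
            "ffq_version_B": base.get(schema.FFQ_VERSION, np.nan),
            "tei_B": base.get(schema.TEI, np.nan),
            "fasting_B": base.get(schema.FASTING, np.nan),
            "fasting_F": fu.get(schema.FASTING, np.nan),
        }
        for trait in schema.TRAITS:
            if trait in grp.columns:
                rec[f"{trait}_B"] = base[trait]
                rec[f"{trait}_F"] = fu[trait]
        if "bmi" in grp.columns:
            b, f = base["bmi"], fu["bmi"]
            rec["meanBMI"] = (b + f) / 2.0 if pd.notna(b) and pd.notna(f) else np.nan
        for col in exposure_columns:
            if col in grp.columns:
                rec[f"{col}_B"] = base[col]
        rows.append(rec)
    return pd.DataFrame(rows)


def _ols(y: np.ndarray, X: np.ndarray, columns: list[str]):
    """OLS through a QR-based orthogonal decomposition, with t p-values."""
    n, p = X.shape
    if n < p + 2:
        raise FitError("too few complete cases for the change model")
    beta, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        dependent = [columns[i] for i in range(p) if i >= rank]
        raise FitError(f"rank-deficient design (suspect columns: {dependent})")
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return beta, se, pvals, sigma2, df_resid, resid


def change_covariates(trait: str, dietary: bool) -> list[str]:
    """Covariate names of the change model for one outcome trait."""
    covs = ["age_B", "age_B_sq", schema.SEX, "followup_years", f"{trait}_B"]
    if dietary:
        covs += ["ffq_version_B", "tei_B"]
    if trait != "bmi":
        covs.append("meanBMI")
    covs += ["fasting_B", "fasting_F"]
    return covs


def fit_change_model(
    pairs: pd.DataFrame,
    exposure: str,
    trait: str,
    dietary: bool = False,
) -> dict:
    """Fit the baseline-adjusted change regression for one exposure/trait.

    ``exposure`` names a baseline column of ``pairs`` (suffix ``_B``
    already applied, or a dummy thereof).  Returns a dict with the
    exposure estimate/SE/p, the full coefficient table, residual
    variance, degrees of freedom and the exposure's semi-partial R^2
    (the R^2 drop when the exposure column is removed).
    """
    covs = change_covariates(trait, dietary)
    y = pairs[f"{trait}_F"].to_numpy(dtype=float)
    work = pairs.copy()
    age_c = work["age_B"].to_numpy(dtype=float)
    age_c = age_c - np.nanmean(age_c)
    work["age_B"] = age_c
    work["age_B_sq"] = age_c**2
    colnames = ["intercept"] + covs + [exposure]
    cols = [np.ones(len(work))]
    cols += [work[c].to_numpy(dtype=float) for c in covs]
    cols.append(work[exposure].to_numpy(dtype=float))
    X = np.column_stack(cols)
    mask = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    n = int(mask.sum())
    Xm, ym = X[mask], y[mask]
    if np.ptp(Xm[:, -1]) == 0:
        raise FitError(f"exposure {exposure!r} constant on complete cases")
    beta, se, pvals, sigma2, df_resid, resid = _ols(ym, Xm, colnames)

    tss = float(np.sum((ym - ym.mean()) ** 2))
    r2_full = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    X_red = Xm[:, :-1]
    beta_r, *_rest, resid_r = _ols(ym, X_red, colnames[:-1])
    r2_red = 1.0 - float(resid_r @ resid_r) / tss if tss > 0 else 0.0
    return {
        "params": pd.Series(beta, index=colnames),
        "se": pd.Series(se, index=colnames),
        "pvalues": pd.Series(pvals, index=colnames),
        "estimate": float(beta[-1]),
        "exposure_se": float(se[-1]),
        "p": float(pvals[-1]),
        "sigma2": sigma2,
        "df_resid": int(df_resid),
        "n": n,
        "semipartial_r2": max(0.0, r2_full - r2_red),
    }


def screen_change(
    clean: pd.DataFrame,
    catalog: pd.DataFrame,
    traits: list[str] | None = None,
    target_years: float = 10.0,
    tolerance_years: float = 2.0,
    min_n: int = 30,
) -> pd.DataFrame:
    """Run the 10-year change screen over all exposures and traits.

    Mirrors the average screen's result schema with ``mode = "change"``;
    variance explained is the exposure's semi-partial R^2.  When no
    participant has an eligible visit pair the result is empty rows with
    an explanatory status.
    """
    traits = list(traits) if traits is not None else [t for t in schema.TRAITS if t in clean]
    exposures = [e for e in catalog["exposure"] if e in clean.columns]
    pairs = build_pairs(clean, target_years, tolerance_years, exposure_columns=exposures)
    rows: list[dict] = []
    if pairs.empty:
        for _, crow in catalog.iterrows():
            for trait in traits:
                rows.append(
                    _failure_row(
                        crow["exposure"], crow["exposure"], crow["category"],
                        trait, "change", "no_pairs",
                    )
                )
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    for _, crow in catalog.iterrows():
        name = crow["exposure"]
        category = crow["category"]
        dietary = category in schema.DIETARY_CATEGORIES
        base_col = f"{name}_B"
        if base_col not in pairs.columns:
            for trait in traits:
                rows.append(
                    _failure_row(name, name, category, trait, "change", "missing_column")
                )
            continue
        if crow["type"] == "categorical":
            try:
                dummies = encode_categorical(pairs[base_col], name=name)
            except Exception as exc:
                for trait in traits:
                    rows.append(
                        _failure_row(name, name, category, trait, "change", f"error:{exc}")
                    )
                continue
            term_cols = {c: dummies[c] for c in dummies.columns}
        elif dietary and "tei_B" in pairs.columns:
            resid = energy_adjust(
                pairs[base_col].to_numpy(dtype=float),
                pairs["tei_B"].to_numpy(dtype=float),
            )
            term_cols = {name: pd.Series(resid, index=pairs.index)}
        else:
            term_cols = {name: pairs[base_col]}

        for tname, series in term_cols.items():
            work = pairs.assign(**{f"__term_{tname}": series})
            for trait in traits:
                try:
                    fit = fit_change_model(
                        work, f"__term_{tname}", trait, dietary=dietary
                    )
                except (FitError, KeyError) as exc:
                    rows.append(
                        _failure_row(tname, name, category, trait, "change", f"error:{exc}")
                    )
                    continue
                if fit["n"] < min_n:
                    rows.append(
                        _failure_row(tname, name, category, trait, "change", "too_few_obs")
                    )
                    continue
                rows.append(
                    {
                        "exposure": tname,
                        "parent_variable": name,
                        "category": category,
                        "trait": trait,
                        "mode": "change",
                        "estimate": fit["estimate"],
                        "se": fit["exposure_se"],
                        "p": fit["p"],
                        "n_obs": fit["n"],
                        "n_participants": fit["n"],
                        "var_explained": fit["semipartial_r2"],
                        "status": "ok",
                    }
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
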