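"""Random-intercept linear mixed model and the average-association screen.

The average association of a lifestyle exposure with a repeatedly
measured trait is estimated by the random-intercept model

    y_ij = x_ij' beta + u_j + e_ij,   u_j ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)

fitted by restricted maximum likelihood (REML).  Estimation profiles the
fixed effects and the residual variance out of the REML objective and
performs a one-dimensional search over the log variance ratio
``lambda = s_u^2 / s_e^2``; fixed effects are then generalized least
squares at the estimated components.  With a single visit per
participant the ratio is unidentifiable and the fit reduces to OLS at
the boundary ``lambda = 0``.

The screen loops exposures x traits, adjusting each model for age,
age^2 (centered), sex, education and follow-up time, plus BMI (except
when BMI is the outcome), fasting status for glycaemic and lipid
outcomes, and FFQ version and total energy intake for dietary
exposures, whose values enter as energy residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import schema
from .harmonize import encode_categorical, energy_adjust


class FitError(RuntimeError):
    """Model could not be estimated (rank deficiency, no groups, ...)."""


@dataclass
class LMMFit:
    """A fitted random-intercept model.

    ``params``/``se`` are indexed by design-column name; ``sigma2_u`` and
    ``sigma2_e`` are the random-intercept and residual variances;
    ``reml_loglik`` is the restricted log-likelihood up to an additive
    constant shared across variance ratios.
    """

    params: pd.Series
    se: pd.Series
    vcov: np.ndarray
    sigma2_u: float
    sigma2_e: float
    reml_loglik: float
    n_obs: int
    n_groups: int
    converged: bool

    @property
    def columns(self) -> list[str]:
        return list(self.params.index)


def _group_structure(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort order and group start offsets for reduceat-based group sums."""
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    starts = np.flatnonzero(
        np.r_[True, sorted_groups[1:] != sorted_groups[:-1]]
    )
    return order, starts


def _reml_profile(lam, XtX, Xty, yty, S, t, n_j, N, p):
    """Profiled REML deviance and GLS pieces at variance ratio ``lam``.

    Uses the rank-one Woodbury form of (I + lam*J)^{-1} per group, so one
    evaluation costs O(groups * p^2).
    """
    c = lam / (1.0 + lam * n_j)
    A = XtX - (S.T * c) @ S
    b = Xty - S.T @ (c * t)
    try:
        L = np.linalg.cholesky(A)
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise FitError("design matrix is rank deficient") from exc
    rss = yty - (c * t) @ t - beta @ b
    rss = max(rss, 1e-300)
    logdet_A = 2.0 * np.log(np.diag(L)).sum()
    logdet_H = np.log1p(lam * n_j).sum()
    deviance = (N - p) * np.log(rss) + logdet_H + logdet_A
    return deviance, beta, A, rss


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    columns: list[str] | None = None,
    tol: float = 1e-8,
) -> LMMFit:
    """REML fit of a random-intercept model on complete-case data.

    Parameters
    ----------
    y, X, groups
        Outcome vector, full-column-rank design matrix (including the
        intercept column) and participant identifiers, all aligned and
        free of missing values.
    columns
        Design column names; defaults to ``x0..x{p-1}``.
    tol
        Convergence tolerance of the variance-ratio search (log scale).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    N, p = X.shape
    if y.shape[0] != N or groups.shape[0] != N:
        raise FitError("y, X and groups must have equal length")
    if np.isnan(y).any() or np.isnan(X).any():
        raise FitError("complete cases required: drop missing rows first")
    columns = columns or [f"x{i}" for i in range(p)]

    order, starts = _group_structure(groups)
    g = starts.size
    if g < 2:
        raise FitError("need at least 2 participants")
    ys = y[order]
    Xs = X[order]
    n_j = np.diff(np.r_[starts, N]).astype(float)
    S = np.add.reduceat(Xs, starts, axis=0)  # per-group column sums of X
    t = np.add.reduceat(ys, starts)  # per-group sums of y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = y @ y

    def deviance(theta: float) -> float:
        return _reml_profile(np.exp(theta), XtX, Xty, yty, S, t, n_j, N, p)[0]

    dev0, *_ = _reml_profile(0.0, XtX, Xty, yty, S, t, n_j, N, p)
    max_visits = n_j.max()
    if max_visits <= 1:
        # One visit per participant: the ratio is unidentifiable; OLS.
        lam_hat, converged = 0.0, True
    else:
        res = optimize.minimize_scalar(
            deviance, bounds=(-15.0, 15.0), method="bounded",
            options={"xatol": tol},
        )
        if not res.success:
            raise FitError(f"variance-ratio search did not converge: {res.message}")
        lam_hat = float(np.exp(res.x))
        converged = True
        if dev0 <= res.fun:
            lam_hat = 0.0  # boundary: no between-participant variance

    dev, beta, A, rss = _reml_profile(lam_hat, XtX, Xty, yty, S, t, n_j, N, p)
    sigma2_e = rss / (N - p)
    sigma2_u = lam_hat * sigma2_e
    vcov = sigma2_e * np.linalg.inv(A)
    se = np.sqrt(np.diag(vcov))
    if not (se > 0).all():
        raise FitError("non-positive standard error: check design scaling")
    loglik = -0.5 * (dev + (N - p) * (1.0 + np.log(2.0 * np.pi) - np.log(N - p)))
    return LMMFit(
        params=pd.Series(beta, index=columns),
        se=pd.Series(se, index=columns),
        vcov=vcov,
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        reml_loglik=float(loglik),
        n_obs=int(N),
        n_groups=int(g),
        converged=converged,
    )


def reml_deviance(y, X, groups, lam: float) -> float:
    """Profiled REML deviance at a given variance ratio (diagnostics)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    N, p = X.shape
    order, starts = _group_structure(groups)
    ys, Xs = y[order], X[order]
    n_j = np.diff(np.r_[starts, N]).astype(float)
    S = np.add.reduceat(Xs, starts, axis=0)
    t = np.add.reduceat(ys, starts)
    return _reml_profile(lam, X.T @ X, X.T @ y, y @ y, S, t, n_j, N, p)[0]


def wald_pvalue(fit: LMMFit, term: str) -> float:
    """Two-sided Wald p-value of a fixed-effect term (normal reference)."""
    if term not in fit.params.index:
        raise FitError(f"term {term!r} not in fitted model")
    se = fit.se[term]
    if not se > 0:
        raise FitError(f"term {term!r} has zero standard error")
    z = fit.params[term] / se
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def marginal_r2(fit: LMMFit, X: np.ndarray) -> float:
    """Marginal variance explained by the fixed effects.

    var(X beta) / (var(X beta) + s_u^2 + s_e^2), the fixed-terms share of
    the model-implied outcome variance.
    """
    fitted = np.asarray(X, float) @ fit.params.to_numpy()
    vf = float(np.var(fitted))
    return vf / (vf + fit.sigma2_u + fit.sigma2_e)


def term_variance_explained(
    fit: LMMFit, X: np.ndarray, term: str | list[str]
) -> float:
    """Marginal-R2 drop when a term's fitted contribution is removed.

    For a categorical exposure pass all sibling dummy columns together.
    Floored at zero: collinear terms can have negative raw drops.
    """
    terms = [term] if isinstance(term, str) else list(term)
    for tname in terms:
        if tname not in fit.params.index:
            raise FitError(f"term {tname!r} not in fitted model")
    X = np.asarray(X, float)
    beta = fit.params.to_numpy()
    fitted = X @ beta
    idx = [fit.columns.index(tname) for tname in terms]
    reduced = fitted - X[:, idx] @ beta[idx]
    denom_full = float(np.var(fitted)) + fit.sigma2_u + fit.sigma2_e
    vr = float(np.var(reduced))
    r2_full = float(np.var(fitted)) / denom_full
    r2_red = vr / (vr + fit.sigma2_u + fit.sigma2_e)
    return max(0.0, r2_full - r2_red)


RESULT_COLUMNS = [
    "exposure",
    "parent_variable",
    "category",
    "trait",
    "mode",
    "estimate",
    "se",
    "p",
    "n_obs",
    "n_participants",
    "var_explained",
    "status",
]


def _failure_row(name: str, parent: str, category: str, trait: str, mode: str, status: str) -> dict:
    return {
        "exposure": name,
        "parent_variable": parent,
        "category": category,
        "trait": trait,
        "mode": mode,
        "estimate": np.nan,
        "se": np.nan,
        "p": np.nan,
        "n_obs": 0,
        "n_participants": 0,
        "var_explained": np.nan,
        "status": status,
    }


def average_covariates(trait: str, dietary: bool) -> list[str]:
    """Covariate names of the average-association model for one outcome."""
    covs = [schema.AGE, "age_sq", schema.SEX, schema.EDUCATION, schema.FOLLOWUP]
    if dietary:
        covs += [schema.FFQ_VERSION, schema.TEI]
    if trait != "bmi":
        covs.append("bmi")
    if trait in schema.FASTING_ADJUSTED_TRAITS:
        covs.append(schema.FASTING)
    return covs


def _exposure_design(
    clean: pd.DataFrame, row: pd.Series
) -> tuple[dict[str, np.ndarray], bool]:
    """Exposure term columns for one catalog entry.

    Numeric/ordinal exposures contribute one column (dietary ones as
    energy residuals); categoricals contribute their k-1 dummies.
    Returns the term-name -> column mapping and the dietary flag.
    """
    name = row["exposure"]
    dietary = row["category"] in schema.DIETARY_CATEGORIES
    vals = clean[name].to_numpy(dtype=float)
    if row["type"] == "categorical":
        dummies = encode_categorical(clean[name], name=name)
        return {c: dummies[c].to_numpy(dtype=float) for c in dummies.columns}, dietary
    if dietary and schema.TEI in clean.columns:
        vals = energy_adjust(vals, clean[schema.TEI].to_numpy(dtype=float))
    return {name: vals}, dietary


def screen_average(
    clean: pd.DataFrame,
    catalog: pd.DataFrame,
    traits: list[str] | None = None,
    min_n: int = 30,
) -> pd.DataFrame:
    """Run the average-association screen: one model per exposure x trait.

    Each row of the returned frame is one exposure term (variable or
    dummy level) against one trait, with the Wald estimate, SE, p-value,
    sample sizes and the term's marginal variance explained.  Per-model
    failures are recorded in the ``status`` column, never raised.
    """
    traits = list(traits) if traits is not None else [t for t in schema.TRAITS if t in clean]
    base = {
        schema.AGE: clean[schema.AGE].to_numpy(dtype=float),
        schema.SEX: clean[schema.SEX].to_numpy(dtype=float),
        schema.EDUCATION: clean[schema.EDUCATION].to_numpy(dtype=float),
        schema.FOLLOWUP: clean[schema.FOLLOWUP].to_numpy(dtype=float),
    }
    age_c = base[schema.AGE] - np.nanmean(base[schema.AGE])
    base[schema.AGE] = age_c
    base["age_sq"] = age_c**2
    for extra in (schema.FFQ_VERSION, schema.TEI, schema.FASTING, "bmi"):
        if extra in clean.columns:
            base[extra] = clean[extra].to_numpy(dtype=float)
    groups_all = clean[schema.PID].to_numpy()

    rows: list[dict] = []
    for _, crow in catalog.iterrows():
        name = crow["exposure"]
        category = crow["category"]
        if name not in clean.columns:
            for trait in traits:
                rows.append(
                    _failure_row(name, name, category, trait, "average", "missing_column")
                )
            continue
        try:
            terms, _dietary = _exposure_design(clean, crow)
        except Exception as exc:  # degenerate exposure: log per trait
            for trait in traits:
                rows.append(
                    _failure_row(name, name, category, trait, "average", f"error:{exc}")
                )
            continue
        dietary = crow["category"] in schema.DIETARY_CATEGORIES
        term_names = list(terms)
        for trait in traits:
            covs = average_covariates(trait, dietary)
            colnames = ["intercept"] + covs + term_names
            cols = [np.ones(len(clean))]
            cols += [base[c] for c in covs]
            cols += [terms[c] for c in term_names]
            M = np.column_stack(cols)
            yv = clean[trait].to_numpy(dtype=float)
            mask = ~np.isnan(yv) & ~np.isnan(M).any(axis=1)
            n = int(mask.sum())
            if n < max(min_n, M.shape[1] + 2):
                for tname in term_names:
                    rows.append(
                        _failure_row(tname, name, category, trait, "average", "too_few_obs")
                    )
                continue
            Xm, ym, gm = M[mask], yv[mask], groups_all[mask]
            # Drop constant exposure columns after masking.
            if any(np.ptp(Xm[:, colnames.index(tn)]) == 0 for tn in term_names):
                for tname in term_names:
                    rows.append(
                        _failure_row(tname, name, category, trait, "average", "degenerate")
                    )
                continue
            try:
                fit = fit_random_intercept(ym, Xm, gm, columns=colnames)
            except FitError as exc:
                for tname in term_names:
                    rows.append(
                        _failure_row(tname, name, category, trait, "average", f"error:{exc}")
                    )
                continue
            n_part = len(np.unique(gm))
            for tname in term_names:
                rows.append(
                    {
                        "exposure": tname,
                        "parent_variable": name,
                        "category": category,
                        "trait": trait,
                        "mode": "average",
                        "estimate": float(fit.params[tname]),
                        "se": float(fit.se[tname]),
                        "p": wald_pvalue(fit, tname),
                        "n_obs": n,
                        "n_participants": n_part,
                        "var_explained": term_variance_explained(fit, Xm, tname),
                        "status": "ok",
                    }
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
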