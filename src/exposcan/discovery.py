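"""Signal calling, prioritization and correlation clustering.

After the screens produce one association record per exposure term and
trait, discovery proceeds in four steps:

1. Benjamini-Hochberg step-up FDR adjustment, one family per
   trait x analysis mode; associations with adjusted p below the level
   (default 0.05) are flagged *tentative signals*.
2. Within each trait and lifestyle category, tentative signals are
   rank-ordered by variance explained and the top k (default 5) kept,
   after collapsing dummy levels to their parent variable.
3. Variables top-ranked for at least ``min_traits`` traits (default 5 of
   9) and flagged modifiable are prioritized as intervention targets.
4. Prioritized variables are clustered by average-linkage hierarchical
   clustering on one minus their pairwise correlation, yielding target
   groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import schema


class DiscoveryError(ValueError):
    pass


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adjusted_(i) = min_{j >= i} m * p_(j) / j`` over the sorted
    sequence, capped at 1.  Missing entries are excluded from the family
    size ``m`` and stay missing in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    obs = ~np.isnan(p)
    v = p[obs]
    if ((v < 0) | (v > 1)).any():
        raise DiscoveryError("p-values must lie in [0, 1]")
    m = v.size
    if m == 0:
        return out
    order = np.argsort(v, kind="stable")
    ranked = v[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[obs] = result
    return out


def call_signals(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag tentative signals at FDR < alpha, one family per trait x mode.

    Adds ``p_fdr``, ``tentative`` and ``family_size`` columns.  Rows
    whose model failed (missing p) keep a missing adjusted p and are
    never flagged.
    """
    out = results.copy()
    if out.empty:
        for col in ("p_fdr", "tentative", "family_size"):
            out[col] = pd.Series(dtype=float)
        return out
    out["p_fdr"] = np.nan
    out["family_size"] = 0
    for (_trait, _mode), idx in out.groupby(["trait", "mode"]).groups.items():
        sub = out.loc[idx, "p"]
        out.loc[idx, "p_fdr"] = bh_adjust(sub.to_numpy(dtype=float))
        out.loc[idx, "family_size"] = int(sub.notna().sum())
    out["tentative"] = out["p_fdr"] < alpha
    out["tentative"] = out["tentative"].fillna(False)
    return out


def rank_and_select(signals: pd.DataFrame, top_k: int = 5) -> pd.DataFrame:
    """Top-k tentative signals per trait x category by variance explained.

    Dummy-level rows are first collapsed to their parent variable,
    keeping the row with the largest variance explained.  Ties are
    broken by smaller raw p, then lexicographic variable name.  Returns
    the retained rows with a ``rank`` column (1 = best).
    """
    sig = signals[signals["tentative"].astype(bool)].copy()
    if sig.empty:
        return sig.assign(rank=pd.Series(dtype=int))
    # Collapse dummies: best row per (trait, mode, category, parent).
    sig = sig.sort_values(
        ["var_explained", "p", "parent_variable"],
        ascending=[False, True, True],
        kind="stable",
    )
    sig = sig.drop_duplicates(["trait", "mode", "category", "parent_variable"], keep="first")
    sig["rank"] = (
        sig.groupby(["trait", "mode", "category"], sort=False).cumcount() + 1
    )
    return sig[sig["rank"] <= top_k].reset_index(drop=True)


@dataclass
class PriorityReport:
    """Prioritization outcome: candidates, exclusions and clusters."""

    top_sets: pd.DataFrame
    #: variable -> number of distinct traits whose top sets contain it.
    trait_counts: pd.Series
    #: candidates meeting the trait threshold, before modifiability filter.
    candidates: list[str]
    #: candidates excluded with reasons (e.g. non-modifiable).
    excluded: dict[str, str]
    prioritized: list[str]
    cluster_labels: pd.Series | None = None
    linkage: np.ndarray | None = None
    leaf_order: list[str] = field(default_factory=list)
    correlation: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        return {
            "trait_counts": {k: int(v) for k, v in self.trait_counts.items()},
            "candidates": self.candidates,
            "excluded": self.excluded,
            "prioritized": self.prioritized,
            "clusters": (
                {k: int(v) for k, v in self.cluster_labels.items()}
                if self.cluster_labels is not None
                else {}
            ),
            "leaf_order": self.leaf_order,
        }


def prioritize(
    top_sets: pd.DataFrame,
    catalog: pd.DataFrame,
    min_traits: int = 5,
) -> PriorityReport:
    """Select modifiable variables top-ranked for at least ``min_traits`` traits.

    A variable qualifies when it appears in the per-category top sets of
    at least ``min_traits`` distinct traits; non-modifiable qualifiers
    are retained in the report with their exclusion reason.  Invariant to
    trait ordering and input row order.
    """
    modifiable = dict(zip(catalog["exposure"], catalog["modifiable"].astype(bool)))
    if top_sets.empty:
        return PriorityReport(
            top_sets=top_sets,
            trait_counts=pd.Series(dtype=int),
            candidates=[],
            excluded={},
            prioritized=[],
        )
    counts = (
        top_sets.groupby("parent_variable")["trait"].nunique().sort_index()
    )
    candidates = sorted(counts.index[counts >= min_traits])
    excluded = {}
    prioritized = []
    for var in candidates:
        if not modifiable.get(var, False):
            excluded[var] = "non-modifiable"
        else:
            prioritized.append(var)
    return PriorityReport(
        top_sets=top_sets,
        trait_counts=counts,
        candidates=candidates,
        excluded=excluded,
        prioritized=prioritized,
    )


def correlation_matrix(
    clean: pd.DataFrame, variables: list[str], min_obs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with a missing mask.

    Pairs with fewer than ``min_obs`` complete observations or zero
    variance on the complete subset are left missing (the mask).  The
    result is symmetric with a unit diagonal wherever the variable has
    any variance.
    """
    if len(variables) < 2:
        raise DiscoveryError("correlation_matrix needs at least 2 variables")
    k = len(variables)
    corr = pd.DataFrame(np.nan, index=variables, columns=variables)
    data = {v: clean[v].to_numpy(dtype=float) for v in variables}
    for i, a in enumerate(variables):
        for b in variables[i:]:
            x, y = data[a], data[b]
            obs = ~np.isnan(x) & ~np.isnan(y)
            if obs.sum() < min_obs:
                continue
            xs, ys = x[obs], y[obs]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                continue
            r = float(np.corrcoef(xs, ys)[0, 1])
            corr.loc[a, b] = r
            corr.loc[b, a] = r
    return corr


def hcluster(
    corr: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
    method: str = "average",
) -> tuple[np.ndarray, list[str], pd.Series]:
    """Average-linkage clustering on one minus the correlation matrix.

    Masked (missing) pairs are imputed with the mean distance of the
    unmasked off-diagonal pairs before linkage.  Returns the scipy
    linkage matrix, the dendrogram leaf order and flat cluster labels
    (cut at ``n_clusters`` or ``height``; default is 1 cluster).
    """
    names = list(corr.index)
    if len(names) < 2:
        raise DiscoveryError("hcluster needs at least 2 variables")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    off = dist[~np.eye(len(names), dtype=bool)]
    if np.isnan(off).all():
        raise DiscoveryError("no computable correlations to cluster")
    fill = float(np.nanmean(off))
    dist = np.where(np.isnan(dist), fill, dist)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    leaves = hierarchy.leaves_list(Z)
    leaf_order = [names[i] for i in leaves]
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    elif height is not None:
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        labels = np.ones(len(names), dtype=int)
    return Z, leaf_order, pd.Series(labels, index=names)


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = len(names)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: names[i] for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(0.0, h - heights[a])
        lb = max(0.0, h - heights[b])
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"
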