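"""Diagnostic plots: Manhattan-style p-value panels and correlation heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan_plot(signals: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> None:
    """-log10 p per exposure, grouped by category, one panel per trait."""
    ok = signals[signals["status"] == "ok"].copy()
    if ok.empty:
        return
    traits = sorted(ok["trait"].unique())
    fig, axes = plt.subplots(
        len(traits), 1, figsize=(10, 2.2 * len(traits)), squeeze=False, sharex=True
    )
    cats = sorted(ok["category"].unique())
    colors = plt.cm.tab10(np.linspace(0, 1, len(cats)))
    for ax, trait in zip(axes[:, 0], traits):
        sub = ok[ok["trait"] == trait].sort_values(["category", "exposure"])
        x = np.arange(len(sub))
        for cat, col in zip(cats, colors):
            m = (sub["category"] == cat).to_numpy()
            ax.scatter(x[m], -np.log10(sub["p"].to_numpy()[m].clip(1e-300)), s=8, color=col, label=cat)
        flagged = sub["tentative"].astype(bool).to_numpy()
        ax.scatter(x[flagged], -np.log10(sub["p"].to_numpy()[flagged].clip(1e-300)),
                   s=14, facecolors="none", edgecolors="black", linewidths=0.5)
        ax.set_ylabel(f"{trait}\n-log10 p", fontsize=8)
    axes[0, 0].legend(fontsize=6, ncol=5, loc="upper right")
    axes[-1, 0].set_xlabel("exposure (grouped by category)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def correlation_heatmap(
    corr: pd.DataFrame, path: str | Path, leaf_order: list[str] | None = None
) -> None:
    """Correlation heatmap, optionally reordered by dendrogram leaves."""
    mat = corr.loc[leaf_order, leaf_order] if leaf_order else corr
    fig, ax = plt.subplots(figsize=(6, 5))
    # Masked (uncomputable) pairs render white.
    im = ax.imshow(mat.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(mat)), mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
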