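"""Plotting helpers: MA plot of differential binding and the motif-rank
dot plot of association scores."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

_CLASS_COLORS = {"unchanged": "0.7", "enriched_KO": "tab:orange",
                 "enriched_WT": "tab:blue"}


def ma_plot(ma: pd.DataFrame, path=None, ax=None):
    """Scatter of M_norm against A colored by enrichment class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for cls, grp in ma.groupby("class"):
        ax.scatter(grp["A"], grp["M_norm"], s=4, alpha=0.6,
                   color=_CLASS_COLORS.get(cls, "k"), label=cls)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("A (average log2 amplitude)")
    ax.set_ylabel("M (normalized log2 KO/WT)")
    ax.legend(markerscale=3, fontsize=7)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def motif_rank_dotplot(ranking: pd.DataFrame, highlight=(), path=None, ax=None):
    """Motif association scores (Spearman rho) by rank, selected motifs labeled."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ranking["rank"], ranking["rho"], s=10, color="0.5")
    for _, row in ranking[ranking["motif_id"].isin(highlight)].iterrows():
        ax.scatter(row["rank"], row["rho"], s=25, color="tab:red")
        ax.annotate(row["motif_id"], (row["rank"], row["rho"]), fontsize=7,
                    xytext=(4, 4), textcoords="offset points")
    ax.set_xlabel("motif rank")
    ax.set_ylabel("Spearman rho (score vs M)")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
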