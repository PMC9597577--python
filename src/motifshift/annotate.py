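"""Peak-to-gene annotation by nearest transcription start site.

Each peak is anchored at its midpoint and assigned to the gene with the
nearest TSS on the same chromosome. The signed distance (positive =
downstream with respect to the gene's strand) is categorized as promoter
(|d| <= 2 kb), enhancer (2 kb < |d| <= 20 kb) or other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROMOTER_BP = 2000
ENHANCER_BP = 20000


def categorize_distance(distance, promoter_bp: int = PROMOTER_BP,
                        enhancer_bp: int = ENHANCER_BP):
    """promoter if |d| <= 2000, enhancer if 2000 < |d| <= 20000, else other.

    Both boundaries are inclusive on the proximal side. Vectorized.
    """
    d = np.abs(np.asarray(distance))
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    cat = np.select([d <= promoter_bp, d <= enhancer_bp],
                    ["promoter", "enhancer"], default="other")
    return cat if np.ndim(distance) else str(cat)


def nearest_tss(peaks: pd.DataFrame, genes: pd.DataFrame,
                promoter_bp: int = PROMOTER_BP,
                enhancer_bp: int = ENHANCER_BP) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS.

    The anchor is the peak midpoint (integer floor of (start+end)/2);
    distance ties go to the smaller gene id. Peaks on chromosomes without
    genes are reported with gene_id NA and excluded downstream (a warning
    is logged). Returns (peak_id, gene_id, distance, category).
    """
    rows = []
    # sort genes so searchsorted works and ties resolve to the smaller id
    unassigned = 0
    for chrom, grp in peaks.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom].sort_values(["tss", "gene_id"])
        anchors = ((grp["start"] + grp["end"]) // 2).to_numpy()
        if g.empty:
            unassigned += len(grp)
            for pid in grp["peak_id"]:
                rows.append((pid, None, np.nan, None))
            continue
        tss = g["tss"].to_numpy()
        ids = g["gene_id"].to_numpy()
        strands = g["strand"].to_numpy()
        idx = np.searchsorted(tss, anchors)
        for pid, anchor, i in zip(grp["peak_id"], anchors, idx):
            cand = [j for j in (i - 1, i) if 0 <= j < len(tss)]
            dists = [abs(int(anchor) - int(tss[j])) for j in cand]
            best_d = min(dists)
            # among equidistant TSSs (incl. duplicated coordinates) pick the
            # smallest gene id
            ties = [j for j in range(len(tss))
                    if abs(int(anchor) - int(tss[j])) == best_d] \
                if dists.count(best_d) > 1 else [cand[int(np.argmin(dists))]]
            j = min(ties, key=lambda j: ids[j])
            signed = (int(anchor) - int(tss[j]) if strands[j] == "+"
                      else int(tss[j]) - int(anchor))
            rows.append((pid, ids[j], signed,
                         categorize_distance(signed, promoter_bp, enhancer_bp)))
    if unassigned:
        logger.warning("%d peaks on chromosomes without genes left unassigned",
                       unassigned)
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance", "category"])


def genes_bound_within(links: pd.DataFrame, max_distance: int = ENHANCER_BP
                       ) -> pd.DataFrame:
    """Per-gene bound flag: >= 1 assigned peak with |distance| <= max_distance.

    Returns (gene_id, bound, peak_ids) with deduplicated peak lists.
    """
    assigned = links.dropna(subset=["gene_id"])
    near = assigned[assigned["distance"].abs() <= max_distance]
    lists = near.groupby("gene_id")["peak_id"].agg(
        lambda s: tuple(dict.fromkeys(s)))
    all_genes = assigned["gene_id"].unique()
    out = pd.DataFrame({"gene_id": all_genes})
    out["peak_ids"] = out["gene_id"].map(lists).apply(
        lambda v: v if isinstance(v, tuple) else ())
    out["bound"] = out["peak_ids"].apply(lambda v: len(v) > 0)
    return out[["gene_id", "bound", "peak_ids"]]
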