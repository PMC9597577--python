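"""Motif-binding association statistics.

The headline analysis: every motif's per-peak top-hit score is rank-
correlated (Spearman) with the normalized binding shift M, and motifs are
ranked by the correlation. Supporting analyses stratify condition-enriched
peaks by p63 motif-score quintiles (reporting AP1 presence fractions per
stratum) and quantify enrichment of differential expression within gene
subcategories by odds ratio and Pearson chi-squared on 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks; average ranks for
    ties). Constant input is undefined and returned as NaN with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def rank_motifs(ma: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Rank all motifs by Spearman correlation of top-hit score with M.

    ``ma`` carries peak_id and M_norm; ``scores`` is a peaks x motifs table
    of top-hit scores (index peak_id). Every motif must have one score per
    peak. Returns (motif_id, rho, n_peaks, rank) with rank 1 = most positive
    rho; rho ties break by motif id.
    """
    missing = set(ma["peak_id"]) - set(scores.index)
    if missing:
        raise ValueError(f"missing motif scores for peaks: {sorted(missing)[:5]}")
    aligned = scores.loc[ma["peak_id"]]
    m = ma["M_norm"].to_numpy()
    rows = [(motif, spearman_rho(m, aligned[motif].to_numpy()), len(m))
            for motif in aligned.columns]
    out = pd.DataFrame(rows, columns=["motif_id", "rho", "n_peaks"])
    out = out.sort_values(["rho", "motif_id"], ascending=[False, True],
                          ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass(frozen=True)
class StratumSummary:
    """One motif-score quintile of the condition-enriched peaks."""

    stratum: int                 # 1 = bottom (weakest motif scores)
    n_enriched_ko: int
    n_enriched_wt: int
    frac_ko_with_ap1: float      # 0.0 when the stratum holds no such peaks
    frac_wt_with_ap1: float


def quintile_stratify(p63_scores: pd.Series, ap1_present: pd.Series,
                      classes: pd.Series) -> list[StratumSummary]:
    """Stratify peaks into p63-motif-score quintiles; per quintile report the
    AP1-motif presence fraction among enriched_KO and enriched_WT peaks.

    Quintile boundaries are the 20/40/60/80th percentiles of the score
    distribution over the analyzed peaks (union of all classes); scores tied
    with a boundary fall in the lower stratum. Fractions over an empty class
    within a stratum are reported as 0.0.
    """
    if len(p63_scores) < 5:
        raise ValueError("need at least 5 peaks to form quintiles")
    df = pd.DataFrame({"score": p63_scores, "ap1": ap1_present, "cls": classes})
    bounds = np.quantile(df["score"].to_numpy(), [0.2, 0.4, 0.6, 0.8])
    df["stratum"] = 1 + (df["score"].to_numpy()[:, None] > bounds[None, :]).sum(axis=1)
    out = []
    for q in range(1, 6):
        sub = df[df["stratum"] == q]
        ko = sub[sub["cls"] == "enriched_KO"]
        wt = sub[sub["cls"] == "enriched_WT"]
        out.append(StratumSummary(
            q, len(ko), len(wt),
            float(ko["ap1"].mean()) if len(ko) else 0.0,
            float(wt["ap1"].mean()) if len(wt) else 0.0))
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 enrichment of up_KO genes within a subcategory vs its complement."""

    subcategory: str
    a: int  # in subcategory, up_KO
    b: int  # in subcategory, not up_KO
    c: int  # not in subcategory, up_KO
    d: int  # not in subcategory, not up_KO
    odds_ratio: float
    chi2: float
    p_value: float


def _table_test(name: str, a: int, b: int, c: int, d: int) -> EnrichmentResult:
    cells = np.array([[a, b], [c, d]], dtype=float)
    if np.any(cells < 0):
        raise ValueError("negative cell count")
    # Haldane-Anscombe 0.5 correction only when a cell is zero
    or_cells = cells + 0.5 if (cells == 0).any() else cells
    odds = (or_cells[0, 0] * or_cells[1, 1]) / (or_cells[0, 1] * or_cells[1, 0])
    if cells.sum(axis=0).min() == 0 or cells.sum(axis=1).min() == 0:
        chi2, p = 0.0, 1.0  # degenerate margin: no evidence of association
    else:
        chi2, p = stats.chi2_contingency(cells, correction=False)[:2]
    return EnrichmentResult(name, a, b, c, d, float(odds), float(chi2), float(p))


def subcategory_enrichment(subcategory: set[str], gene_classes: pd.Series,
                           reference: set[str], name: str = "subcategory",
                           direction: str = "up_KO") -> EnrichmentResult:
    """Odds ratio and Pearson chi-squared (1 df, no continuity correction)
    for ``direction`` genes inside a subcategory versus its complement
    within the reference set.

    The subcategory must be a subset of the reference (genes passing the
    expression filter and annotation requirements); comparing subset vs
    complement is the standard non-degenerate contingency construction.
    """
    if not subcategory or not reference:
        raise ValueError("empty subcategory or reference set")
    if not subcategory <= reference:
        raise ValueError("subcategory must be a subset of the reference set")
    cls = gene_classes.reindex(sorted(reference))
    in_sub = cls.index.isin(subcategory)
    up = (cls == direction).to_numpy()
    a = int((in_sub & up).sum())
    b = int((in_sub & ~up).sum())
    c = int((~in_sub & up).sum())
    d = int((~in_sub & ~up).sum())
    return _table_test(name, a, b, c, d)


def locus_set_enrichment(gene_set: set[str], gene_classes: pd.Series,
                         reference: set[str], name: str = "locus_set",
                         direction: str = "up_KO") -> EnrichmentResult:
    """Enrichment of differential expression in an arbitrary named gene set
    (e.g. a clustered co-regulated locus); same machinery as
    ``subcategory_enrichment``."""
    return subcategory_enrichment(gene_set, gene_classes, reference,
                                  name=name, direction=direction)
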