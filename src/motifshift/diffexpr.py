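"""Negative-binomial two-condition differential expression.

A lightweight, deterministic stand-in for a full shrinkage-based DE fit:
median-of-ratios size factors, method-of-moments gene dispersions shrunk
toward a mean-dispersion trend, and a Wald-type test on the log2 fold
change (KO vs WT) with BH adjustment. Genes are classified up_KO / up_WT /
unchanged at adjusted p < alpha (default 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import bh_adjust

DISPERSION_FLOOR = 1e-8


def low_count_filter(counts: pd.DataFrame, min_total: int = 10) -> pd.Series:
    """True for genes whose total count across all samples >= min_total."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    return counts.sum(axis=1) >= min_total


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scaling factors, rescaled to geometric
    mean 1 so they are invariant to a common depth change.

    Only genes with positive counts in every sample enter the reference
    geometric mean.
    """
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in every sample")
    geo = np.exp(np.log(positive).mean(axis=1))
    factors = positive.div(geo, axis=0).median(axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors.to_numpy(), index=counts.columns, name="size_factor")


def _check_design(counts: pd.DataFrame, condition: pd.Series) -> None:
    condition = condition.reindex(counts.columns)
    if condition.isna().any():
        raise ValueError("condition labels must cover all samples")
    levels = set(condition)
    if levels != {"WT", "KO"}:
        raise ValueError(f"conditions must be WT and KO, got {sorted(levels)}")
    for lvl in ("WT", "KO"):
        if (condition == lvl).sum() < 2:
            raise ValueError(f"condition {lvl} has fewer than 2 replicates")


def _center_batches(norm: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Per-batch centering of log counts (batch means removed, grand mean
    restored), a documented simplification of a batch-covariate design."""
    log = np.log2(norm + 0.5)
    grand = log.mean(axis=1)
    adjusted = log.copy()
    for b in batch.unique():
        cols = batch.index[batch == b]
        adjusted[cols] = log[cols].sub(log[cols].mean(axis=1), axis=0).add(grand, axis=0)
    return 2.0 ** adjusted - 0.5


def estimate_dispersions(norm: pd.DataFrame, condition: pd.Series,
                         shrink_weight: float = 0.25) -> pd.Series:
    """Gene-wise NB dispersion alpha (var = mu + alpha*mu^2).

    Method-of-moments estimates pooled across the two conditions are shrunk
    toward a trend fitted by regressing the raw estimates on 1/mean; the
    trend absorbs most of the small-replicate noise (shrink_weight is the
    weight left on the gene-wise estimate).
    """
    mu = norm.mean(axis=1)
    ss = np.zeros(len(norm))
    df = 0
    for lvl in ("WT", "KO"):
        cols = condition.index[condition == lvl]
        sub = norm[cols]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1).to_numpy()
        df += len(cols) - 1
    var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu) / mu ** 2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.clip(raw, 0.0, None)
    # trend alpha(mu) = a + b/mu on genes with informative estimates
    x = 1.0 / np.clip(mu.to_numpy(), 1e-8, None)
    usable = mu.to_numpy() > 0
    if usable.sum() >= 2:
        coef = np.polyfit(x[usable], raw[usable], deg=1)  # raw ~ b/mu + a
        trend = np.clip(coef[1] + coef[0] * x, DISPERSION_FLOOR, None)
    else:
        trend = np.full(len(norm), max(np.median(raw), DISPERSION_FLOOR))
    alpha = shrink_weight * raw + (1.0 - shrink_weight) * trend
    return pd.Series(np.clip(alpha, DISPERSION_FLOOR, None), index=norm.index,
                     name="dispersion")


def de_test(counts: pd.DataFrame, condition: pd.Series,
            batch: pd.Series | None = None, alpha: float = 0.05,
            min_total: int = 10, lfc_pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene differential expression table (KO vs WT).

    Returns columns gene_id, baseMean, log2FC, p_value, adjusted_p, class,
    passes_filter. Genes failing the low-count filter keep NaN statistics
    and class 'unchanged'; BH adjustment runs across tested genes only.
    """
    _check_design(counts, condition)
    condition = condition.reindex(counts.columns)
    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    if batch is not None:
        norm = _center_batches(norm, batch.reindex(counts.columns))

    passes = low_count_filter(counts, min_total)
    tested = norm[passes]
    wt_cols = condition.index[condition == "WT"]
    ko_cols = condition.index[condition == "KO"]
    mu_wt = tested[wt_cols].mean(axis=1)
    mu_ko = tested[ko_cols].mean(axis=1)
    disp = estimate_dispersions(tested, condition)

    c = lfc_pseudocount
    lfc = np.log2(mu_ko + c) - np.log2(mu_wt + c)
    # delta-method variance of log2 of a mean of NB samples
    ln2sq = np.log(2.0) ** 2
    var_wt = (mu_wt + disp * mu_wt ** 2) / len(wt_cols) / ((mu_wt + c) ** 2 * ln2sq)
    var_ko = (mu_ko + disp * mu_ko ** 2) / len(ko_cols) / ((mu_ko + c) ** 2 * ln2sq)
    se = np.sqrt(var_wt + var_ko)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    # normal reference: the trend-shrunk dispersions are stable enough that a
    # small-sample t correction overshoots into strong conservatism
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame({
        "gene_id": counts.index,
        "baseMean": norm.mean(axis=1),
        "log2FC": np.nan, "p_value": np.nan, "adjusted_p": np.nan,
        "passes_filter": passes.to_numpy()}).set_index("gene_id", drop=False)
    out.loc[tested.index, "log2FC"] = lfc
    out.loc[tested.index, "p_value"] = p
    out.loc[tested.index, "adjusted_p"] = bh_adjust(p)
    return classify_genes(out, alpha).reset_index(drop=True)


def classify_genes(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """up_KO if adjusted_p < alpha and log2FC > 0; up_WT if < alpha and
    log2FC < 0; else unchanged (including untested genes)."""
    if "adjusted_p" not in de:
        raise ValueError("missing adjusted_p")
    out = de.copy()
    sig = out["adjusted_p"] < alpha
    out["class"] = np.select(
        [sig & (out["log2FC"] > 0), sig & (out["log2FC"] < 0)],
        ["up_KO", "up_WT"], default="unchanged")
    return out


def gene_class_counts(de: pd.DataFrame) -> dict[str, int]:
    counts = de["class"].value_counts()
    return {k: int(counts.get(k, 0)) for k in ("up_KO", "up_WT", "unchanged")}
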