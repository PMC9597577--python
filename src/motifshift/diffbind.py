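"""MA-style differential ChIP-seq binding between two conditions.

Each peak carries raw counts in the two conditions (WT as reference, KO as
test). We compute the log2 fold-change M and average amplitude A, rescale M
by a robust line fitted on "common" peaks (those unlikely to differ between
conditions), assign a per-peak significance from a symmetric count-comparison
statistic, and classify peaks as enriched in KO, enriched in WT, or
unchanged at a p-value threshold (default 5e-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class NormalizationFit:
    """Robust line M = intercept + slope * A fitted on common peaks."""

    intercept: float
    slope: float
    common_peak_ids: tuple[str, ...]
    method: str = "theil-sen"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("non-finite normalization coefficients")
        if len(self.common_peak_ids) < 2:
            raise ValueError("need at least 2 common peaks")


def compute_ma(x_wt, x_ko, pseudocount: float = 1.0):
    """M = log2(ko+c) - log2(wt+c); A = mean of the two log2 terms.

    Vectorized over array inputs; the pseudocount keeps both finite at zero
    counts.
    """
    x_wt = np.asarray(x_wt, dtype=float)
    x_ko = np.asarray(x_ko, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if np.any(x_wt < 0) or np.any(x_ko < 0):
        raise ValueError("counts must be non-negative")
    lw, lk = np.log2(x_wt + pseudocount), np.log2(x_ko + pseudocount)
    return lk - lw, 0.5 * (lk + lw)


def select_common_peaks(ma: pd.DataFrame, quantile: float = 0.5) -> pd.Series:
    """Boolean mask of normalization-fit peaks: raw |M| below the given
    quantile of |M| (a proxy for peaks shared by both conditions)."""
    abs_m = ma["M_raw"].abs()
    return abs_m < abs_m.quantile(quantile)


def fit_normalization(ma_common: pd.DataFrame) -> NormalizationFit:
    """Theil-Sen line through the common peaks' (A, M_raw) cloud.

    Deterministic median-of-pairwise-slopes with median-residual intercept;
    resistant to the minority of genuinely changed peaks that leak into the
    common set.
    """
    if len(ma_common) < 2:
        raise ValueError("need at least 2 common peaks to fit normalization")
    a = ma_common["A"].to_numpy(dtype=float)
    m = ma_common["M_raw"].to_numpy(dtype=float)
    if np.all(a == a[0]):
        raise ValueError("all common-peak A values identical; line is undefined")
    res = stats.theilslopes(m, a, method="joint")
    return NormalizationFit(float(res.intercept), float(res.slope),
                            tuple(ma_common["peak_id"]))


def apply_normalization(ma: pd.DataFrame, fit: NormalizationFit) -> pd.DataFrame:
    out = ma.copy()
    out["M_norm"] = out["M_raw"] - (fit.intercept + fit.slope * out["A"])
    return out


def binding_significance(x_wt, x_ko):
    """Two-sided p-value of count imbalance under the symmetric Poisson-mixture
    count model P(y|x) = (x+y)! / (x! y! 2^(x+y+1)).

    P(y|x) is the negative-binomial pmf NB(r = x+1, p = 1/2), so the
    one-sided tail P(Y >= max | min) is an exact scipy survival function;
    it is doubled and capped at 1. Using max/min makes the statistic exactly
    symmetric in the two conditions.
    """
    x = np.asarray(x_wt)
    y = np.asarray(x_ko)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    lo = np.minimum(x, y)
    hi = np.maximum(x, y)
    tail = stats.nbinom.sf(hi - 1, lo + 1, 0.5)
    return np.minimum(1.0, 2.0 * tail)


def ac_term(y: int, x: int) -> float:
    """Single outcome probability P(y|x) = (x+y)! / (x! y! 2^(x+y+1))."""
    return float(stats.nbinom.pmf(y, x + 1, 0.5))


def classify_peaks(ma: pd.DataFrame, threshold: float = 5e-3) -> pd.DataFrame:
    """Assign enriched_KO / enriched_WT / unchanged per peak.

    enriched_KO: p < threshold and M_norm > 0; enriched_WT: p < threshold and
    M_norm < 0; everything else unchanged. The three classes partition the
    peak set.
    """
    for col in ("p_value", "M_norm"):
        if col not in ma or ma[col].isna().any():
            raise ValueError(f"missing {col}")
    out = ma.copy()
    sig = out["p_value"] < threshold
    out["class"] = np.select(
        [sig & (out["M_norm"] > 0), sig & (out["M_norm"] < 0)],
        ["enriched_KO", "enriched_WT"], default="unchanged")
    return out


def class_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = classified["class"].value_counts()
    return {k: int(counts.get(k, 0))
            for k in ("enriched_KO", "enriched_WT", "unchanged")}


def filter_excluded_regions(peaks: pd.DataFrame,
                            exclusions: pd.DataFrame) -> pd.DataFrame:
    """Drop peaks overlapping any exclusion interval by >= 1 bp.

    Intervals are 0-based half-open; input order is preserved. ``exclusions``
    needs columns chrom/start/end.
    """
    if len(exclusions):
        bad = exclusions["start"] >= exclusions["end"]
        if bad.any():
            raise ValueError("malformed exclusion interval (start >= end)")
    if not len(peaks) or not len(exclusions):
        return peaks.copy()
    drop = np.zeros(len(peaks), dtype=bool)
    for chrom, excl in exclusions.groupby("chrom"):
        sel = (peaks["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        ps = peaks.loc[sel, "start"].to_numpy()[:, None]
        pe = peaks.loc[sel, "end"].to_numpy()[:, None]
        es = excl["start"].to_numpy()[None, :]
        ee = excl["end"].to_numpy()[None, :]
        drop[np.flatnonzero(sel)] = ((ps < ee) & (es < pe)).any(axis=1)
    return peaks.loc[~drop].copy()


def differential_binding(counts: pd.DataFrame, pseudocount: float = 1.0,
                         threshold: float = 5e-3,
                         common_quantile: float = 0.5
                         ) -> tuple[pd.DataFrame, NormalizationFit]:
    """Full MA stage: M/A, robust normalization, significance, classes.

    ``counts`` has columns peak_id/count_wt/count_ko; returns the per-peak
    table (peak_id, count_wt, count_ko, A, M_raw, M_norm, p_value, class)
    plus the normalization fit.
    """
    ma = counts.copy()
    m_raw, a = compute_ma(ma["count_wt"], ma["count_ko"], pseudocount)
    ma["M_raw"], ma["A"] = m_raw, a
    fit = fit_normalization(ma[select_common_peaks(ma, common_quantile)])
    ma = apply_normalization(ma, fit)
    ma["p_value"] = binding_significance(ma["count_wt"], ma["count_ko"])
    return classify_peaks(ma, threshold), fit
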