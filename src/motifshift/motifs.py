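"""PWM construction, best-hit scanning, and score p-values.

A transcription-factor motif enters as a position frequency matrix (PFM,
counts over A/C/G/T per column) and is converted to a log-odds position
weight matrix (PWM, log2 relative to a background letter distribution).
Each peak sequence is scanned on both strands for its single best-scoring
window ("top hit"); the window score is converted to a p-value by exact
dynamic programming over the discretized per-column score distribution
under the background model, and presence/absence of the motif in each peak
is called by Benjamini-Hochberg FDR across peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from statsmodels.stats.multitest import multipletests

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> code lookup; anything unrecognised scores like N (code 4)
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, N/other=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PFMotif:
    """Position frequency matrix: 4 rows (A,C,G,T) x width columns of counts."""

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: counts must be 4 x width with width >= 1")
        if np.any(counts < 0):
            raise ValueError(f"{self.motif_id}: negative counts")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError(f"{self.motif_id}: every column must have positive sum")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in np.argmax(self.counts, axis=0))

    def column_probabilities(self) -> np.ndarray:
        """Per-column letter probabilities (counts normalized columnwise)."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class PWMatrix:
    """Log-odds motif model: 4 x width matrix in log2 units plus its background."""

    motif_id: str
    logodds: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        lo = np.asarray(self.logodds, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive probabilities summing to 1")
        if not np.all(np.isfinite(lo)):
            raise ValueError(
                f"{self.motif_id}: non-finite log-odds; use a positive pseudocount "
                "when the count matrix has zero cells"
            )
        object.__setattr__(self, "logodds", lo)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.logodds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=0).sum())

    def reverse_complement(self) -> "PWMatrix":
        # complementing letters reverses the A,C,G,T row order; then reverse columns
        return PWMatrix(self.motif_id, self.logodds[::-1, ::-1],
                        self.background, self.pseudocount)


@dataclass
class MotifHit:
    """Best match of one motif in one peak sequence."""

    peak_id: str
    motif_id: str
    score: float
    start: int
    strand: str
    p_value: float | None = None
    q_value: float | None = None
    present: bool | None = None


UNIFORM_BACKGROUND = np.full(4, 0.25)


def build_pwm(pfm: PFMotif, background: Sequence[float] | None = None,
              pseudocount: float = 0.1) -> PWMatrix:
    """Log-odds PWM: entry[b][j] = log2((count[b][j] + pc*bg[b]) / (colsum[j] + pc) / bg[b]).

    The pseudocount is distributed across letters proportionally to the
    background; it must be positive whenever the count matrix has zero cells
    (otherwise the log-odds would be -inf, which is rejected).
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    bg = bg / bg.sum()
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and np.any(pfm.counts == 0):
        raise ValueError(
            f"{pfm.motif_id}: zero counts require a positive pseudocount")
    colsum = pfm.counts.sum(axis=0, keepdims=True)
    prob = (pfm.counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    return PWMatrix(pfm.motif_id, np.log2(prob / bg[:, None]), bg, pseudocount)


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """Order-0 background letter frequencies over a set of sequences (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no A/C/G/T letters in the input sequences")
    # guard against absent letters so log-odds stay finite
    counts = counts + 1.0
    return counts / counts.sum()


def _window_scores(logodds: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Scores of every window of an encoded sequence; windows with N are -inf."""
    w = logodds.shape[1]
    lut = np.vstack([logodds, np.full(w, -np.inf)])  # row 4 = N
    windows = sliding_window_view(encoded, w)
    return lut[windows, np.arange(w)].sum(axis=1)


def best_hit(pwm: PWMatrix, sequence: str, scan_both_strands: bool = True,
             peak_id: str = "") -> MotifHit:
    """Highest-scoring motif window in a sequence.

    Ties are broken by smallest start offset, then by '+' strand. Windows
    containing N (or any non-ACGT letter) are skipped.
    """
    if len(sequence) < pwm.width:
        raise ValueError(
            f"sequence length {len(sequence)} < motif width {pwm.width}")
    enc = encode_sequence(sequence)
    fwd = _window_scores(pwm.logodds, enc)
    if scan_both_strands:
        rev = _window_scores(pwm.reverse_complement().logodds, enc)
    else:
        rev = np.full_like(fwd, -np.inf)
    best = max(fwd.max(), rev.max())
    if not np.isfinite(best):
        raise ValueError("no scorable window (all windows contain N)")
    # smallest offset wins; at equal offset '+' wins
    fwd_idx = np.flatnonzero(fwd == best)
    rev_idx = np.flatnonzero(rev == best)
    start_f = fwd_idx[0] if fwd_idx.size else len(enc)
    start_r = rev_idx[0] if rev_idx.size else len(enc)
    if start_f <= start_r:
        return MotifHit(peak_id, pwm.motif_id, float(best), int(start_f), "+")
    return MotifHit(peak_id, pwm.motif_id, float(best), int(start_r), "-")


class ScoreDistribution:
    """Exact distribution of the single-window PWM score under the background.

    Column scores are discretized to ``granularity`` log2 units and the pmf of
    their sum is built by dynamic programming (one convolution per column).
    The survival function carries a rounding guard of half a bin per column,
    so the returned p-value can overstate the exact tail only by the mass
    within ~``width * granularity`` of the threshold and never understates it.
    """

    def __init__(self, pwm: PWMatrix, granularity: float = 1e-3):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        self.granularity = float(granularity)
        self.width = pwm.width
        ints = np.rint(pwm.logodds / granularity).astype(np.int64)
        offsets = ints.min(axis=0)
        spans = (ints.max(axis=0) - offsets).astype(int)
        pmf = np.ones(1)
        for j in range(pwm.width):
            new = np.zeros(len(pmf) + spans[j])
            for b in range(4):
                shift = int(ints[b, j] - offsets[j])
                new[shift:shift + len(pmf)] += pwm.background[b] * pmf
            pmf = new
        self.pmf = pmf
        self.min_int = int(offsets.sum())
        self._sf = np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)
        self._guard = self.width // 2 + 1

    def sf(self, score: float) -> float:
        """P(window score >= score); 1 at or below the minimum attainable score."""
        if not np.isfinite(score):
            raise ValueError("score must be finite")
        t = int(np.rint(score / self.granularity)) - self.min_int - self._guard
        if t <= 0:
            return 1.0
        if t >= len(self.pmf):
            return 0.0
        return float(self._sf[t])


_DIST_CACHE: dict[tuple[int, float], ScoreDistribution] = {}


def score_pvalue(pwm: PWMatrix, score: float, granularity: float = 1e-3) -> float:
    """Single-window p-value P(score' >= score) under the PWM's background."""
    key = (id(pwm), granularity)
    dist = _DIST_CACHE.get(key)
    if dist is None:
        dist = _DIST_CACHE[key] = ScoreDistribution(pwm, granularity)
    return dist.sf(score)


def best_hit_pvalue(window_pvalue: float, n_windows: int) -> float:
    """p-value of the best of ``n_windows`` scanned windows.

    Sidak length correction 1 - (1 - p)^n under window independence;
    overlapping windows are positively dependent, so this is mildly
    conservative. It is what makes BH presence calls across peaks of
    different (effective) lengths calibrated.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    return float(-np.expm1(n_windows * np.log1p(-min(window_pvalue, 1.0 - 1e-16))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving with the input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_motif_presence(hits: pd.DataFrame, fdr_threshold: float = 1e-3) -> pd.DataFrame:
    """BH-adjust one motif's per-peak p-values and call presence at the FDR cut.

    ``hits`` must have one row per peak with columns ``peak_id`` and
    ``p_value``. Returns a copy with ``q_value`` and ``present`` filled in.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    if hits["peak_id"].duplicated().any():
        dupes = hits.loc[hits["peak_id"].duplicated(), "peak_id"].unique()
        raise ValueError(f"duplicate peak ids: {list(dupes)[:5]}")
    out = hits.copy()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["present"] = out["q_value"] <= fdr_threshold
    return out


def scan_sequences(pwm: PWMatrix, sequences: Mapping[str, str],
                   scan_both_strands: bool = True,
                   granularity: float = 1e-3) -> pd.DataFrame:
    """Best hit of one motif in every sequence, with per-peak p-values.

    Returns a DataFrame (peak_id, motif_id, score, start, strand, p_value)
    where ``p_value`` is the length-corrected best-hit p-value. Sequences of
    equal length are scored as a single vectorized batch.
    """
    ids = list(sequences)
    if not ids:
        return pd.DataFrame(
            columns=["peak_id", "motif_id", "score", "start", "strand", "p_value"])
    dist = ScoreDistribution(pwm, granularity)
    lengths = {len(sequences[i]) for i in ids}
    rows: list[tuple] = []
    if len(lengths) == 1 and min(lengths) >= pwm.width:
        enc = np.stack([encode_sequence(sequences[i]) for i in ids])
        w = pwm.width
        lut = np.vstack([pwm.logodds, np.full(w, -np.inf)])
        lut_rc = np.vstack([pwm.reverse_complement().logodds, np.full(w, -np.inf)])
        windows = sliding_window_view(enc, w, axis=1)          # (n, L-w+1, w)
        cols = np.arange(w)
        fwd = lut[windows, cols].sum(axis=2)
        rev = (lut_rc[windows, cols].sum(axis=2) if scan_both_strands
               else np.full_like(fwd, -np.inf))
        n_valid = (np.isfinite(fwd).sum(axis=1)
                   + (np.isfinite(rev).sum(axis=1) if scan_both_strands else 0))
        best = np.maximum(fwd.max(axis=1), rev.max(axis=1))
        for k, pid in enumerate(ids):
            if not np.isfinite(best[k]):
                raise ValueError(f"{pid}: no scorable window")
            fi = np.flatnonzero(fwd[k] == best[k])
            ri = np.flatnonzero(rev[k] == best[k])
            sf_, sr_ = (fi[0] if fi.size else enc.shape[1],
                        ri[0] if ri.size else enc.shape[1])
            start, strand = (sf_, "+") if sf_ <= sr_ else (sr_, "-")
            p = best_hit_pvalue(dist.sf(float(best[k])), int(n_valid[k]))
            rows.append((pid, pwm.motif_id, float(best[k]), int(start), strand, p))
    else:
        for pid in ids:
            hit = best_hit(pwm, sequences[pid], scan_both_strands, peak_id=pid)
            enc = encode_sequence(sequences[pid])
            n_win = int(np.isfinite(_window_scores(pwm.logodds, enc)).sum())
            if scan_both_strands:
                n_win += int(np.isfinite(
                    _window_scores(pwm.reverse_complement().logodds, enc)).sum())
            p = best_hit_pvalue(dist.sf(hit.score), max(n_win, 1))
            rows.append((pid, pwm.motif_id, hit.score, hit.start, hit.strand, p))
    return pd.DataFrame(
        rows, columns=["peak_id", "motif_id", "score", "start", "strand", "p_value"])
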