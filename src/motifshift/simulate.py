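"""Synthetic regulatory-genomics data with planted ground truth.

Emulates the structure of a two-condition (WT vs knockout) ChIP-seq /
RNA-seq study at toy scale: ~600 bp peak sequences with motifs planted at
known positions, negative-binomial per-peak read counts with a
multiplicative binding effect in the KO condition for AP1-motif peaks, and
a replicated gene count table where genes near affected peaks (and a
clustered co-regulated locus, mimicking a differentiation gene complex)
carry planted expression effects. A truth table records every plant so
downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .motifs import PFMotif, reverse_complement

# Idealized sharp AP1-like motif (TRE core TGACTCA with fixed flanks).
# Columns put probability 0.95 on the consensus letter; the width and
# sharpness are chosen so that a planted sample is individually detectable
# in a 600 bp peak at a presence FDR of 1e-3.
_AP1_CONSENSUS = "CGATGACTCATCGC"
# Idealized p63-like response element: two RRRCATGYYY half-sites. Softer
# columns (0.70 on consensus) give a broad, informative score distribution
# for quintile stratification.
_P63_CONSENSUS = "AAACATGTTTAAACATGTTT"

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _consensus_pfm(motif_id: str, name: str, consensus: str,
                   dominant: float, total: int = 300) -> PFMotif:
    counts = np.full((4, len(consensus)), (1 - dominant) * total / 3.0)
    for j, b in enumerate(consensus):
        counts[_BASE_INDEX[b], j] = dominant * total
    return PFMotif(motif_id, name, counts)


AP1_PFM = _consensus_pfm("AP1_SYN", "AP1-like (synthetic)", _AP1_CONSENSUS, 0.95)
P63_PFM = _consensus_pfm("P63_SYN", "p63-like (synthetic)", _P63_CONSENSUS, 0.70)


@dataclass(frozen=True)
class GenomeModel:
    """Toy genome: chromosome lengths plus gene records with TSS and strand."""

    chromosomes: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        for _, row in g.iterrows():
            if row["chrom"] not in self.chromosomes:
                raise ValueError(f"gene {row['gene_id']} on unknown chromosome")
            if not 0 <= row["tss"] < self.chromosomes[row["chrom"]]:
                raise ValueError(f"gene {row['gene_id']} TSS out of bounds")
        if not set(g["strand"]).issubset({"+", "-"}):
            raise ValueError("gene strand must be + or -")


@dataclass
class SyntheticTruth:
    """Ground truth of every plant the generator made."""

    peaks: pd.DataFrame  # peak_id, has_ap1_motif, has_p63_motif,
    #                      planted_log2_binding_effect, ap1_pos, ap1_strand,
    #                      ap1_score, p63_pos, p63_strand
    genes: pd.DataFrame | None
    seed: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PeakSimConfig:
    """Peak-dataset generator parameters (defaults = the study conditions)."""

    n_peaks: int = 1000
    peak_length: int = 600
    gc_fraction: float = 0.42          # mouse-genome-like base composition
    p63_prob: float = 0.40             # fraction of peaks with a planted p63 motif
    ap1_prob_given_p63: float = 0.075  # AP1 plants anti-correlate with p63 ...
    ap1_prob_given_no_p63: float = 0.45  # ... so the effect sits at weak p63 sites
    mean_count: float = 50.0           # baseline NB mean per condition
    dispersion: float = 0.05           # NB alpha: var = mu + alpha*mu^2 (0 = Poisson)
    log2_binding_effect: float = 1.0   # applied to the KO mean of AP1 peaks
    peak_spacing: int = 50000          # genomic pitch of the tiled peaks; sparse
    #                                    enough that effect peaks touch only a
    #                                    minority of genes within 20 kb
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if self.peak_length <= 0:
            raise ValueError("peak_length must be positive")
        if self.mean_count <= 0:
            raise ValueError("NB mean must be positive")
        if self.dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")


@dataclass(frozen=True)
class ExprSimConfig:
    """Expression-dataset generator parameters."""

    n_replicates: int = 3
    mean_count: float = 100.0          # median of the lognormal baseline means
    baseline_sigma: float = 1.0        # lognormal spread of per-gene means
    dispersion: float = 0.05
    log2_expression_effect: float = 1.0  # genes near an affected peak, KO up
    cluster_log2_effect: float = 2.0     # planted co-regulated locus, KO up
    proximity_bp: int = 20000

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.mean_count <= 0 or self.dispersion < 0:
            raise ValueError("invalid NB parameters")


@dataclass(frozen=True)
class GenomeSimConfig:
    n_genes: int = 1000                # genes interleaved with the peaks
    #                                    (~1 gene / 50 kb, mammalian-like)
    cluster_size: int = 25             # co-regulated locus on its own chromosome
    cluster_spacing: int = 5000
    cluster_chrom: str = "chr2"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_background_sequence(length: int, gc_fraction: float, seed) -> str:
    """Order-0 random sequence with the given GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    probs = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                      gc_fraction / 2, (1 - gc_fraction) / 2])
    draws = _rng(seed).choice(4, size=length, p=probs)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[draws].tobytes().decode("ascii")


def sample_motif_window(pfm: PFMotif, seed) -> str:
    """One realization of the motif: each column sampled independently."""
    rng = _rng(seed)
    probs = pfm.column_probabilities()
    out = []
    for j in range(pfm.width):
        out.append("ACGT"[rng.choice(4, p=probs[:, j])])
    return "".join(out)


def plant_motif(sequence: str, pfm: PFMotif, position: int, strand: str, seed,
                window: str | None = None) -> str:
    """Splice a sampled motif instance into a sequence.

    The planted window is a sample from the motif's probability columns
    (reverse-complemented for '-'); only the window changes. A pre-sampled
    ``window`` (forward-strand orientation) may be supplied for
    reproducibility across strands.
    """
    if strand not in "+-":
        raise ValueError("strand must be + or -")
    if position < 0 or position + pfm.width > len(sequence):
        raise ValueError("motif window out of sequence bounds")
    if window is None:
        window = sample_motif_window(pfm, seed)
    if strand == "-":
        window = reverse_complement(window)
    return sequence[:position] + window + sequence[position + pfm.width:]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, alpha) with var = mu + alpha*mu^2; alpha=0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def _pwm_score(pfm: PFMotif, window: str) -> float:
    """Log-odds score of a window under the motif with uniform background."""
    from .motifs import build_pwm
    pwm = build_pwm(pfm, pseudocount=0.1)
    return float(sum(pwm.logodds[_BASE_INDEX[b], j] for j, b in enumerate(window)))


_EMPTY_TRUTH_COLS = ["peak_id", "has_ap1_motif", "has_p63_motif",
                     "planted_log2_binding_effect", "ap1_pos", "ap1_strand",
                     "ap1_score", "p63_pos", "p63_strand"]


def generate_peak_dataset(config: PeakSimConfig, seed: int
                          ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Peaks with sequences, two-condition counts, and the truth table.

    Returns ``(peaks, counts, truth)`` where ``peaks`` has columns
    (peak_id, chrom, start, end, sequence), ``counts`` has
    (peak_id, count_wt, count_ko), and ``truth.peaks`` records plants and
    planted binding effects. The binding effect multiplies the KO-condition
    mean of AP1-motif peaks by 2**log2_binding_effect (WT is the reference,
    so positive M means enriched in KO).
    """
    rng = _rng(seed)
    n = config.n_peaks
    if n == 0:
        peaks = pd.DataFrame(columns=["peak_id", "chrom", "start", "end", "sequence"])
        counts = pd.DataFrame(columns=["peak_id", "count_wt", "count_ko"])
        return peaks, counts, SyntheticTruth(
            pd.DataFrame(columns=_EMPTY_TRUTH_COLS), None, seed, config.__dict__.copy())

    width = len(str(n - 1)) if n > 1 else 1
    ids = [f"peak_{i:0{width}d}" for i in range(n)]
    jitter_room = max(config.peak_spacing - config.peak_length, 1)
    starts = (np.arange(n) * config.peak_spacing
              + rng.integers(0, jitter_room, size=n))
    has_p63 = rng.random(n) < config.p63_prob
    p_ap1 = np.where(has_p63, config.ap1_prob_given_p63, config.ap1_prob_given_no_p63)
    has_ap1 = rng.random(n) < p_ap1

    sequences, rows = [], []
    for i in range(n):
        seq = generate_background_sequence(config.peak_length, config.gc_fraction, rng)
        p63_pos = p63_strand = ap1_pos = ap1_strand = None
        ap1_score = np.nan
        if has_p63[i]:
            p63_pos = int(rng.integers(0, config.peak_length - P63_PFM.width + 1))
            p63_strand = "+-"[rng.integers(0, 2)]
            seq = plant_motif(seq, P63_PFM, p63_pos, p63_strand, rng)
        if has_ap1[i]:
            for _ in range(100):  # rejection-sample a non-overlapping position
                pos = int(rng.integers(0, config.peak_length - AP1_PFM.width + 1))
                if p63_pos is None or (pos + AP1_PFM.width <= p63_pos
                                       or pos >= p63_pos + P63_PFM.width):
                    break
            else:
                raise RuntimeError("could not place AP1 motif without overlap")
            ap1_pos, ap1_strand = pos, "+-"[rng.integers(0, 2)]
            window = sample_motif_window(AP1_PFM, rng)
            seq = plant_motif(seq, AP1_PFM, ap1_pos, ap1_strand, rng, window=window)
            ap1_score = _pwm_score(AP1_PFM, window)
        sequences.append(seq)
        effect = config.log2_binding_effect if has_ap1[i] else 0.0
        rows.append((ids[i], bool(has_ap1[i]), bool(has_p63[i]), effect,
                     ap1_pos, ap1_strand, ap1_score, p63_pos, p63_strand))

    peaks = pd.DataFrame({
        "peak_id": ids, "chrom": config.chrom, "start": starts,
        "end": starts + config.peak_length, "sequence": sequences})
    ko_mean = config.mean_count * np.where(
        has_ap1, 2.0 ** config.log2_binding_effect, 1.0)
    counts = pd.DataFrame({
        "peak_id": ids,
        "count_wt": _nb_draw(rng, np.full(n, config.mean_count), config.dispersion),
        "count_ko": _nb_draw(rng, ko_mean, config.dispersion)})
    truth = SyntheticTruth(pd.DataFrame(rows, columns=_EMPTY_TRUTH_COLS),
                           None, seed, config.__dict__.copy())
    return peaks, counts, truth


def make_genome(peaks: pd.DataFrame, config: GenomeSimConfig, seed: int) -> GenomeModel:
    """Toy genome around a peak set: genes interleaved with the peaks on the
    peak chromosome plus a gene-dense co-regulated cluster on its own
    chromosome (an EDC-like locus)."""
    rng = _rng(seed)
    if len(peaks):
        chrom = peaks["chrom"].iloc[0]
        length = int(peaks["end"].max() + 50000)
    else:
        chrom, length = "chr1", 1_000_000
    tss = np.sort(rng.integers(0, length, size=config.n_genes))
    width = len(str(config.n_genes + config.cluster_size))
    genes = pd.DataFrame({
        "gene_id": [f"gene_{i:0{width}d}" for i in range(config.n_genes)],
        "chrom": chrom, "tss": tss,
        "strand": np.where(rng.random(config.n_genes) < 0.5, "+", "-")})
    cluster_len = (config.cluster_size + 1) * config.cluster_spacing
    cluster = pd.DataFrame({
        "gene_id": [f"clust_{i:0{width}d}" for i in range(config.cluster_size)],
        "chrom": config.cluster_chrom,
        "tss": (np.arange(config.cluster_size) + 1) * config.cluster_spacing,
        "strand": np.where(rng.random(config.cluster_size) < 0.5, "+", "-")})
    chroms = {chrom: length}
    if config.cluster_size:
        chroms[config.cluster_chrom] = cluster_len
    return GenomeModel(chroms, pd.concat([genes, cluster], ignore_index=True))


def generate_expression_dataset(genome: GenomeModel, peaks: pd.DataFrame,
                                peak_truth: SyntheticTruth, config: ExprSimConfig,
                                seed: int
                                ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Replicated two-condition gene counts with planted expression effects.

    Genes whose TSS lies within ``proximity_bp`` of a peak carrying a planted
    binding effect are upregulated in KO by ``log2_expression_effect``;
    cluster genes (ids starting ``clust_``) by ``cluster_log2_effect``.
    Returns (counts genes x samples, condition labels per sample, gene truth).
    """
    rng = _rng(seed)
    genes = genome.genes.reset_index(drop=True)
    effect = np.zeros(len(genes))

    affected = peaks.merge(peak_truth.peaks, on="peak_id")
    affected = affected[affected["planted_log2_binding_effect"] != 0]
    for chrom, grp in affected.groupby("chrom"):
        mid = ((grp["start"] + grp["end"]) // 2).to_numpy()
        sel = genes["chrom"] == chrom
        t = genes.loc[sel, "tss"].to_numpy()
        near = (np.abs(t[:, None] - mid[None, :]) <= config.proximity_bp).any(axis=1)
        effect[np.flatnonzero(sel)[near]] = config.log2_expression_effect
    is_cluster = genes["gene_id"].str.startswith("clust_").to_numpy()
    effect[is_cluster] = config.cluster_log2_effect

    base = rng.lognormal(np.log(config.mean_count), config.baseline_sigma,
                         size=len(genes))
    samples = ([f"wt_{r + 1}" for r in range(config.n_replicates)]
               + [f"ko_{r + 1}" for r in range(config.n_replicates)])
    condition = pd.Series(["WT"] * config.n_replicates + ["KO"] * config.n_replicates,
                          index=samples, name="condition")
    cols = {}
    for s in samples:
        mean = base * (2.0 ** effect if s.startswith("ko") else 1.0)
        cols[s] = _nb_draw(rng, mean, config.dispersion)
    counts = pd.DataFrame(cols, index=genes["gene_id"])
    truth = pd.DataFrame({"gene_id": genes["gene_id"],
                          "planted_log2_expression_effect": effect,
                          "in_cluster": is_cluster})
    return counts, condition, truth


def shuffle_pfm_columns(pfm: PFMotif, seed, motif_id: str | None = None) -> PFMotif:
    """Decoy motif: the same columns in a random order (information content
    preserved, sequence specificity destroyed)."""
    rng = _rng(seed)
    perm = rng.permutation(pfm.width)
    mid = motif_id or f"{pfm.motif_id}_shuf"
    return PFMotif(mid, f"{pfm.name} column-shuffle", pfm.counts[:, perm])


def make_decoys(pfm: PFMotif, n_decoys: int, seed: int) -> list[PFMotif]:
    rng = _rng(seed)
    return [shuffle_pfm_columns(pfm, rng, motif_id=f"{pfm.motif_id}_decoy{i:02d}")
            for i in range(n_decoys)]
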