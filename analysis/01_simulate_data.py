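#!/usr/bin/env python
"""Generate the synthetic study dataset with planted ground truth.

Writes the two-condition peak dataset (BED intervals, 600 bp sequences with
planted AP1/p63 motifs, WT/KO read counts), the motif set (AP1, p63, and 20
column-shuffled AP1 decoys), the toy genome annotation, and the replicated
gene count table, all under results/data/. Later numbered scripts consume
these files through the package's readers.
"""

import argparse
import dataclasses
from pathlib import Path

import numpy as np

from motifshift import io, simulate
from motifshift.config import AnalysisConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = dataclasses.replace(AnalysisConfig(), seed=args.seed)
    root = np.random.SeedSequence(cfg.seed)
    peak_seed, genome_seed, expr_seed, decoy_seed = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(4))

    peaks, counts, truth = simulate.generate_peak_dataset(cfg.peaks, peak_seed)
    genome = simulate.make_genome(peaks, cfg.genome, genome_seed)
    gene_counts, condition, gene_truth = simulate.generate_expression_dataset(
        genome, peaks, truth, cfg.expression, expr_seed)
    pfms = [simulate.AP1_PFM, simulate.P63_PFM] + simulate.make_decoys(
        simulate.AP1_PFM, cfg.n_decoys, decoy_seed)

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    io.write_bed(peaks.assign(name=peaks["peak_id"]), out / "peaks.bed")
    io.write_fasta(dict(zip(peaks["peak_id"], peaks["sequence"])),
                   out / "peaks.fa")
    io.write_tsv(counts, out / "counts.tsv")
    io.write_tsv(truth.peaks, out / "truth_peaks.tsv")
    io.write_jaspar_pfm(pfms, out / "motifs.pfm")
    io.write_tsv(genome.genes, out / "genes.tsv")
    io.write_tsv(gene_counts, out / "gene_counts.tsv", index=True)
    io.write_tsv(condition.rename_axis("sample").reset_index(),
                 out / "conditions.tsv")
    io.write_tsv(gene_truth, out / "truth_genes.tsv")

    n_ap1 = int(truth.peaks["has_ap1_motif"].sum())
    n_p63 = int(truth.peaks["has_p63_motif"].sum())
    n_eff = int((gene_truth["planted_log2_expression_effect"] > 0).sum())
    print(f"seed {args.seed}: {len(peaks)} peaks "
          f"({n_ap1} with AP1 motif + log2 binding effect "
          f"{cfg.peaks.log2_binding_effect}, {n_p63} with p63 motif); "
          f"{len(gene_counts)} genes x {gene_counts.shape[1]} samples "
          f"({n_eff} with planted expression effect, "
          f"{int(gene_truth['in_cluster'].sum())} in the co-regulated cluster)")
    print(f"data written to {out}")


if __name__ == "__main__":
    main()
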