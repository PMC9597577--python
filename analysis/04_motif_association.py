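#!/usr/bin/env python
"""Rank motifs by association of their scores with the binding shift M.

The headline analysis: Spearman correlation of each motif's per-peak best
score with normalized M, a dot plot of the ranking, and the stratification
of condition-enriched peaks by p63 motif-score quintile with AP1-presence
fractions per stratum. Writes motif_ranking.tsv and strata.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from motifshift import associate, io, plots


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tabledir", type=Path, default=Path("results/tables"))
    args = ap.parse_args()

    ma = pd.read_csv(args.tabledir / "ma_stats.tsv", sep="\t")
    hits = pd.read_csv(args.tabledir / "motif_hits.tsv", sep="\t")
    scores = hits.pivot(index="peak_id", columns="motif_id", values="score")

    ranking = associate.rank_motifs(ma, scores)
    io.write_tsv(ranking, args.tabledir / "motif_ranking.tsv")
    plots.motif_rank_dotplot(ranking, highlight=("AP1_SYN", "P63_SYN"),
                             path=args.tabledir.parent / "figures" / "motif_rank_dotplot.png")

    ap1 = hits[hits["motif_id"] == "AP1_SYN"].set_index("peak_id")
    p63_scores = scores["P63_SYN"].loc[ma["peak_id"]]
    strata = associate.quintile_stratify(
        p63_scores, ap1["present"].loc[ma["peak_id"]],
        ma.set_index("peak_id")["class"].loc[ma["peak_id"]])
    io.write_tsv(pd.DataFrame([s.__dict__ for s in strata]),
                 args.tabledir / "strata.tsv")

    top = ranking.iloc[0]
    ap1_row = ranking.set_index("motif_id").loc["AP1_SYN"]
    print(f"top-ranked motif: {top['motif_id']} (rho={top['rho']:.3f}); "
          f"AP1 rank {int(ap1_row['rank'])}/{len(ranking)}")
    s1 = strata[0]
    print(f"bottom p63-score quintile: AP1 motif present in "
          f"{100 * s1.frac_ko_with_ap1:.0f}% of {s1.n_enriched_ko} KO-enriched "
          f"vs {100 * s1.frac_wt_with_ap1:.0f}% of {s1.n_enriched_wt} "
          f"WT-enriched peaks")


if __name__ == "__main__":
    main()
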