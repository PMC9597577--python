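"""End-to-end pipeline over a synthetic two-condition dataset.

Chains the stages in the order the analysis runs on real data: simulate
(stand-in for upstream peak calling / counting), exclusion filtering,
MA differential binding, motif scanning and presence calls, motif-shift
association, p63-quintile stratification, peak-to-gene annotation,
differential expression, and subcategory enrichment. Every stage writes a
TSV and the run emits a manifest with record counts and the config hash.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, associate, diffbind, diffexpr, io, motifs, simulate
from .config import AnalysisConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage(name, fn, manifest, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc
    manifest["stages"].append({"stage": name,
                               "elapsed_s": round(time.perf_counter() - t0, 3)})
    logger.info("stage %-12s done in %.2fs", name, manifest["stages"][-1]["elapsed_s"])
    return result


def scan_motif_set(pfms, sequences, config: AnalysisConfig):
    """Best hits of every motif in every peak sequence.

    Returns (scores peaks x motifs, hits per motif dict). The scan
    background is estimated order-0 from the scanned sequences unless the
    config selects uniform.
    """
    bg = (motifs.estimate_background(sequences.values())
          if config.background == "sequences" else None)
    hits, score_cols = {}, {}
    for pfm in pfms:
        pwm = motifs.build_pwm(pfm, background=bg,
                               pseudocount=config.pwm_pseudocount)
        df = motifs.scan_sequences(pwm, sequences,
                                   scan_both_strands=config.scan_both_strands,
                                   granularity=config.pvalue_granularity)
        hits[pfm.motif_id] = df
        score_cols[pfm.motif_id] = df.set_index("peak_id")["score"]
    scores = pd.DataFrame(score_cols)
    return scores, hits


def run_pipeline(config: AnalysisConfig, outdir=None,
                 exclusions: pd.DataFrame | None = None) -> dict:
    """Run the full synthetic-data analysis; returns the result bundle.

    When ``outdir`` is given every stage output is written as TSV together
    with a ``manifest.json`` listing outputs, row counts, seed and config
    hash.
    """
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": [], "outputs": {}}
    logger.info("run config hash=%s seed=%d", config.config_hash(), config.seed)
    root = np.random.SeedSequence(config.seed)
    peak_seed, genome_seed, expr_seed, decoy_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4))

    peaks, counts, truth = _stage(
        "simulate", simulate.generate_peak_dataset, manifest, config.peaks, peak_seed)
    if exclusions is not None:
        peaks = _stage("filter", diffbind.filter_excluded_regions, manifest,
                       peaks, exclusions)
        counts = counts[counts["peak_id"].isin(peaks["peak_id"])].reset_index(drop=True)

    ma, norm_fit = _stage("diffbind", diffbind.differential_binding, manifest,
                          counts, config.ma_pseudocount, config.binding_threshold)

    sequences = dict(zip(peaks["peak_id"], peaks["sequence"]))
    pfms = [simulate.AP1_PFM, simulate.P63_PFM] + simulate.make_decoys(
        simulate.AP1_PFM, config.n_decoys, decoy_seed)
    scores, hits = _stage("scan", scan_motif_set, manifest, pfms, sequences, config)

    ranking = _stage("associate", associate.rank_motifs, manifest, ma, scores)

    ap1_calls = _stage("presence", motifs.call_motif_presence, manifest,
                       hits[simulate.AP1_PFM.motif_id], config.presence_fdr)
    strata = _stage(
        "stratify", associate.quintile_stratify, manifest,
        scores[simulate.P63_PFM.motif_id].loc[ma["peak_id"]],
        ap1_calls.set_index("peak_id")["present"].loc[ma["peak_id"]],
        ma.set_index("peak_id")["class"].loc[ma["peak_id"]])

    genome = _stage("genome", simulate.make_genome, manifest,
                    peaks, config.genome, genome_seed)
    gene_counts, condition, gene_truth = _stage(
        "expression", simulate.generate_expression_dataset, manifest,
        genome, peaks, truth, config.expression, expr_seed)
    de = _stage("de", diffexpr.de_test, manifest, gene_counts, condition,
                None, config.de_alpha)

    links = _stage("annotate", annotate.nearest_tss, manifest, peaks,
                   genome.genes, config.promoter_bp, config.enhancer_bp)
    bound = annotate.genes_bound_within(links, config.enhancer_bp)

    enrichments = _stage("enrich", integrate_enrichment, manifest,
                         de, links, bound, ma, ap1_calls, gene_truth,
                         config)

    bundle = {"peaks": peaks, "counts": counts, "truth": truth, "ma": ma,
              "normalization": norm_fit, "scores": scores, "hits": hits,
              "ranking": ranking, "ap1_calls": ap1_calls, "strata": strata,
              "genome": genome, "gene_counts": gene_counts,
              "condition": condition, "gene_truth": gene_truth, "de": de,
              "links": links, "bound": bound, "enrichments": enrichments,
              "manifest": manifest}
    if outdir is not None:
        _write_bundle(bundle, Path(outdir), manifest, config)
    return bundle


def integrate_enrichment(de, links, bound, ma, ap1_calls, gene_truth,
                         config: AnalysisConfig) -> pd.DataFrame:
    """Odds-ratio / chi-squared enrichment of upregulation in gene
    subcategories of the integrated (expressed + annotated) dataset."""
    expressed = set(de.loc[de["passes_filter"], "gene_id"])
    reference = expressed
    classes = de.set_index("gene_id")["class"]

    bound_genes = set(bound.loc[bound["bound"], "gene_id"]) & reference
    link_cls = links.dropna(subset=["gene_id"]).merge(
        ma[["peak_id", "class"]], on="peak_id")
    near = link_cls[link_cls["distance"].abs() <= config.enhancer_bp]
    ko_genes = set(near.loc[near["class"] == "enriched_KO", "gene_id"]) & reference
    wt_genes = set(near.loc[near["class"] == "enriched_WT", "gene_id"]) & reference
    unchanged_genes = (bound_genes - ko_genes - wt_genes)
    ap1_peaks = set(ap1_calls.loc[ap1_calls["present"], "peak_id"])
    ap1_genes = set(near.loc[near["peak_id"].isin(ap1_peaks), "gene_id"]) & reference
    cluster = set(gene_truth.loc[gene_truth["in_cluster"], "gene_id"]) & reference

    rows = []
    for name, subset, fn in (
            ("p63_bound", bound_genes, associate.subcategory_enrichment),
            ("p63_bound_ko_enriched", ko_genes, associate.subcategory_enrichment),
            ("p63_bound_unchanged", unchanged_genes, associate.subcategory_enrichment),
            ("p63_bound_wt_enriched", wt_genes, associate.subcategory_enrichment),
            ("p63_bound_ap1_motif", ap1_genes, associate.subcategory_enrichment),
            ("cluster_locus", cluster, associate.locus_set_enrichment)):
        if not subset:
            logger.warning("subcategory %s empty; skipped", name)
            continue
        r = fn(subset, classes, reference, name=name)
        rows.append((r.subcategory, r.a, r.b, r.c, r.d,
                     r.odds_ratio, r.chi2, r.p_value))
    return pd.DataFrame(rows, columns=["subcategory", "a", "b", "c", "d",
                                       "odds_ratio", "chi2", "p_value"])


def _write_bundle(bundle, outdir: Path, manifest, config: AnalysisConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    peaks = bundle["peaks"]
    io.write_bed(peaks.assign(name=peaks["peak_id"]), outdir / "peaks.bed")
    io.write_fasta(dict(zip(peaks["peak_id"], peaks["sequence"])),
                   outdir / "peaks.fa")
    tables = {
        "counts.tsv": bundle["counts"],
        "ma_stats.tsv": bundle["ma"][["peak_id", "count_wt", "count_ko", "A",
                                      "M_raw", "M_norm", "p_value", "class"]],
        "motif_ranking.tsv": bundle["ranking"],
        "ap1_presence.tsv": bundle["ap1_calls"],
        "strata.tsv": pd.DataFrame([s.__dict__ for s in bundle["strata"]]),
        "de_results.tsv": bundle["de"],
        "peak_gene_links.tsv": bundle["links"],
        "enrichment.tsv": bundle["enrichments"],
        "truth_peaks.tsv": bundle["truth"].peaks,
        "truth_genes.tsv": bundle["gene_truth"],
    }
    io.write_tsv(bundle["gene_counts"], outdir / "gene_counts.tsv", index=True)
    io.write_tsv(bundle["condition"].rename_axis("sample").reset_index(),
                 outdir / "conditions.tsv")
    for name, df in tables.items():
        io.write_tsv(df, outdir / name)
        manifest["outputs"][name] = int(len(df))
    manifest["outputs"]["gene_counts.tsv"] = int(len(bundle["gene_counts"]))
    manifest["config"] = config.to_dict()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
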