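"""Synthetic-data generator: determinism, planted truth, planted effects."""

import dataclasses

import numpy as np
import pytest

from motifshift.diffbind import binding_significance
from motifshift.motifs import best_hit, build_pwm, reverse_complement
from motifshift.simulate import (
    AP1_PFM, P63_PFM, ExprSimConfig, GenomeSimConfig, PeakSimConfig,
    generate_background_sequence, generate_expression_dataset,
    generate_peak_dataset, make_decoys, make_genome, plant_motif,
    sample_motif_window, shuffle_pfm_columns,
)


class TestBackgroundSequence:
    def test_zero_gc_contains_only_a_and_t(self):
        seq = generate_background_sequence(200, 0.0, 7)
        assert set(seq) <= {"A", "T"}

    def test_gc_converges_binomially(self):
        """Observed GC within 3 binomial SD of the target."""
        n, gc = 100_000, 0.5
        seq = generate_background_sequence(n, gc, 1)
        observed = (seq.count("G") + seq.count("C")) / n
        assert abs(observed - gc) < 3 * np.sqrt(gc * (1 - gc) / n)

    def test_deterministic_given_seed(self):
        assert (generate_background_sequence(500, 0.4, 11)
                == generate_background_sequence(500, 0.4, 11))

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (-3, 0.5), (10, 1.2), (10, -0.1)])
    def test_invalid_arguments_rejected(self, length, gc):
        with pytest.raises(ValueError):
            generate_background_sequence(length, gc, 0)


class TestPlantMotif:
    def test_locality_outside_window_unchanged(self, consensus_only_pfm):
        seq = "A" * 10
        out = plant_motif(seq, consensus_only_pfm, 0, "+", 3)
        assert len(out) == 10
        assert out[4:] == seq[4:]

    def test_consensus_only_motif_plants_consensus(self, consensus_only_pfm):
        out = plant_motif("A" * 10, consensus_only_pfm, 2, "+", 0)
        assert out[2:6] == consensus_only_pfm.consensus
        assert out[:2] == "AA" and out[6:] == "AAAA"

    def test_minus_strand_is_revcomp_of_plus(self):
        window = sample_motif_window(AP1_PFM, 5)
        plus = plant_motif("T" * 30, AP1_PFM, 4, "+", 0, window=window)
        minus = plant_motif("T" * 30, AP1_PFM, 4, "-", 0, window=window)
        w = AP1_PFM.width
        assert minus[4:4 + w] == reverse_complement(plus[4:4 + w])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            plant_motif("ACGT", AP1_PFM, 0, "+", 0)


class TestPeakDataset:
    def test_empty_request_gives_empty_outputs(self):
        peaks, counts, truth = generate_peak_dataset(
            dataclasses.replace(PeakSimConfig(), n_peaks=0), 0)
        assert peaks.empty and counts.empty and truth.peaks.empty

    def test_deterministic_given_seed(self):
        cfg = PeakSimConfig(n_peaks=30)
        a = generate_peak_dataset(cfg, 42)
        b = generate_peak_dataset(cfg, 42)
        assert a[0].equals(b[0]) and a[1].equals(b[1])
        assert a[2].peaks.equals(b[2].peaks)

    def test_truth_flags_match_actual_plants(self):
        """Every AP1-flagged peak carries a window whose best hit reproduces
        the planted sample's score."""
        cfg = PeakSimConfig(n_peaks=40)
        peaks, _, truth = generate_peak_dataset(cfg, 3)
        pwm = build_pwm(AP1_PFM, pseudocount=0.1)
        merged = peaks.merge(truth.peaks, on="peak_id")
        planted = merged[merged["has_ap1_motif"]]
        assert len(planted) > 0
        for _, row in planted.iterrows():
            pos = int(row["ap1_pos"])
            window = row["sequence"][pos:pos + AP1_PFM.width]
            if row["ap1_strand"] == "-":
                window = reverse_complement(window)
            hit = best_hit(pwm, window)
            assert hit.score == pytest.approx(row["ap1_score"])

    def test_zero_effect_mean_m_near_zero(self):
        """With effect 0 the expected raw M of every peak is ~0."""
        cfg = dataclasses.replace(PeakSimConfig(), n_peaks=2000,
                                  log2_binding_effect=0.0)
        _, counts, _ = generate_peak_dataset(cfg, 9)
        m = np.log2(counts["count_ko"] + 1) - np.log2(counts["count_wt"] + 1)
        assert abs(m.mean()) < 0.05

    def test_zero_effect_null_call_rate(self):
        """Enriched fraction at p<5e-3 approximates the statistic's null rate
        (Poisson sampling, the statistic's own count model)."""
        cfg = dataclasses.replace(PeakSimConfig(), n_peaks=2000,
                                  log2_binding_effect=0.0, dispersion=0.0)
        _, counts, _ = generate_peak_dataset(cfg, 10)
        p = binding_significance(counts["count_wt"], counts["count_ko"])
        rate = (p < 5e-3).mean()
        assert rate < 5e-3 + 3 * np.sqrt(5e-3 * 0.995 / 2000)

    def test_planted_effect_recovered_in_raw_m(self):
        """Mean M of AP1 peaks minus mean M of the rest ~ the planted log2
        effect, within Monte-Carlo tolerance."""
        cfg = dataclasses.replace(PeakSimConfig(), n_peaks=3000)
        _, counts, truth = generate_peak_dataset(cfg, 11)
        m = np.log2(counts["count_ko"] + 1) - np.log2(counts["count_wt"] + 1)
        ap1 = truth.peaks["has_ap1_motif"].to_numpy()
        assert m[ap1].mean() - m[~ap1].mean() == pytest.approx(1.0, abs=0.1)

    def test_invalid_distribution_parameters_rejected(self):
        with pytest.raises(ValueError):
            PeakSimConfig(mean_count=-1)
        with pytest.raises(ValueError):
            PeakSimConfig(dispersion=-0.5)


class TestExpressionDataset:
    @pytest.fixture
    def small_world(self):
        cfg = PeakSimConfig(n_peaks=50)
        peaks, _, truth = generate_peak_dataset(cfg, 21)
        genome = make_genome(peaks, GenomeSimConfig(n_genes=100, cluster_size=10), 22)
        return peaks, truth, genome

    def test_dimensions_and_integer_counts(self, small_world):
        peaks, truth, genome = small_world
        counts, condition, gene_truth = generate_expression_dataset(
            genome, peaks, truth, ExprSimConfig(n_replicates=3), 5)
        assert counts.shape == (len(genome.genes), 6)
        assert (counts.to_numpy() >= 0).all()
        assert counts.to_numpy().dtype.kind in "iu"
        assert set(condition) == {"WT", "KO"}

    def test_deterministic_given_seed(self, small_world):
        peaks, truth, genome = small_world
        cfg = ExprSimConfig()
        a = generate_expression_dataset(genome, peaks, truth, cfg, 6)[0]
        b = generate_expression_dataset(genome, peaks, truth, cfg, 6)[0]
        assert a.equals(b)

    def test_truth_marks_genes_near_effect_peaks(self, small_world):
        peaks, truth, genome = small_world
        _, _, gene_truth = generate_expression_dataset(
            genome, peaks, truth, ExprSimConfig(), 7)
        effect_peaks = peaks.merge(truth.peaks, on="peak_id")
        effect_peaks = effect_peaks[effect_peaks["planted_log2_binding_effect"] != 0]
        mids = ((effect_peaks["start"] + effect_peaks["end"]) // 2).to_numpy()
        for _, g in genome.genes[genome.genes["chrom"] == "chr1"].iterrows():
            near = bool((np.abs(mids - g["tss"]) <= 20000).any())
            row = gene_truth.set_index("gene_id").loc[g["gene_id"]]
            assert (row["planted_log2_expression_effect"] > 0) == near

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            ExprSimConfig(n_replicates=1)


class TestDecoys:
    def test_column_shuffle_preserves_information(self):
        decoy = shuffle_pfm_columns(AP1_PFM, 0)
        assert sorted(map(tuple, decoy.counts.T)) == sorted(map(tuple, AP1_PFM.counts.T))

    def test_make_decoys_unique_ids(self):
        decoys = make_decoys(AP1_PFM, 5, 1)
        assert len({d.motif_id for d in decoys}) == 5


def test_genome_invariants_enforced():
    import pandas as pd
    genes = pd.DataFrame({"gene_id": ["a", "a"], "chrom": ["c1", "c1"],
                          "tss": [5, 6], "strand": ["+", "+"]})
    from motifshift.simulate import GenomeModel
    with pytest.raises(ValueError, match="unique"):
        GenomeModel({"c1": 100}, genes)
    genes2 = genes.assign(gene_id=["a", "b"], tss=[5, 500])
    with pytest.raises(ValueError, match="bounds"):
        GenomeModel({"c1": 100}, genes2)
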