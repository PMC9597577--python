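"""Motif model construction, best-hit scanning, score p-values, FDR calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from motifshift.motifs import (
    PFMotif, ScoreDistribution, best_hit, best_hit_pvalue, bh_adjust,
    build_pwm, call_motif_presence, encode_sequence, estimate_background,
    reverse_complement, scan_sequences, score_pvalue,
)


class TestBuildPwm:
    def test_uniform_column_gives_zero_logodds(self):
        pfm = PFMotif("m", "m", np.ones((4, 2)))
        pwm = build_pwm(pfm, pseudocount=0.0)
        assert np.allclose(pwm.logodds, 0.0)

    def test_pure_column_zero_pseudocount_rejected(self):
        counts = np.array([[1.0], [0.0], [0.0], [0.0]])
        with pytest.raises(ValueError, match="pseudocount"):
            build_pwm(PFMotif("m", "m", counts), pseudocount=0.0)

    def test_pure_column_no_zero_cells_gives_two_bits(self):
        # all-A column with no zero cells elsewhere is fine at pc=0
        counts = np.array([[1.0], [0.0], [0.0], [0.0]])
        pwm = build_pwm(PFMotif("m", "m", counts), pseudocount=1.0)
        # hand evaluation: A = log2((1+0.25)/2/0.25), others log2(0.25/2/0.25)
        assert pwm.logodds[0, 0] == pytest.approx(np.log2(1.25 / 2 / 0.25))
        assert pwm.logodds[1, 0] == pytest.approx(np.log2(0.25 / 2 / 0.25))

    def test_formula_oracle_column_8000_pc1(self):
        """Independent scalar evaluation of the log-odds formula."""
        counts = np.array([[8.0], [0.0], [0.0], [0.0]])
        pwm = build_pwm(PFMotif("m", "m", counts), pseudocount=1.0)
        expected_a = np.log2((8 + 1 * 0.25) / (8 + 1) / 0.25)
        expected_other = np.log2((0 + 1 * 0.25) / (8 + 1) / 0.25)
        assert pwm.logodds[0, 0] == pytest.approx(expected_a)
        for b in (1, 2, 3):
            assert pwm.logodds[b, 0] == pytest.approx(expected_other)

    def test_zero_background_letter_rejected(self, small_pfm):
        with pytest.raises(ValueError, match="background"):
            build_pwm(small_pfm, background=[0.5, 0.5, 0.0, 0.0])


class TestBestHit:
    def test_consensus_sequence_scores_column_max_sum(self, small_pwm, small_pfm):
        hit = best_hit(small_pwm, small_pfm.consensus)
        assert hit.score == pytest.approx(small_pwm.logodds.max(axis=0).sum())
        assert hit.start == 0 and hit.strand == "+"

    def test_strand_symmetry(self, small_pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 30))
        fwd = best_hit(small_pwm, seq, scan_both_strands=True)
        rev = best_hit(small_pwm, reverse_complement(seq), scan_both_strands=True)
        assert fwd.score == pytest.approx(rev.score)

    def test_matches_exhaustive_window_enumeration(self, small_pwm, rng):
        """Brute-force scoring of all forward and reverse windows."""
        seq = "".join(rng.choice(list("ACGT"), 8))
        enc = encode_sequence(seq)
        rc = encode_sequence(reverse_complement(seq))
        w = small_pwm.width
        scores = []
        for i in range(len(seq) - w + 1):
            scores.append(sum(small_pwm.logodds[enc[i + j], j] for j in range(w)))
            scores.append(sum(small_pwm.logodds[rc[i + j], j] for j in range(w)))
        hit = best_hit(small_pwm, seq)
        assert hit.score == pytest.approx(max(scores))

    def test_n_windows_are_skipped(self, small_pwm):
        hit = best_hit(small_pwm, "NNNACG")
        assert hit.start == 3 and hit.strand in "+-"

    def test_too_short_sequence_rejected(self, small_pwm):
        with pytest.raises(ValueError, match="width"):
            best_hit(small_pwm, "AC")

    def test_all_n_rejected(self, small_pwm):
        with pytest.raises(ValueError, match="scorable"):
            best_hit(small_pwm, "NNNNN")

    def test_tie_breaks_smallest_offset_then_plus(self):
        # palindromic single-letter motif: every A window ties on both strands
        counts = np.array([[4.0], [4.0], [4.0], [4.0]])
        pwm = build_pwm(PFMotif("m", "m", counts), pseudocount=0.0)
        hit = best_hit(pwm, "CCAA")
        assert hit.start == 0 and hit.strand == "+"


class TestScorePvalue:
    def test_minimum_score_gives_one(self, small_pwm):
        assert score_pvalue(small_pwm, small_pwm.min_score) == 1.0
        assert score_pvalue(small_pwm, small_pwm.min_score - 5.0) == 1.0

    @pytest.mark.parametrize("width", [1, 2, 3, 4])
    def test_exhaustive_kmer_oracle(self, width, rng):
        """DP tail matches enumeration over all 4^w words (uniform bg),
        up to the per-column rounding neighborhood of the discretization."""
        counts = rng.integers(1, 20, size=(4, width)).astype(float)
        pwm = build_pwm(PFMotif("m", "m", counts), pseudocount=0.1)
        g = 1e-3
        word_scores = np.sort([
            sum(pwm.logodds[b, j] for j, b in enumerate(word))
            for word in itertools.product(range(4), repeat=width)])[::-1]

        def enum_p(s):
            return np.mean(word_scores >= s)

        for s in np.unique(np.round(word_scores, 6)):
            p = score_pvalue(pwm, s, granularity=g)
            slack = 2 * width * g
            assert enum_p(s + slack) - 1e-12 <= p <= enum_p(s - slack) + 1e-12

    def test_analytic_product_oracle_at_maximum(self, consensus_only_pfm):
        """For a strictly unique consensus, P(max) = product of background
        probabilities of the maximizing letters."""
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwm = build_pwm(consensus_only_pfm, background=bg, pseudocount=0.01)
        expected = np.prod(bg[np.argmax(pwm.logodds, axis=0)])
        assert score_pvalue(pwm, pwm.max_score) == pytest.approx(expected, rel=1e-6)

    def test_monotone_non_increasing(self, small_pwm):
        grid = np.linspace(small_pwm.min_score - 1, small_pwm.max_score + 1, 50)
        ps = [score_pvalue(small_pwm, s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_above_maximum_gives_zero(self, small_pwm):
        assert score_pvalue(small_pwm, small_pwm.max_score + 1.0) == 0.0


class TestBestHitPvalue:
    def test_single_window_identity(self):
        assert best_hit_pvalue(0.01, 1) == pytest.approx(0.01)

    def test_length_correction_increases_p(self):
        assert best_hit_pvalue(0.001, 100) == pytest.approx(
            1 - 0.999 ** 100)


class TestBhAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_all_equal_stay_equal(self):
        q = bh_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_against_literal_step_up(self, rng):
        """Independent literal implementation of the BH step-up."""
        p = rng.random(100)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, m * p[order[i]] / (i + 1))
            q_sorted[i] = running
        expected = np.empty(m)
        expected[order] = q_sorted
        assert np.allclose(bh_adjust(p), expected)

    def test_q_at_least_p_and_order_preserved(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        # order-preserving: q is non-decreasing along increasing p
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_sorted_p(self, ps):
        q = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPresenceCalls:
    def test_all_p_one_gives_zero_present(self):
        hits = pd.DataFrame({"peak_id": ["a", "b"], "p_value": [1.0, 1.0]})
        out = call_motif_presence(hits)
        assert out["present"].sum() == 0

    def test_single_dominant_peak(self):
        hits = pd.DataFrame({"peak_id": [f"p{i}" for i in range(101)],
                             "p_value": [1e-9] + [1.0] * 100})
        out = call_motif_presence(hits)
        assert out["present"].tolist() == [True] + [False] * 100

    def test_present_iff_q_below_threshold(self, rng):
        hits = pd.DataFrame({"peak_id": [f"p{i}" for i in range(200)],
                             "p_value": rng.random(200) ** 4})
        out = call_motif_presence(hits, fdr_threshold=0.05)
        assert (out["present"] == (out["q_value"] <= 0.05)).all()
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()

    def test_duplicate_peak_ids_rejected(self):
        hits = pd.DataFrame({"peak_id": ["a", "a"], "p_value": [0.1, 0.2]})
        with pytest.raises(ValueError, match="duplicate"):
            call_motif_presence(hits)


class TestScanSequences:
    def test_batch_matches_single_hits(self, small_pwm, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 40)) for i in range(8)}
        df = scan_sequences(small_pwm, seqs)
        for _, row in df.iterrows():
            hit = best_hit(small_pwm, seqs[row["peak_id"]])
            assert row["score"] == pytest.approx(hit.score)
            assert (row["start"], row["strand"]) == (hit.start, hit.strand)

    def test_unequal_lengths_fall_back(self, small_pwm):
        seqs = {"a": "ACGTACGT", "b": "ACGTA"}
        df = scan_sequences(small_pwm, seqs)
        assert len(df) == 2 and df["p_value"].between(0, 1).all()

    def test_empty_input(self, small_pwm):
        assert scan_sequences(small_pwm, {}).empty


def test_estimate_background_counts_letters():
    bg = estimate_background(["AACC", "GGTT"])
    assert np.allclose(bg, 0.25)
    with pytest.raises(ValueError):
        estimate_background(["NNN"])
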