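import io
import math

import numpy as np
import pytest

from secistrome.core import GenomicInterval, Peak
from secistrome.motifs import (
    PWM,
    MotifHit,
    NEG_INF,
    cluster_by_motif_presence,
    enrichment_test,
    motif_distribution,
    read_pfm,
    scan,
    select_score_threshold,
    top_motif_score,
)
from secistrome.simulate import embed_motif

COMP = str.maketrans("ACGT", "TGCA")


def _uniform_pwm(L, id="U"):
    return PWM(id, np.full((L, 4), 0.25), np.full(4, 0.25))


def _strong_pwm(consensus, id="S"):
    rows = []
    for b in consensus:
        row = [0.05] * 4
        row["ACGT".index(b)] = 0.85
        rows.append(row)
    return PWM(id, np.array(rows), np.full(4, 0.25))


class TestReadPfm:
    def test_jaspar_counts_regularized(self, tmp_path):
        f = tmp_path / "m.pfm"
        f.write_text(">M1 M1\nA [ 8 0 ]\nC [ 0 8 ]\nG [ 0 0 ]\nT [ 0 0 ]\n")
        pwm = read_pfm(f)
        assert pwm.consensus == "AC"
        assert (pwm.matrix > 0).all()

    def test_probability_input_preserved_up_to_pseudocount(self):
        text = "0.7 0.1\n0.1 0.7\n0.1 0.1\n0.1 0.1\n"
        pwm = read_pfm(io.StringIO(text), id="P")
        assert pwm.matrix[0, 0] == pytest.approx(0.7, abs=0.01)

    def test_three_row_matrix_rejected(self):
        with pytest.raises(ValueError):
            read_pfm(io.StringIO("1 2\n3 4\n5 6\n"), id="bad")


class TestScan:
    def test_uniform_pwm_scores_zero_everywhere(self):
        hits = scan("ACGTACGT", _uniform_pwm(3))
        assert hits and all(h.score == pytest.approx(0.0) for h in hits)

    def test_hand_summed_log_odds_on_consensus(self):
        # two positions of (0.85, 0.05, 0.05, 0.05) on "AA":
        # 2 * log2(0.85 / 0.25) = 3.5305...
        pwm = _strong_pwm("AA")
        plus = [h for h in scan("AA", pwm) if h.strand == "+"]
        assert plus[0].score == pytest.approx(2 * math.log2(0.85 / 0.25), abs=1e-9)

    def test_reverse_complement_scores_on_minus_strand(self):
        pwm = _strong_pwm("AA")
        minus = [h for h in scan("TT", pwm) if h.strand == "-"]
        assert minus[0].score == pytest.approx(2 * math.log2(0.85 / 0.25), abs=1e-9)

    def test_windows_containing_n_skipped(self):
        hits = scan("AANTT", _strong_pwm("AA"))
        assert {h.offset for h in hits} == {0, 3}

    def test_matches_per_position_bruteforce(self):
        # oracle: naive per-position, per-strand log2-odds summation
        rng = np.random.default_rng(7)
        for _ in range(100):
            L = int(rng.integers(2, 13))
            n = int(rng.integers(L, 201))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            mat = rng.dirichlet(np.full(4, 0.5), size=L) + 1e-4
            mat /= mat.sum(axis=1, keepdims=True)
            pwm = PWM("R", mat, np.full(4, 0.25))
            got = {(h.offset, h.strand): h.score for h in scan(seq, pwm)}
            for o in range(n - L + 1):
                window = seq[o : o + L]
                expect_p = sum(
                    math.log2(mat[j, "ACGT".index(b)] / 0.25)
                    for j, b in enumerate(window)
                )
                rc = window.translate(COMP)[::-1]
                expect_m = sum(
                    math.log2(mat[j, "ACGT".index(b)] / 0.25)
                    for j, b in enumerate(rc)
                )
                assert got[(o, "+")] == pytest.approx(expect_p, abs=1e-9)
                assert got[(o, "-")] == pytest.approx(expect_m, abs=1e-9)

    def test_score_multiset_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(11)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        pwm = _strong_pwm("ACGTT")
        fwd = sorted(round(h.score, 9) for h in scan(seq, pwm))
        rev = sorted(round(h.score, 9) for h in scan(seq.translate(COMP)[::-1], pwm))
        assert fwd == rev


class TestTopScore:
    def test_embedded_consensus_reaches_pwm_maximum(self):
        pwm = _strong_pwm("ACGTAC")
        seq = embed_motif("T" * 200, pwm, 100, "+")
        genome = {"chr1": seq}
        peak = Peak(GenomicInterval("chr1", 0, 200), 100)
        assert top_motif_score(peak, genome, pwm, 50) == pytest.approx(pwm.max_score)

    def test_all_n_sequence_gives_sentinel(self):
        genome = {"chr1": "N" * 100}
        peak = Peak(GenomicInterval("chr1", 0, 100), 50)
        assert top_motif_score(peak, genome, _strong_pwm("AA"), 20) == NEG_INF

    def test_both_strand_max_at_least_plus_strand_max(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        genome = {"chr1": seq}
        pwm = _strong_pwm("GATTAC")
        peak = Peak(GenomicInterval("chr1", 0, 300), 150)
        both = top_motif_score(peak, genome, pwm, 100)
        plus = max(
            h.score for h in scan(seq[50:250], pwm) if h.strand == "+"
        )
        assert both >= plus


class TestDistribution:
    def _region(self):
        return Peak(GenomicInterval("chr1", 0, 1500), 750, 0.0, "r0")

    def test_hit_at_summit_lands_in_central_bin(self):
        pwm = _strong_pwm("ACGTACGT")  # L=8, centre offset +4
        hit = MotifHit("S", "r0", 746, "+", 10.0)
        m = motif_distribution([self._region()], {"r0": [hit]}, [pwm], 1500, 30)
        assert m.shape == (1, 50, 1)
        assert m[0, 25, 0] == 1 and m.sum() == 1

    def test_hit_40bp_right_of_summit_in_bin_26(self):
        pwm = _strong_pwm("ACGTACGT")
        hit = MotifHit("S", "r0", 786, "+", 10.0)  # centre 790 -> floor(790/30)=26
        m = motif_distribution([self._region()], {"r0": [hit]}, [pwm], 1500, 30)
        assert m[0, 26, 0] == 1

    def test_no_hits_gives_zero_matrix(self):
        m = motif_distribution([self._region()], {}, [_strong_pwm("AA")], 1500, 30)
        assert m.sum() == 0

    def test_hits_outside_frame_dropped(self):
        pwm = _strong_pwm("AC")
        region = Peak(GenomicInterval("chr1", 0, 5000), 2500, 0.0, "r0")
        far = MotifHit("S", "r0", 4000, "+", 10.0)
        m = motif_distribution([region], {"r0": [far]}, [pwm], 1500, 30)
        assert m.sum() == 0


class TestPresenceClusters:
    def test_patterns_follow_ordered_subset(self):
        hits = {"r1": [MotifHit("ERE", "r1", 0, "+", 9.0)], "r2": []}
        labels = cluster_by_motif_presence(["r1", "r2"], hits, ["ERE", "TEAD"])
        assert labels == {"r1": "10", "r2": "00"}

    def test_identical_hit_sets_get_identical_labels(self):
        h = [MotifHit("A", "x", 0, "+", 1.0)]
        labels = cluster_by_motif_presence(["r1", "r2"], {"r1": h, "r2": list(h)}, ["A"])
        assert labels["r1"] == labels["r2"]


class TestEnrichment:
    def test_equal_rates_closed_form_tail(self):
        # 5/10 targets at background rate 0.5: P(X >= 5 | 10, 0.5) = 0.623
        t = [1.0] * 5 + [-1.0] * 5
        b = [1.0] * 50 + [-1.0] * 50
        frac_t, frac_b, p = enrichment_test(t, b, 0.0)
        assert (frac_t, frac_b) == (0.5, 0.5)
        assert p == pytest.approx(0.623046875, abs=1e-9)

    def test_strong_enrichment_closed_form_tail(self):
        # 8/10 targets at rate 0.2: sum_{k=8..10} C(10,k) 0.2^k 0.8^(10-k)
        t = [1.0] * 8 + [-1.0] * 2
        b = [1.0] * 20 + [-1.0] * 80
        _, _, p = enrichment_test(t, b, 0.0)
        assert p == pytest.approx(7.79264e-5, rel=1e-4)

    def test_zero_target_hits_gives_p_one(self):
        assert enrichment_test([-1.0] * 5, [1.0] * 5, 0.0)[2] == 1.0

    def test_zero_background_rate_regularized(self):
        frac_t, frac_b, p = enrichment_test([1.0] * 5, [-1.0] * 9, 0.0)
        assert frac_b == 0.0
        assert p == pytest.approx(0.1 ** 5, rel=1e-6)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([], [1.0], 0.0)


class TestThreshold:
    def test_bimodal_scores_threshold_before_signal_mode(self):
        # oracle: direct histogram construction — bins of width 1 from 2.1;
        # the 10.2 spike falls in bin 8 with left edge 10.1
        scores = [2.1] * 100 + [10.2] * 30
        t = select_score_threshold(scores, "m")
        assert t.provenance == "heuristic"
        assert t.threshold == pytest.approx(10.1)

    def test_unimodal_scores_use_single_mode(self):
        t = select_score_threshold([5.0] * 50, "m")
        assert t.threshold == pytest.approx(5.0)

    def test_manual_override_wins(self):
        t = select_score_threshold([2.0] * 100, "m", manual=8.0)
        assert (t.threshold, t.provenance) == (8.0, "manual")

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="manual"):
            select_score_threshold([1.0] * 19, "m")
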