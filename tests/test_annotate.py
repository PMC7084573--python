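import numpy as np
import pandas as pd
import pytest

from secistrome.annotate import (
    SIMILAR,
    ExpressionClass,
    ExpressionMatrix,
    GeneModel,
    annotate_se,
    classify_expression,
    expression_summary,
    read_gene_models,
)
from secistrome.core import AnalysisConfig, GenomicInterval


def _gene(gene_id, tss, strand="+", coding=True, chrom="chr1", body=10_000):
    if strand == "+":
        start, end = tss, tss + body
    else:
        start, end = tss - body, tss + 1
    return GeneModel(gene_id, chrom, strand, tss, start, end, coding)


def _expr(values_by_sample, metadata):
    fpkm = pd.DataFrame(values_by_sample)
    samples = pd.DataFrame(metadata, columns=["sample", "cell_line", "timepoint_min", "replicate"])
    return ExpressionMatrix(fpkm, samples)


def _simple_expr(a_reps, b_reps, gene="g"):
    data = {}
    meta = []
    for i, v in enumerate(a_reps, 1):
        data[f"A_r{i}"] = {gene: v}
        meta.append((f"A_r{i}", "cellA", 320, i))
    for i, v in enumerate(b_reps, 1):
        data[f"B_r{i}"] = {gene: v}
        meta.append((f"B_r{i}", "cellB", 240, i))
    return _expr(data, meta)


class TestAnnotate:
    SE = GenomicInterval("chr1", 500_000, 520_000)  # centre 510 000

    def test_highest_expressed_promoter_in_window_wins(self):
        genes = [_gene("G1", 520_000), _gene("G2", 580_000)]
        gid, rule = annotate_se(self.SE, genes, {"G1": 5.0, "G2": 50.0})
        assert (gid, rule) == ("G2", "promoter_overlap")

    def test_fallback_requires_min_fpkm(self):
        # no promoter within +/-100 kb; nearest gene under 1 FPKM is skipped
        genes = [_gene("NEAR", 700_000), _gene("FAR", 800_000)]
        gid, rule = annotate_se(self.SE, genes, {"NEAR": 0.5, "FAR": 3.0})
        assert (gid, rule) == ("FAR", "nearest_fallback")

    def test_noncoding_genes_ignored(self):
        genes = [_gene("LNC", 510_000, coding=False), _gene("PC", 560_000)]
        gid, _ = annotate_se(self.SE, genes, {"LNC": 100.0, "PC": 2.0})
        assert gid == "PC"

    def test_no_candidate_returns_none(self):
        genes = [_gene("OTHER", 100_000, chrom="chr9")]
        gid, rule = annotate_se(self.SE, genes, {"OTHER": 50.0})
        assert (gid, rule) == (None, "none")

    def test_deterministic_under_gene_permutation(self):
        rng = np.random.default_rng(4)
        genes = [_gene(f"G{i}", int(rng.integers(400_000, 620_000))) for i in range(20)]
        means = {g.gene_id: float(rng.gamma(2, 5)) for g in genes}
        base = annotate_se(self.SE, genes, means)
        for _ in range(5):
            rng.shuffle(genes)
            assert annotate_se(self.SE, genes, means) == base

    def test_empty_gene_model_rejected(self):
        with pytest.raises(ValueError):
            annotate_se(self.SE, [], {})

    def test_minus_strand_promoter_extends_downstream_of_tss(self):
        g = _gene("G", 10_000, strand="-")
        prom = g.promoter(1000, 100)
        assert (prom.start, prom.end) == (9_900, 11_000)


class TestClassifyExpression:
    def test_near_equal_replicates_similar(self):
        expr = _simple_expr([10, 12], [10, 11])
        assert classify_expression(expr, "g", "cellA", "cellB", 320, 240).label == SIMILAR

    def test_strong_skew_is_cell_specific_all_pairs(self):
        # min pair fold = 50.1/6.1 = 8.21 > 2 -> A-specific
        expr = _simple_expr([50, 60], [5, 6])
        c = classify_expression(expr, "g", "cellA", "cellB", 320, 240)
        assert c.label == "A_SPECIFIC"
        assert min(c.pair_folds) == pytest.approx(50.1 / 6.1)

    def test_exactly_twofold_is_similar_strict_band(self):
        # 20.1/10.1 = 1.990: the strict > threshold is not met
        expr = _simple_expr([20, 20], [10, 10])
        c = classify_expression(expr, "g", "cellA", "cellB", 320, 240)
        assert c.label == SIMILAR
        assert c.pair_folds[0] == pytest.approx(20.1 / 10.1)

    def test_antisymmetric_under_cell_line_swap(self):
        expr = _simple_expr([50, 60], [5, 6])
        fwd = classify_expression(expr, "g", "cellA", "cellB", 320, 240)
        rev = classify_expression(expr, "g", "cellB", "cellA", 240, 320)
        assert (fwd.label, rev.label) == ("A_SPECIFIC", "B_SPECIFIC")

    def test_one_discordant_pair_blocks_specific_call(self):
        expr = _simple_expr([50, 3], [5, 6])
        assert classify_expression(expr, "g", "cellA", "cellB", 320, 240).label == SIMILAR

    def test_missing_replicate_rejected(self):
        expr = _simple_expr([10], [10, 11])
        with pytest.raises(ValueError, match="replicates"):
            classify_expression(expr, "g", "cellA", "cellB", 320, 240)


class TestSummary:
    def test_all_similar_is_100_percent(self):
        classes = [ExpressionClass(f"g{i}", SIMILAR, (1.0,)) for i in range(4)]
        table = expression_summary({"SHARED": classes})
        assert table.loc["SHARED", "pct_similar"] == 100.0

    def test_counts_conserved_and_deduplicated(self):
        classes = [
            ExpressionClass("g1", SIMILAR, (1.0,)),
            ExpressionClass("g1", SIMILAR, (1.0,)),  # same gene, two SEs
            ExpressionClass("g2", "A_SPECIFIC", (5.0,)),
        ]
        table = expression_summary({"A_SPECIFIC": classes})
        row = table.loc["A_SPECIFIC"]
        assert row["n_genes"] == 2
        assert row["n_similar"] + row["n_a_specific"] + row["n_b_specific"] == 2

    def test_empty_label_gives_zero_row_without_division_error(self):
        table = expression_summary({"SHARED": []})
        assert table.loc["SHARED", "n_genes"] == 0
        assert table.loc["SHARED", "pct_similar"] == 0.0


def test_gene_model_tsv_round_trip(tmp_path):
    f = tmp_path / "genes.tsv"
    f.write_text(
        "gene_id\tchrom\tstrand\ttss\tstart\tend\tbiotype\n"
        "G1\tchr1\t+\t100\t100\t5000\tprotein_coding\n"
        "L1\tchr1\t-\t9000\t4000\t9001\tlincRNA\n"
    )
    genes = read_gene_models(f)
    assert [g.gene_id for g in genes] == ["G1", "L1"]
    assert genes[1].is_protein_coding is False
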