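"""SE-to-gene annotation and replicate-aware 2-fold expression comparison.

A super-enhancer is extended +/- 100 kb around its centre; the highest
expressed protein-coding gene whose promoter overlaps the extension is
assigned to it. If no promoter falls in the window, the nearest
protein-coding gene (by TSS distance on the same chromosome) with at least
1 FPKM is assigned instead. Genes are then classed SIMILAR or
cell-line-specific by whether every cross-line replicate FPKM ratio exceeds
a 2-fold band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AnalysisConfig, GenomicInterval

__all__ = [
    "GeneModel",
    "ExpressionMatrix",
    "ExpressionClass",
    "read_gene_models",
    "annotate_se",
    "classify_expression",
    "expression_summary",
    "SIMILAR",
]

SIMILAR = "SIMILAR"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    start: int
    end: int
    is_protein_coding: bool

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"{self.gene_id}: TSS outside gene body")

    def promoter(self, upstream: int = 1000, downstream: int = 100) -> GenomicInterval:
        """Strand-oriented promoter window around the TSS."""
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream, self.tss + upstream
        return GenomicInterval(self.chrom, max(0, lo), max(1, hi))


def read_gene_models(path) -> List[GeneModel]:
    """Read a gene model TSV: gene_id, chrom, strand, tss, start, end, biotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "strand", "tss", "start", "end", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneModel(
            str(r.gene_id),
            str(r.chrom),
            str(r.strand),
            int(r.tss),
            int(r.start),
            int(r.end),
            str(r.biotype) == "protein_coding",
        )
        for r in df.itertuples()
    ]


class ExpressionMatrix:
    """Gene x sample FPKM with (cell line, timepoint, replicate) metadata."""

    def __init__(self, fpkm: pd.DataFrame, samples: pd.DataFrame) -> None:
        required = {"sample", "cell_line", "timepoint_min", "replicate"}
        missing = required - set(samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns {sorted(missing)}")
        unknown = set(fpkm.columns) - set(samples["sample"])
        if unknown:
            raise ValueError(f"samples without metadata: {sorted(unknown)}")
        if (fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be >= 0")
        self.fpkm = fpkm
        self.samples = samples.set_index("sample", drop=False)

    @classmethod
    def from_files(cls, fpkm_path, samples_path) -> "ExpressionMatrix":
        fpkm = pd.read_csv(fpkm_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(fpkm, samples)

    def replicate_values(
        self, gene_id: str, cell_line: str, timepoint_min: int
    ) -> np.ndarray:
        mask = (self.samples["cell_line"] == cell_line) & (
            self.samples["timepoint_min"] == timepoint_min
        )
        cols = self.samples.loc[mask].sort_values("replicate")["sample"]
        if gene_id not in self.fpkm.index:
            raise KeyError(f"gene {gene_id} not in expression matrix")
        return self.fpkm.loc[gene_id, cols].to_numpy(dtype=float)

    def mean_fpkm(self, gene_id: str, cell_line: str, timepoint_min: int) -> float:
        return float(self.replicate_values(gene_id, cell_line, timepoint_min).mean())


@dataclass(frozen=True)
class ExpressionClass:
    gene_id: str
    label: str  # SIMILAR / A_SPECIFIC / B_SPECIFIC
    pair_folds: Tuple[float, ...]  # A-over-B fold per cross-line replicate pair


def annotate_se(
    se_region: GenomicInterval,
    genes: Sequence[GeneModel],
    mean_expression: Dict[str, float],
    config: Optional[AnalysisConfig] = None,
) -> Tuple[Optional[str], str]:
    """Assign a gene to a super-enhancer region.

    ``mean_expression`` maps gene id to the replicate-mean FPKM to rank by
    (the caller picks cell line and timepoint). Primary rule: among
    protein-coding genes whose promoter overlaps the SE centre +/- 100 kb
    window, the highest expressed wins (ties: nearest TSS to the centre,
    then lexicographic id). Fallback: nearest protein-coding gene on the
    same chromosome with mean FPKM >= 1. Returns (gene_id or None, rule),
    rule in {"promoter_overlap", "nearest_fallback", "none"}.
    """
    if not genes:
        raise ValueError("empty gene model")
    cfg = config or AnalysisConfig()
    center = se_region.center
    window = GenomicInterval(
        se_region.chrom,
        max(0, center - cfg.annot_halfwidth_bp),
        center + cfg.annot_halfwidth_bp,
    )
    coding = [g for g in genes if g.is_protein_coding]

    def expr(g: GeneModel) -> float:
        return float(mean_expression.get(g.gene_id, 0.0))

    in_window = [
        g
        for g in coding
        if g.chrom == window.chrom
        and g.promoter(cfg.promoter_upstream_bp, cfg.promoter_downstream_bp).start
        < window.end
        and g.promoter(cfg.promoter_upstream_bp, cfg.promoter_downstream_bp).end
        > window.start
    ]
    if in_window:
        best = min(
            in_window, key=lambda g: (-expr(g), abs(g.tss - center), g.gene_id)
        )
        return best.gene_id, "promoter_overlap"
    expressed = [
        g
        for g in coding
        if g.chrom == se_region.chrom and expr(g) >= cfg.min_fpkm
    ]
    if expressed:
        best = min(expressed, key=lambda g: (abs(g.tss - center), g.gene_id))
        return best.gene_id, "nearest_fallback"
    return None, "none"


def classify_expression(
    expr: ExpressionMatrix,
    gene_id: str,
    cell_a: str,
    cell_b: str,
    timepoint_a: int,
    timepoint_b: int,
    fold_threshold: float = 2.0,
    pseudocount: float = 0.1,
    label_a: str = "A_SPECIFIC",
    label_b: str = "B_SPECIFIC",
) -> ExpressionClass:
    """Classify one gene by the 2-fold band over all cross-line replicate pairs.

    fold = (FPKM_A + c) / (FPKM_B + c) for every (replicate_A, replicate_B)
    pair. The gene is A-specific iff ALL pairs exceed the threshold,
    B-specific iff ALL pairs fall below 1/threshold, otherwise SIMILAR
    (exactly-threshold folds are SIMILAR: the band is exceeded strictly).
    """
    a = expr.replicate_values(gene_id, cell_a, timepoint_a)
    b = expr.replicate_values(gene_id, cell_b, timepoint_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"{gene_id}: need >=2 replicates per cell line "
            f"(got {len(a)} for {cell_a}, {len(b)} for {cell_b})"
        )
    folds = tuple(
        float((va + pseudocount) / (vb + pseudocount)) for va in a for vb in b
    )
    if all(f > fold_threshold for f in folds):
        label = label_a
    elif all(f < 1.0 / fold_threshold for f in folds):
        label = label_b
    else:
        label = SIMILAR
    return ExpressionClass(gene_id, label, folds)


def expression_summary(
    classes_by_se_label: Dict[str, Sequence[ExpressionClass]],
    label_a: str = "A_SPECIFIC",
    label_b: str = "B_SPECIFIC",
) -> pd.DataFrame:
    """Counts and percentages of expression classes per SE label.

    A gene annotated to several SEs of the same label is counted once for
    that label. Empty label sets produce a zero row.
    """
    rows = {}
    for se_label, classes in classes_by_se_label.items():
        seen = {}
        for c in classes:
            seen[c.gene_id] = c.label
        n = len(seen)
        counts = {
            SIMILAR: sum(1 for v in seen.values() if v == SIMILAR),
            label_a: sum(1 for v in seen.values() if v == label_a),
            label_b: sum(1 for v in seen.values() if v == label_b),
        }
        row = {"n_genes": n}
        for k, v in counts.items():
            row[f"n_{k.lower()}"] = v
            row[f"pct_{k.lower()}"] = 100.0 * v / n if n else 0.0
        rows[se_label] = row
    return pd.DataFrame(rows).T
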