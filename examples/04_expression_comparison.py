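"""Annotate SEs to genes and compare expression with the 2-fold band.

Each SE is extended by 100 kb around its centre and assigned the highest
expressed protein-coding gene with a promoter in the window (nearest
expressed gene as fallback); genes are then classed SIMILAR or
cell-line-specific by whether every cross-line replicate FPKM ratio
exceeds a 2-fold band.
"""

import tempfile
from pathlib import Path

from secistrome import pipeline as pl
from secistrome.annotate import ExpressionMatrix, classify_expression
from secistrome.simulate import ScenarioParams, generate_scenario

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_scenario(ScenarioParams(seed=42), Path(tmp) / "scenario")
    config = pl.validate_config(bundle.config_path)
    res = pl.run_pipeline(config, Path(tmp) / "results")

    print("expression classes of SE-annotated genes, per SE set:")
    print(res["expression_summary"].round(1).to_string())

    expr = ExpressionMatrix.from_files(bundle.fpkm_table, bundle.sample_metadata)
    hits = {"SIMILAR": 0, "specific": 0}
    n = {"SIMILAR": 0, "specific": 0}
    for g in bundle.truth["genes"]:
        c = classify_expression(expr, g["gene_id"], "cellA", "cellB", 320, 240)
        key = "SIMILAR" if g["expected_class"] == "SIMILAR" else "specific"
        n[key] += 1
        hits[key] += c.label == g["expected_class"]
    print(
        f"\nplanted-gene recovery: {hits['SIMILAR']}/{n['SIMILAR']} shared-SE genes SIMILAR, "
        f"{hits['specific']}/{n['specific']} specific-SE genes correctly line-specific"
    )

# Genes under shared SEs are expressed alike in both lines (grey in a
# fold-change scatter); genes under line-specific SEs exceed the 2-fold
# band in every replicate pair, in the direction of their own cell line.
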