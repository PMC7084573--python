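"""Compare two cistromes: constituent clusters and shared-SE composition.

Runs the full pipeline on the default synthetic scenario and reports the
three constituent clusters (A-specific / shared / B-specific), their
abundance ratios, and how many constituents the shared SEs actually share.
"""

import tempfile
from pathlib import Path

from secistrome import pipeline as pl
from secistrome.compare import cluster_abundance_ratios
from secistrome.simulate import ScenarioParams, generate_scenario

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_scenario(ScenarioParams(seed=42), Path(tmp) / "scenario")
    config = pl.validate_config(bundle.config_path)
    res = pl.run_pipeline(config, Path(tmp) / "results")

    counts = res["label_counts"]
    a, s, b = counts["A_SPECIFIC"], counts["SHARED"], counts["B_SPECIFIC"]
    ra, rb = cluster_abundance_ratios(a, s, b)
    print(f"constituent clusters: {a} A-specific, {s} shared, {b} B-specific")
    print(f"specific-over-shared abundance ratios: A {ra:.1f}x, B {rb:.1f}x")

    totals = res["breakdown_totals"]
    n_hulls = len(res["hulls"])
    in_hulls = sum(totals.values())
    print(
        f"shared SE regions: {n_hulls}; of their {in_hulls} constituents only "
        f"{totals['SHARED']} ({100 * totals['SHARED'] / in_hulls:.0f}%) are bound in both lines"
    )

# Shared SEs overlap between the cell lines, yet most of their constituent
# binding sites are line-specific — the hallmark of a shared regulatory
# region rebuilt from different parts in each cell type.
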