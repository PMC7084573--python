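"""Motif scanning, score thresholds and known-motif enrichment per cluster.

Scans every SE constituent with the PWM set, picks score thresholds from
the score distributions, and tests each motif's enrichment in each
constituent cluster against random background regions (binomial tail).
"""

import tempfile
from pathlib import Path

from secistrome import pipeline as pl
from secistrome.simulate import ScenarioParams, generate_scenario

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_scenario(ScenarioParams(seed=42), Path(tmp) / "scenario")
    config = pl.validate_config(bundle.config_path)
    res = pl.run_pipeline(config, Path(tmp) / "results")

    print("threshold per motif (bits):")
    for mid, thr in res["thresholds"].items():
        print(f"  {mid:7s} {thr.threshold:6.2f}  ({thr.provenance})")

    print("\ncluster      motif   target  background  p-value")
    for (label, mid), (ft, fb, p) in sorted(res["enrichment"].items()):
        if p < 1e-3 or mid == "CEBP":
            print(f"{label:12s} {mid:7s} {ft:6.1%}  {fb:9.1%}  {p:9.2e}")

# Planted motifs (ERE in shared, FOX/AP2 in A-specific, TEAD/TCF in
# B-specific) come out strongly enriched; the C/EBP-type control, which the
# generator never plants, stays at background rates in every cluster.
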