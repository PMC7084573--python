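# secistrome

Comparative super-enhancer (SE) analysis of one master transcription
factor's cistrome in two cell lines — the analysis pattern behind studies
of, e.g., estrogen receptor alpha (ERα) in breast-cancer (MCF-7) versus
endometrial-cancer (Ishikawa) cells. The package takes called ChIP-seq
peaks, coverage tracks, a genome, motif matrices, a gene model and an FPKM
table for each cell line, and produces: SE calls, the three-way
constituent classification (A-specific / shared / B-specific), the motif
landscape around constituent summits, TF co-occupancy matrices, shared-SE
composition, SE-to-gene annotations and a replicate-aware expression
comparison. A first-class synthetic-data generator with planted ground
truth makes every stage testable without any downloads.

## The method in brief

**SE calling (ROSE-style).** Peaks closer than 12.5 kb (edge-to-edge,
strict) are stitched into candidate regions. Each candidate's tag density
is

    d = (reads in region / region length) / (library size / 10^6)   [rpm/bp]

Candidates are ranked by ascending density; with rank scaled to
x = i/(n−1) and density scaled to y = d/d_max, the cutoff is the tangent
point of a slope-1 line on the curve — the discrete argmin of (y − x),
ties to the larger index. Candidates strictly above the cutoff are
super-enhancers.

**Constituent classification.** SE constituents from the two lines are
SHARED when peaks overlap across lines (≥1 bp, half-open; overlapping
peaks merge, the stronger member keeps the summit), otherwise labelled by
their line of origin. The heat-map sort key is
log2(RPKM_B + 0.1) − log2(RPKM_A + 0.1), where RPKM is computed on
summit ± 50 bp windows.

**Motif landscape.** Position probability matrices are scored as summed
log2-odds against a uniform background on both strands. Per constituent
the top score in the summit ± 100 bp window is kept; a per-motif score
threshold is selected just below the last high mode of the score
distribution (manual overrides supported); thresholded hits are binned in
30-bp windows within 1.5-kb frames for distribution matrices, and
known-motif enrichment per cluster is a binomial upper tail against the
hit rate in random background regions.

**Annotation and expression.** Each SE is extended ±100 kb around its
centre; the highest expressed protein-coding gene with a promoter
(TSS −1000/+100, strand-aware) in the window is assigned, else the nearest
protein-coding gene with ≥1 FPKM. A gene is cell-line-specific when
*every* cross-line replicate pair of (FPKM + 0.1) ratios exceeds 2-fold in
the same direction, SIMILAR otherwise.

## Worked example

```bash
python examples/02_cistrome_comparison.py
```

prints (default synthetic scenario, seed 42):

```
constituent clusters: 53 A-specific, 13 shared, 46 B-specific
specific-over-shared abundance ratios: A 4.1x, B 3.5x
shared SE regions: 10; of their 34 constituents only 13 (38%) are bound in both lines
```

Reading: most SE constituents are specific to one cell line even though
the SE *regions* overlap — the shared SEs are rebuilt from different
binding sites in each line. `examples/01_superenhancer_calling.py` shows
the slope-1 cutoff recovering exactly the 20 planted SEs of one line,
`examples/03_motif_landscape.py` the planted-motif enrichment
(ERE in shared constituents at p ≈ 5e-32, FOX/AP2 and TEAD/TCF in the
specific clusters, a never-planted C/EBP control flat at background), and
`examples/04_expression_comparison.py` the 2-fold expression classes
(10/10 shared-SE genes SIMILAR, 19/20 specific-SE genes called for their
own line).

The same analysis is available as a CLI:

```bash
secistrome simulate --seed 7 --outdir scenario
secistrome all --config scenario/config.yaml --outdir results
```

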