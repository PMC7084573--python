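# Methods

## Scope and model

The package implements a two-cistrome comparison for a single master TF:
which stitched enhancer clusters qualify as super-enhancers in each cell
line, how their constituent binding sites partition into line-specific and
shared sets, which DNA motifs and collaborating TFs underlie each set, and
what the associated genes do transcriptionally. All coordinates are
0-based half-open throughout (BED/narrowPeak native); any 1-based input
would need conversion at the boundary. A summit window of half-width *h*
is `[summit − h, summit + h)`, length exactly 2*h* (so "±50 bp" is a
100-bp window) — chosen over 2*h*+1 so downstream 30-bp binning divides
evenly.

## Coverage and RPKM

Coverage tracks are step functions whose values are read counts (binned
read 5' starts); library size is supplied separately because it comes
from the alignment, not the track. A read counts toward a window when its
stored interval overlaps the window by ≥1 bp (default) or, behind the
`read_count_mode="five_prime"` toggle, when its start lies inside the
window; whole reads are counted, never fractions. RPKM is
reads / (window kb × library millions), invariant under joint scaling of
counts and library size.

## SE calling

Stitching merges peaks whose edge-to-edge gap is strictly below 12.5 kb,
transitively per chromosome; the candidate region is the constituent
hull. Gaps are measured between interval edges, not summits — the
reproducible, conservative reading of "closer than". Blacklist filtering
runs before stitching, so artifact pileups can never seed a candidate.
Ranking uses tag density in rpm/bp with deterministic tie-breaks (region
start, then chromosome). The cutoff is the discrete argmin of
(y_scaled − x_scaled), equivalent to the tangent point of a slope-1 line
for convex curves and exactly testable against enumeration; ties resolve
to the largest index so a flat curve yields zero SEs, and the tangent
candidate itself is *not* an SE ("above slope 1" read strictly). Only the
master-TF track defines SEs; H3K27ac/MED1-based definitions are out of
scope. A caveat worth knowing: with few candidates, a single extreme
density outlier compresses the scaled curve and can push the tangent
point into the signal block — with thousands of real enhancers this is
immaterial, and the synthetic scenario avoids planting such degenerate
regions (see below).

## Constituent classification

SHARED means cross-line peak overlap (≥1 bp); overlap components merge
into one constituent whose summit comes from the higher-RPKM member
(deterministic, favours the stronger signal). The RPKM log-ratio
log2(RPKM_B + 0.1) − log2(RPKM_A + 0.1) is only the heat-map sort key,
not the cluster rule: an explicit ratio threshold would need an arbitrary
cut, while overlap matches how cross-line peak agreement is usually
counted. Both interpretations exist in the code; overlap is the default.

## Motif engine

PFMs (JASPAR layout, parsed via Biopython) are row-normalised with a
0.001 pseudocount so log-odds are finite. Scores are summed
log2(p/background) in bits, uniform background by default; the minus
strand scores the reverse complement, windows containing N are skipped.
The distribution matrix bins hit *centres* (offset + L//2) in 30-bp
windows within 1.5-kb frames (50 bins); hits are thresholded first.
Threshold selection operationalises "just before the last markedly high
peak of the score distribution" as: histogram at 1-bit bins, keep local
maxima at least 2× the median bin height, return the left edge of the
rightmost such bin; the 2× knob is exposed and a per-motif manual
override always wins. This heuristic is a stand-in — the original
rule was visual and its thresholds are not recoverable. Enrichment is a
binomial upper tail P(X ≥ k | n_target, background rate) — background
treated as a rate rather than hypergeometric sampling, which is standard
practice for large background sets and numerically stable; an empty
background with target hits uses rate 1/(n_bg + 1). Known-motif scanning
replaces de novo discovery deliberately: discovery is a separate research
artifact, and enrichment of a user-supplied motif set answers the
comparative question.

## Co-occupancy and composition

The density matrix is RPKM of every constituent in every
(TF, treatment, cell line) track; correlations are Pearson on
log2(RPKM + 0.1) because raw densities are heavy-tailed (raw scale is a
toggle); zero-variance columns give NaN, never 0. A collaborator binds a
constituent when one of its peaks overlaps summit ± 100 bp; co-binding
fractions report ≥2 collaborators and the ≤1 complement, which partition
to 1. Motif composition assigns each constituent exactly one category —
its single present motif, "multiple" (combination recorded), or "none" —
so percentages sum to 100 per cluster.

## Annotation and expression

SEs extend ±100 kb around their centre. Promoters default to TSS
−1000/+100 strand-aware (the common convention; the extent was not
otherwise specified), mirrored for minus-strand genes. Ties on expression
break by TSS distance then gene id, so annotation is invariant to gene
order. The fallback (nearest protein-coding gene with ≥1 FPKM) searches
the SE's chromosome: cross-chromosome TSS distance is undefined.
"Highest expressed" uses the replicate mean at one stated timepoint per
line (320 min for line A, 240 min for line B, the ligand-treatment
analogs); shared SEs rank genes by the across-line mean since neither
line is privileged. Expression classes use fold = (FPKM + 0.1)/(FPKM + 0.1)
for *every* cross-line replicate pair; a gene is line-specific only when
all pairs exceed 2-fold in the same direction (strict >, so an
exactly-2-fold gene is SIMILAR). The all-pairs rule is the conservative
reading of "between both replicates"; a replicate-mean variant is a
toggle.

## Synthetic scenario

The generator emulates the data structure of the real comparison: 2
chromosomes × 2 Mb of uniform-random sequence; 10 shared + 10 A-specific
+ 10 B-specific SEs of 3–5 constituents (300-bp peaks, 1.5–2.5 kb apart);
40 singleton background enhancers per line (15–40 reads over 1 kb);
Poisson background of 2e-4 reads/bp; planted constituents get 200–400
reads. Shared SEs nucleate on an ERE-bearing "mother" constituent present
in both lines and must look SE-like in both cistromes, so each line gets
at least one further co-present constituent; remaining constituents are a
~35/35/30 mix of shared and line-specific sites, which reproduces the
observation that overlapping SEs share only a minority of their binding
sites. Constituents carry motifs according to their own character (ERE ±
NR half-site when shared; FOX/AP2 when A-specific; TEAD/TCF/SIX when
B-specific; some none), embedded as PWM consensus at the summit;
a C/EBP-type motif exists in the PFM set but is never planted, serving as
the negative control. Collaborator TFs get peaks and tracks wherever
their motif is planted in their own line; vehicle-treatment master-TF
tracks carry signal only at mother constituents (hub enhancers active
before ligand). Blacklist regions contain decoy peak clusters with
artifact-scale coverage, so skipping the filter visibly corrupts the rank
curve. Regions are laid out on a jittered grid whose pitch guarantees
>12.5 kb clearance; an infeasible layout raises an error suggesting a
larger genome.

Expression: each SE gets one protein-coding gene (TSS 5–30 kb from the SE
centre, lognormal base FPKM with ln-mean 3.4), shared-SE genes share one
base value across lines, specific-SE genes are divided by a 4-fold effect
in the other line; ~30% of SEs also get a high-expressed non-coding decoy
(exercises the biotype filter), and background genes (ln-mean 1.0) fill
the table to 200. Replicate noise is multiplicative lognormal with
σ = 0.25, at which essentially no equal-mean gene escapes the 2-fold
band on all four replicate pairs by chance (≪5%), while a 4-fold effect
crosses the band in every pair for ~92% of genes — so a few specific-SE
genes per seed may legitimately classify SIMILAR; the strictness is the
point of the all-pairs rule. All randomness flows from one seed through
named substreams, and every emitted file (FASTA, narrowPeak, bedGraph,
TSVs, PFMs, truth JSON, pipeline config with relative paths) is
byte-identical across reruns.

What the generator does not emulate — mappability structure, GC bias,
fragment-length effects, peak-shape asymmetry, chromatin contact
information, transient induction kinetics — bounds what passing tests
show: they validate the analysis logic end to end, not robustness to
real-data artifacts.

## Problem sizes and numerics

The default scenario (4 Mb genome, ~120 master-TF peaks/line, 8 PWMs,
500 background regions, 200 genes) runs the full pipeline in a few
seconds, so the test suite and the acceptance script regenerate it from
scratch. Score comparisons in oracle tests use 1e-9 bits; correlation
degeneracy uses a relative 1e-12 guard on column standard deviation;
the RPKM pseudocount (0.1) is reused as the correlation offset.
Degenerate inputs are defined choices, not accidents: empty blacklist is
identity, all-zero rank densities and empty targets are errors, an all-N
window yields a −inf top score, an empty SE-label set yields a zero
summary row.

## Known limitations

- The slope-1 cutoff assumes an approximately convex scaled rank curve;
  tiny candidate sets with extreme outliers can misplace it (see above).
- Score thresholds from the histogram heuristic differ from the original
  visually chosen ones; headline motif percentages therefore depend on
  the threshold knob.
- Annotation without chromatin-contact data is heuristic; the highest
  expressed promoter in ±100 kb may belong to a neighbouring locus, and
  the pipeline reports the rule used per SE rather than pretending
  certainty.
- FPKM tables are consumed as given; no normalisation or differential
  testing beyond the 2-fold band is performed.
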