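"""Synthetic two-cell-line SE dataset with planted ground truth.

The generator emulates the structure of a two-cistrome comparison driven by
one master TF (the estrogen-receptor setting): a set of super-enhancers
shared between cell lines A and B, nucleated by a strong canonical-motif
("mother") constituent present in both lines; A-specific SEs whose
constituents carry pioneer-factor-type motifs (FOX/AP2 analogs) and peaks
only in line A; B-specific SEs carrying TEAD/TCF/SIX-type motifs and peaks
only in line B; singleton background enhancers per line; Poisson read
background plus enrichment at planted peaks; blacklist regions containing
decoy peak clusters; and an FPKM table in which shared-SE genes are
expressed alike in both lines while specific-SE genes are skewed by a fixed
fold effect. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .motifs import PWM

__all__ = ["ScenarioParams", "ScenarioBundle", "generate_scenario", "embed_motif",
           "builtin_motifs"]

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

# Consensus patterns for the built-in motif set (N = unconstrained position).
# These are synthetic stand-ins shaped like the canonical family motifs:
# a palindromic nuclear-receptor element (ERE), forkhead (FOX), AP-2 (AP2),
# TEA-domain (TEAD), E-box (TCF), homeodomain (SIX), a single NR half-site,
# and a C/EBP-type control that the generator never plants.
_MOTIF_CONSENSUS = {
    "ERE": "GGTCANNNTGACC",
    "FOX": "TGTTTACA",
    "AP2": "GCCTGAGGC",
    "TEAD": "AGGAATGT",
    "TCF": "AACAGCTG",
    "SIX": "TGATACCT",
    "NRHALF": "AGGTCA",
    "CEBP": "TTGCGCAA",
}


def _counts_from_consensus(consensus: str, strength: int = 17) -> np.ndarray:
    rows = []
    for base in consensus:
        if base == "N":
            rows.append([5, 5, 5, 5])
        else:
            row = [1, 1, 1, 1]
            row[_BASES.index(base)] = strength
            rows.append(row)
    return np.array(rows, dtype=float)


def builtin_motifs() -> Dict[str, PWM]:
    """The generator's motif set as regularized PWMs."""
    return {
        name: PWM.from_counts(name, _counts_from_consensus(cons))
        for name, cons in _MOTIF_CONSENSUS.items()
    }


@dataclass
class ScenarioParams:
    """Study conditions of the default synthetic scenario.

    Sized so the full pipeline runs in well under a minute: 2 chromosomes of
    2 Mb, 30 planted SEs (10 shared, 10 per-line specific) of 3-5
    constituents each, 40 singleton background enhancers per line,
    constituent enrichment 200-400 reads over 300 bp against a 2e-4
    reads/bp Poisson background, replicate lognormal noise sigma 0.25 (keeps
    chance escapes from the 2-fold band of equal-mean genes well below 5%),
    and a 4-fold expression effect for specific-SE genes.
    """

    genome_n_chrom: int = 2
    chrom_length_bp: int = 2_000_000
    n_shared_ses: int = 10
    n_a_specific_ses: int = 10
    n_b_specific_ses: int = 10
    constituents_per_se: Tuple[int, int] = (3, 5)
    constituent_gap_bp: Tuple[int, int] = (1500, 2500)
    peak_width_bp: int = 300
    peak_enrichment: Tuple[int, int] = (200, 400)  # reads per planted constituent
    background_rate: float = 2e-4  # reads per bp per track
    n_background_peaks: int = 40  # singleton enhancers per cell line
    background_peak_reads: Tuple[int, int] = (15, 40)
    background_peak_width_bp: int = 1000
    n_blacklist_regions: int = 4
    n_genes: int = 200
    se_gene_log_fpkm: Tuple[float, float] = (3.4, 0.8)  # ln-space mean, sd
    background_gene_log_fpkm: Tuple[float, float] = (1.0, 1.0)
    replicate_sigma_ln: float = 0.25
    specific_se_fold_effect: float = 4.0
    n_replicates: int = 2
    timepoint_a_min: int = 320
    timepoint_b_min: int = 240
    track_bin_bp: int = 10
    stitch_gap_bp: int = 12500
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_shared_ses, self.n_a_specific_ses, self.n_b_specific_ses) < 0:
            raise ValueError("SE counts must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.constituents_per_se[0] < 1:
            raise ValueError("need >= 1 constituent per SE")


@dataclass
class ScenarioBundle:
    """Paths of every emitted file plus the in-memory truth table."""

    outdir: Path
    genome_fasta: Path
    blacklist_bed: Path
    peak_files: Dict[Tuple[str, str], Path]  # (cell, TF) -> narrowPeak
    track_files: Dict[Tuple[str, str, str], Path]  # (cell, TF, treatment)
    library_sizes: Dict[Tuple[str, str, str], int]
    gene_model: Path
    fpkm_table: Path
    sample_metadata: Path
    motif_files: Dict[str, Path]
    truth: dict
    truth_path: Path
    config_path: Path
    params: ScenarioParams


def embed_motif(sequence: str, pwm: PWM, position: int, strand: str = "+") -> str:
    """Write the PWM consensus (reverse-complemented for '-') into a sequence."""
    cons = pwm.consensus
    if strand == "-":
        cons = cons.translate(_COMP)[::-1]
    if position < 0 or position + len(cons) > len(sequence):
        raise ValueError(
            f"motif of length {len(cons)} does not fit at {position} "
            f"in sequence of length {len(sequence)}"
        )
    return sequence[:position] + cons + sequence[position + len(cons):]


# --- internal helpers -------------------------------------------------------

# per-label motif menu: (category weights over tuples of motif names)
_MOTIF_MENU = {
    "shared": [(("ERE",), 0.6), (("ERE", "NRHALF"), 0.2), (("NRHALF",), 0.1), ((), 0.1)],
    "A_specific": [
        (("FOX",), 0.4),
        (("AP2",), 0.25),
        (("FOX", "AP2"), 0.15),
        (("NRHALF",), 0.1),
        ((), 0.1),
    ],
    "B_specific": [
        (("TEAD",), 0.35),
        (("TCF",), 0.25),
        (("TEAD", "TCF"), 0.15),
        (("SIX",), 0.1),
        (("NRHALF",), 0.05),
        ((), 0.1),
    ],
}

_MOTIF_TO_TF = {"FOX": "FOX", "AP2": "AP2", "TEAD": "TEAD", "TCF": "TCF"}


def _pick(rng: np.random.Generator, menu) -> Tuple[str, ...]:
    weights = np.array([w for _, w in menu])
    i = rng.choice(len(menu), p=weights / weights.sum())
    return menu[i][0]


def _write_fasta(path: Path, seqs: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = seqs[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _write_jaspar_pfm(path: Path, name: str, counts: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name} {name}\n")
        for bi, base in enumerate(_BASES):
            row = " ".join(f"{int(v):d}" for v in counts[:, bi])
            fh.write(f"{base} [ {row} ]\n")


class _TrackBuilder:
    """Accumulates binned read-start counts and writes bedGraph."""

    def __init__(self, chrom_lengths: Dict[str, int], bin_bp: int):
        self.bin = bin_bp
        self.counts = {
            c: np.zeros(int(np.ceil(L / bin_bp)), dtype=np.int64)
            for c, L in chrom_lengths.items()
        }

    def add_background(self, rng: np.random.Generator, rate_per_bp: float) -> None:
        for c, arr in self.counts.items():
            arr += rng.poisson(rate_per_bp * self.bin, size=arr.shape)

    def add_peak(
        self, rng: np.random.Generator, chrom: str, start: int, end: int, reads: int
    ) -> None:
        lo, hi = start // self.bin, max(start // self.bin + 1, -(-end // self.bin))
        hi = min(hi, len(self.counts[chrom]))
        n_bins = hi - lo
        alloc = rng.multinomial(reads, np.full(n_bins, 1.0 / n_bins))
        self.counts[chrom][lo:hi] += alloc

    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))

    def write(self, path: Path) -> int:
        with open(path, "w") as fh:
            for chrom in sorted(self.counts):
                arr = self.counts[chrom]
                for i in np.nonzero(arr)[0]:
                    s = int(i) * self.bin
                    fh.write(f"{chrom}\t{s}\t{s + self.bin}\t{int(arr[i])}\n")
        return self.total()


def _narrowpeak_line(chrom, start, end, name, signal, summit_offset) -> str:
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t0\t.\t{signal:g}\t-1\t-1\t{summit_offset}\n"
    )


def generate_scenario(
    params: Optional[ScenarioParams] = None, outdir="scenario"
) -> ScenarioBundle:
    """Emit the complete dataset bundle; byte-identical for a given seed."""
    p = params or ScenarioParams()
    p.validate()
    outdir = Path(outdir)
    for sub in ("peaks", "tracks", "motifs"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(p.seed)
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ("genome", "placement", "motifs", "coverage", "expression"),
            root.spawn(5),
        )
    }
    motifs = builtin_motifs()
    chroms = [f"chr{i + 1}" for i in range(p.genome_n_chrom)]
    chrom_lengths = {c: p.chrom_length_bp for c in chroms}

    # --- genome --------------------------------------------------------------
    rng = streams["genome"]
    seqs = {
        c: "".join(np.array(list(_BASES))[rng.integers(0, 4, L)])
        for c, L in chrom_lengths.items()
    }
    seq_arrays = {c: bytearray(s, "ascii") for c, s in seqs.items()}

    # --- placement -----------------------------------------------------------
    rng = streams["placement"]
    units: List[tuple] = []
    for i in range(p.n_shared_ses):
        units.append(("SE", "shared", i))
    for i in range(p.n_a_specific_ses):
        units.append(("SE", "A_specific", i))
    for i in range(p.n_b_specific_ses):
        units.append(("SE", "B_specific", i))
    for cell in ("A", "B"):
        for i in range(p.n_background_peaks):
            units.append(("bg", cell, i))
    for i in range(p.n_blacklist_regions):
        units.append(("blk", "", i))
    rng.shuffle(units)

    margin = 60_000
    max_se_span = (
        (p.constituents_per_se[1] - 1) * p.constituent_gap_bp[1] + p.peak_width_bp
    )
    per_chrom = -(-len(units) // len(chroms))
    pitch = (p.chrom_length_bp - 2 * margin) // per_chrom
    jitter_max = 3000
    if pitch < p.stitch_gap_bp + max_se_span + jitter_max + 2000:
        raise ValueError(
            "cannot place all regions with enough separation; "
            "increase chrom_length_bp or reduce the number of regions"
        )
    placements = []  # (unit, chrom, anchor_start)
    for idx, unit in enumerate(units):
        chrom = chroms[idx % len(chroms)]
        slot = idx // len(chroms)
        anchor = margin + slot * pitch + int(rng.integers(0, jitter_max))
        placements.append((unit, chrom, anchor))

    # --- plant constituents, peaks, motifs ------------------------------------
    rng_m = streams["motifs"]
    truth_ses = []
    peak_records: Dict[Tuple[str, str], List[str]] = {}
    # (cell, TF) -> list of (chrom, start, end, summit, reads, name)
    planted_peaks: Dict[Tuple[str, str], List[tuple]] = {}
    blacklist: List[Tuple[str, int, int]] = []

    def add_peak(cell, tf, chrom, start, end, summit, reads, name):
        planted_peaks.setdefault((cell, tf), []).append(
            (chrom, start, end, summit, reads, name)
        )

    half_w = p.peak_width_bp // 2
    for unit, chrom, anchor in placements:
        kind = unit[0]
        if kind == "SE":
            label, se_idx = unit[1], unit[2]
            se_id = f"SE_{label}_{se_idx}"
            k = int(rng_m.integers(p.constituents_per_se[0], p.constituents_per_se[1] + 1))
            # A shared SE nucleates on an ERE "mother" constituent present in
            # both lines and must look SE-like in both cistromes, so each line
            # gets at least one further co-present constituent; the remaining
            # ones are a random mix of shared and line-specific sites.
            if label == "shared":
                con_labels = ["shared", "A_specific", "B_specific"]
                while len(con_labels) < k:
                    r = rng_m.random()
                    con_labels.append(
                        "shared" if r < 0.35 else ("A_specific" if r < 0.70 else "B_specific")
                    )
                tail = con_labels[1:]
                rng_m.shuffle(tail)
                con_labels = con_labels[:1] + tail
            else:
                con_labels = [label] * k
            summit = anchor + half_w
            constituents = []
            for ci in range(k):
                if ci > 0:
                    summit += int(
                        rng_m.integers(p.constituent_gap_bp[0], p.constituent_gap_bp[1] + 1)
                    )
                start, end = summit - half_w, summit + half_w
                cid = f"{se_id}_c{ci}"
                con_label = con_labels[ci]
                if label == "shared" and ci == 0:
                    combo: Tuple[str, ...] = ("ERE",)
                else:
                    combo = _pick(rng_m, _MOTIF_MENU[con_label])
                placed = []
                pos = summit - 4
                for mname in combo:
                    pwm = motifs[mname]
                    mpos = pos - pwm.length // 2 + int(rng_m.integers(-8, 9))
                    strand = "+" if rng_m.integers(0, 2) == 0 else "-"
                    cons = pwm.consensus
                    if strand == "-":
                        cons = cons.translate(_COMP)[::-1]
                    seq_arrays[chrom][mpos : mpos + pwm.length] = cons.encode()
                    placed.append([mname, strand, int(mpos)])
                    pos = mpos + pwm.length + 14
                reads = int(rng_m.integers(p.peak_enrichment[0], p.peak_enrichment[1] + 1))
                present_in = {"shared": ("A", "B"), "A_specific": ("A",),
                              "B_specific": ("B",)}[con_label]
                for cell in present_in:
                    jit = int(rng_m.integers(-40, 41)) if cell == "B" and con_label == "shared" else 0
                    add_peak(cell, "ER", chrom, start + jit, end + jit, summit, reads, cid)
                # collaborator TF peak wherever its motif is planted and the
                # constituent carries a peak in that TF's cell line
                for mname, _, _ in placed:
                    tf = _MOTIF_TO_TF.get(mname)
                    if tf is None:
                        continue
                    tf_cell = "A" if tf in ("FOX", "AP2") else "B"
                    if tf_cell in present_in:
                        add_peak(tf_cell, tf, chrom, start, end, summit,
                                 reads // 2, f"{cid}_{tf}")
                constituents.append(
                    {
                        "id": cid,
                        "label": con_label,
                        "chrom": chrom,
                        "start": int(start),
                        "end": int(end),
                        "summit": int(summit),
                        "motifs": placed,
                        "present_in": list(present_in),
                        "reads": reads,
                    }
                )
            region_start = constituents[0]["start"]
            region_end = constituents[-1]["end"]

            def _hull(cell):
                xs = [c for c in constituents if cell in c["present_in"]]
                if not xs:
                    return None
                return [int(min(c["start"] for c in xs)), int(max(c["end"] for c in xs))]

            truth_ses.append(
                {
                    "id": se_id,
                    "label": label,
                    "chrom": chrom,
                    "start": int(region_start),
                    "end": int(region_end),
                    "region_a": _hull("A"),
                    "region_b": _hull("B"),
                    "constituents": constituents,
                    "gene_id": None,  # filled below
                }
            )
        elif kind == "bg":
            cell, i = unit[1], unit[2]
            w = p.background_peak_width_bp
            start = anchor
            end = start + w
            summit = start + w // 2
            reads = int(rng_m.integers(*p.background_peak_reads))
            add_peak(cell, "ER", chrom, start, end, summit, reads, f"bg_{cell}_{i}")
        else:  # blacklist decoy cluster
            i = unit[2]
            cluster_start = anchor
            s = cluster_start
            decoy_reads = 2 * p.peak_enrichment[1]  # artifact-style pileups
            for j in range(3):
                add_peak("A", "ER", chrom, s, s + 200, s + 100, decoy_reads, f"blk_{i}_{j}")
                add_peak("B", "ER", chrom, s, s + 200, s + 100, decoy_reads, f"blk_{i}_{j}")
                s += 1500
            blacklist.append((chrom, cluster_start - 500, s + 500))

    # --- peak files ------------------------------------------------------------
    peak_paths: Dict[Tuple[str, str], Path] = {}
    for (cell, tf), recs in sorted(planted_peaks.items()):
        recs = sorted(recs)
        path = outdir / "peaks" / f"cell{cell}_{tf}.narrowPeak"
        with open(path, "w") as fh:
            for chrom, start, end, summit, reads, name in recs:
                fh.write(
                    _narrowpeak_line(chrom, start, end, name, reads, summit - start)
                )
        peak_paths[(cell, tf)] = path

    blacklist_path = outdir / "blacklist.bed"
    with open(blacklist_path, "w") as fh:
        for chrom, s, e in sorted(blacklist):
            fh.write(f"{chrom}\t{s}\t{e}\n")

    # --- coverage tracks --------------------------------------------------------
    rng_c = streams["coverage"]
    track_paths: Dict[Tuple[str, str, str], Path] = {}
    library_sizes: Dict[Tuple[str, str, str], int] = {}
    track_specs = []  # (cell, tf, treatment, peak list)
    for (cell, tf), recs in sorted(planted_peaks.items()):
        track_specs.append((cell, tf, "E2", recs))
    # vehicle master-TF tracks: signal only at shared-SE mother constituents
    mothers = [
        (se["chrom"], c["start"], c["end"], c["reads"] // 2)
        for se in truth_ses
        if se["label"] == "shared"
        for c in se["constituents"][:1]
    ]
    for cell in ("A", "B"):
        track_specs.append((cell, "ER", "vehicle", None))

    for cell, tf, treatment, recs in track_specs:
        tb = _TrackBuilder(chrom_lengths, p.track_bin_bp)
        tb.add_background(rng_c, p.background_rate)
        if treatment == "vehicle":
            for chrom, s, e, reads in mothers:
                tb.add_peak(rng_c, chrom, s, e, reads)
        else:
            for chrom, start, end, summit, reads, name in recs:
                tb.add_peak(rng_c, chrom, start, end, reads)
        path = outdir / "tracks" / f"cell{cell}_{tf}_{treatment}.bedGraph"
        total = tb.write(path)
        track_paths[(cell, tf, treatment)] = path
        library_sizes[(cell, tf, treatment)] = max(1, total)

    # --- genes & expression -----------------------------------------------------
    rng_e = streams["expression"]
    genes = []  # dicts
    truth_genes = []
    for se in truth_ses:
        gid = f"G_{se['id']}"
        center = (se["start"] + se["end"]) // 2
        offset = int(rng_e.integers(5000, 30001)) * (1 if rng_e.integers(0, 2) else -1)
        tss = center + offset
        strand = "+" if rng_e.integers(0, 2) == 0 else "-"
        body_len = int(rng_e.integers(8000, 20001))
        if strand == "+":
            start, end = tss, tss + body_len
        else:
            start, end = tss - body_len, tss + 1
        base = float(np.exp(rng_e.normal(*p.se_gene_log_fpkm)))
        fold = p.specific_se_fold_effect
        mean_a, mean_b = {
            "shared": (base, base),
            "A_specific": (base, base / fold),
            "B_specific": (base / fold, base),
        }[se["label"]]
        expected = {"shared": "SIMILAR", "A_specific": "A_SPECIFIC",
                    "B_specific": "B_SPECIFIC"}[se["label"]]
        genes.append(
            dict(gene_id=gid, chrom=se["chrom"], strand=strand, tss=tss,
                 start=start, end=end, biotype="protein_coding",
                 mean_a=mean_a, mean_b=mean_b)
        )
        se["gene_id"] = gid
        truth_genes.append(
            dict(gene_id=gid, se_id=se["id"], se_label=se["label"],
                 expected_class=expected, mean_a=mean_a, mean_b=mean_b)
        )
        # occasional high-expressed non-coding decoy near the SE centre
        if rng_e.random() < 0.3:
            dtss = center + int(rng_e.integers(-2000, 2001))
            genes.append(
                dict(gene_id=f"L_{se['id']}", chrom=se["chrom"], strand="+",
                     tss=dtss, start=dtss, end=dtss + 3000, biotype="lincRNA",
                     mean_a=float(np.exp(rng_e.normal(4.0, 0.5))),
                     mean_b=float(np.exp(rng_e.normal(4.0, 0.5))))
            )
    n_planted = len(genes)
    n_background_genes = max(0, p.n_genes - n_planted)
    for i in range(n_background_genes):
        chrom = chroms[i % len(chroms)]
        tss = int(rng_e.integers(margin, p.chrom_length_bp - margin))
        strand = "+" if rng_e.integers(0, 2) == 0 else "-"
        body_len = int(rng_e.integers(5000, 15001))
        start, end = (tss, tss + body_len) if strand == "+" else (tss - body_len, tss + 1)
        base = float(np.exp(rng_e.normal(*p.background_gene_log_fpkm)))
        wobble = float(np.exp(rng_e.normal(0.0, 0.5)))
        genes.append(
            dict(gene_id=f"BGgene_{i}", chrom=chrom, strand=strand, tss=tss,
                 start=start, end=end, biotype="protein_coding",
                 mean_a=base, mean_b=base * wobble)
        )

    gene_model_path = outdir / "genes.tsv"
    with open(gene_model_path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tstart\tend\tbiotype\n")
        for g in genes:
            fh.write(
                f"{g['gene_id']}\t{g['chrom']}\t{g['strand']}\t{g['tss']}\t"
                f"{g['start']}\t{g['end']}\t{g['biotype']}\n"
            )

    samples = []
    for cell, tp in (("cellA", p.timepoint_a_min), ("cellB", p.timepoint_b_min)):
        for tpoint in (0, tp):
            for r in range(1, p.n_replicates + 1):
                samples.append((f"{cell}_t{tpoint}_r{r}", cell, tpoint, r))
    sample_path = outdir / "samples.tsv"
    with open(sample_path, "w") as fh:
        fh.write("sample\tcell_line\ttimepoint_min\treplicate\n")
        for s in samples:
            fh.write("\t".join(map(str, s)) + "\n")

    fpkm_path = outdir / "fpkm.tsv"
    with open(fpkm_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(s[0] for s in samples) + "\n")
        for g in genes:
            vals = []
            for _, cell, _, _ in samples:
                mean = g["mean_a"] if cell == "cellA" else g["mean_b"]
                v = mean * float(np.exp(rng_e.normal(0.0, p.replicate_sigma_ln)))
                vals.append(f"{v:.3f}")
            fh.write(g["gene_id"] + "\t" + "\t".join(vals) + "\n")

    # --- genome written after motif embedding ------------------------------------
    genome_path = outdir / "genome.fa"
    _write_fasta(genome_path, {c: a.decode("ascii") for c, a in seq_arrays.items()})

    # --- motif files --------------------------------------------------------------
    motif_paths = {}
    for name, cons in _MOTIF_CONSENSUS.items():
        path = outdir / "motifs" / f"{name}.pfm"
        _write_jaspar_pfm(path, name, _counts_from_consensus(cons))
        motif_paths[name] = path

    # --- truth table ----------------------------------------------------------------
    truth = {
        "replicate_sigma_ln": p.replicate_sigma_ln,
        "specific_se_fold_effect": p.specific_se_fold_effect,
        "ses": truth_ses,
        "genes": truth_genes,
        "planted_motifs_by_label": {
            "shared": ["ERE"],
            "A_specific": ["FOX", "AP2"],
            "B_specific": ["TEAD", "TCF", "SIX"],
        },
        "unplanted_control_motif": "CEBP",
    }
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    # --- pipeline config manifest (paths relative to the scenario dir so the
    # bundle is relocatable and byte-identical across output locations) -----------
    def rel(path: Path) -> str:
        return str(path.relative_to(outdir))

    config = {
        "seed": p.seed,
        "genome": rel(genome_path),
        "blacklist": rel(blacklist_path),
        "genes": rel(gene_model_path),
        "fpkm": rel(fpkm_path),
        "samples": rel(sample_path),
        "motifs": {k: rel(v) for k, v in sorted(motif_paths.items())},
        "master_tf": "ER",
        "cell_lines": {
            "cellA": {
                "timepoint_min": p.timepoint_a_min,
                "peaks": {
                    tf: rel(path)
                    for (cell, tf), path in sorted(peak_paths.items())
                    if cell == "A"
                },
                "tracks": {
                    f"{tf}|{trt}": {
                        "path": rel(path),
                        "total_mapped_reads": library_sizes[(cell, tf, trt)],
                    }
                    for (cell, tf, trt), path in sorted(track_paths.items())
                    if cell == "A"
                },
            },
            "cellB": {
                "timepoint_min": p.timepoint_b_min,
                "peaks": {
                    tf: rel(path)
                    for (cell, tf), path in sorted(peak_paths.items())
                    if cell == "B"
                },
                "tracks": {
                    f"{tf}|{trt}": {
                        "path": rel(path),
                        "total_mapped_reads": library_sizes[(cell, tf, trt)],
                    }
                    for (cell, tf, trt), path in sorted(track_paths.items())
                    if cell == "B"
                },
            },
        },
        "analysis": {},
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    return ScenarioBundle(
        outdir=outdir,
        genome_fasta=genome_path,
        blacklist_bed=blacklist_path,
        peak_files=peak_paths,
        track_files=track_paths,
        library_sizes=library_sizes,
        gene_model=gene_model_path,
        fpkm_table=fpkm_path,
        sample_metadata=sample_path,
        motif_files=motif_paths,
        truth=truth,
        truth_path=truth_path,
        config_path=config_path,
        params=p,
    )
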