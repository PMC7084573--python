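"""Configuration, orchestration and end-to-end execution of all stages.

The pipeline consumes a YAML manifest (per cell line: peak and coverage
files with library sizes; genome, gene model, FPKM table, motif PFMs,
blacklist) and runs: blacklist filtering -> SE calling per cell line ->
constituent classification -> motif scanning/thresholds/distribution/
enrichment -> density/correlation/co-binding -> shared-SE breakdown and
motif composition -> SE-to-gene annotation -> expression classes ->
summary. Every stage writes plain-text tables; a rerun with the same
config and inputs reproduces identical data files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import compare, motifs as mot, secall
from .core import (
    AnalysisConfig,
    CoverageTrack,
    GenomicInterval,
    Peak,
    compute_rpkm,
    filter_blacklist,
    read_bed_intervals,
    read_peaks,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineError"]

STAGES = (
    "filter",
    "se_call",
    "classify",
    "motifs",
    "density",
    "shared_se",
    "annotate",
    "expression",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class CellLineConfig:
    name: str
    timepoint_min: int
    peaks: Dict[str, Path]  # TF -> narrowPeak
    tracks: Dict[Tuple[str, str], Tuple[Path, int]]  # (TF, treatment) -> (path, libsize)


@dataclass
class PipelineConfig:
    seed: int
    genome: Path
    blacklist: Optional[Path]
    genes: Path
    fpkm: Path
    samples: Path
    motifs: Dict[str, Path]
    master_tf: str
    cell_a: CellLineConfig
    cell_b: CellLineConfig
    analysis: AnalysisConfig
    motif_thresholds: Dict[str, float] = field(default_factory=dict)
    n_background_regions: int = 500
    raw_correlation_scale: bool = False

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "analysis": dataclasses.asdict(self.analysis),
            "master_tf": self.master_tf,
            "cells": [
                [c.name, c.timepoint_min, sorted(str(p) for p in c.peaks.values())]
                for c in (self.cell_a, self.cell_b)
            ],
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; all problems are reported
    together in a single error message."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).resolve().parent
    problems: List[str] = []

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    def need(key):
        if key not in raw:
            problems.append(f"missing required key {key!r}")
            return None
        return raw[key]

    analysis = AnalysisConfig(**raw.get("analysis", {}) or {})
    problems.extend(analysis.validate())
    master = need("master_tf")
    for key in ("genome", "genes", "fpkm", "samples"):
        p = need(key)
        if p is not None and not resolve(p).exists():
            problems.append(f"{key} path does not exist: {p}")
    blacklist = raw.get("blacklist")
    if blacklist is not None and not resolve(blacklist).exists():
        problems.append(f"blacklist path does not exist: {blacklist}")
    motif_paths = {}
    for mid, mp in (raw.get("motifs") or {}).items():
        if not resolve(mp).exists():
            problems.append(f"motif {mid} path does not exist: {mp}")
        motif_paths[mid] = resolve(mp)
    if not motif_paths:
        problems.append("no motifs declared")

    cells = raw.get("cell_lines") or {}
    if len(cells) != 2:
        problems.append(f"need exactly 2 cell_lines entries, got {len(cells)}")
    cell_cfgs = []
    for name in sorted(cells):
        entry = cells[name] or {}
        peaks = {}
        for tf, pp in (entry.get("peaks") or {}).items():
            if not resolve(pp).exists():
                problems.append(f"{name}: peak file for {tf} does not exist: {pp}")
            peaks[tf] = resolve(pp)
        if master is not None and master not in peaks:
            problems.append(f"{name}: no peak file for master TF {master!r}")
        tracks = {}
        for key, spec in (entry.get("tracks") or {}).items():
            tf, _, treatment = key.partition("|")
            tp = resolve(spec["path"])
            if not tp.exists():
                problems.append(f"{name}: track {key} path does not exist: {tp}")
            total = int(spec.get("total_mapped_reads", 0))
            if total <= 0:
                problems.append(f"{name}: track {key} needs positive total_mapped_reads")
            tracks[(tf, treatment or "E2")] = (tp, total)
        if master is not None and (master, "E2") not in tracks:
            problems.append(f"{name}: no E2 track for master TF {master!r}")
        cell_cfgs.append(
            CellLineConfig(name, int(entry.get("timepoint_min", 0)), peaks, tracks)
        )
    if problems:
        raise ValueError(
            "invalid pipeline config:\n  - " + "\n  - ".join(problems)
        )
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        genome=resolve(raw["genome"]),
        blacklist=resolve(blacklist) if blacklist else None,
        genes=resolve(raw["genes"]),
        fpkm=resolve(raw["fpkm"]),
        samples=resolve(raw["samples"]),
        motifs=motif_paths,
        master_tf=master,
        cell_a=cell_cfgs[0],
        cell_b=cell_cfgs[1],
        analysis=analysis,
        motif_thresholds={
            str(k): float(v) for k, v in (raw.get("motif_thresholds") or {}).items()
        },
    )


def _load_genome(path):
    import pyfaidx

    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)


def _sample_background_regions(
    genome, n: int, width: int, rng: np.random.Generator
) -> List[Peak]:
    chroms = list(genome.keys())
    lengths = {c: len(genome[c]) for c in chroms}
    out = []
    for i in range(n):
        c = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(width, lengths[c] - width))
        out.append(Peak(GenomicInterval(c, s - width // 2, s + width // 2), s, 0.0, f"bg{i}"))
    return out


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Execute every stage; returns a results dict and writes all outputs.

    Data outputs are deterministic for a fixed config and inputs; the run
    log and RunSummary carry wall times and are the only non-reproducible
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.analysis
    log_lines: List[str] = []
    summary = {"config_hash": config.config_hash(), "stages": {}, "seed": config.seed,
               "parameters": dataclasses.asdict(cfg)}
    results: Dict = {}

    def record(stage, t0, **info):
        summary["stages"][stage] = {"wall_s": round(time.time() - t0, 3), **info}
        log_lines.append(f"[{stage}] {info}")

    current_stage = "filter"
    try:
        # ---- filter -----------------------------------------------------------
        t0 = time.time()
        blacklist = (
            read_bed_intervals(config.blacklist) if config.blacklist else []
        )
        peaks: Dict[Tuple[str, str], List[Peak]] = {}
        n_in = n_out = 0
        for cell_cfg in (config.cell_a, config.cell_b):
            for tf, path in sorted(cell_cfg.peaks.items()):
                raw = read_peaks(path, "narrowPeak")
                kept = filter_blacklist(raw, blacklist)
                peaks[(cell_cfg.name, tf)] = kept
                n_in += len(raw)
                n_out += len(kept)
        record("filter", t0, peaks_in=n_in, peaks_kept=n_out,
               blacklist_regions=len(blacklist))

        # ---- SE calling per cell line ----------------------------------------
        current_stage = "se_call"
        t0 = time.time()
        tracks: Dict[Tuple[str, str, str], CoverageTrack] = {}
        for cell_cfg in (config.cell_a, config.cell_b):
            for (tf, trt), (path, total) in sorted(cell_cfg.tracks.items()):
                tracks[(cell_cfg.name, tf, trt)] = CoverageTrack.from_bedgraph(
                    path, total
                )
        se_calls: Dict[str, secall.SECall] = {}
        for cell_cfg in (config.cell_a, config.cell_b):
            name = cell_cfg.name
            master_peaks = peaks[(name, config.master_tf)]
            cands = secall.stitch_peaks(master_peaks, cfg.stitch_gap_bp)
            curve = secall.rank_candidates(
                cands, tracks[(name, config.master_tf, "E2")], cfg.read_count_mode
            )
            call = secall.call_superenhancers(curve)
            se_calls[name] = call
            _write_se_call(call, outdir / f"se_calls_{name}.tsv",
                           outdir / f"se_regions_{name}.bed",
                           outdir / f"se_constituents_{name}.bed")
        record("se_call", t0, **{
            f"n_se_{c.name}": int(se_calls[c.name].is_super.sum())
            for c in (config.cell_a, config.cell_b)
        })

        # ---- constituent classification --------------------------------------
        current_stage = "classify"
        t0 = time.time()
        name_a, name_b = config.cell_a.name, config.cell_b.name
        cons_a = [p for se in se_calls[name_a].superenhancers for p in se.constituents]
        cons_b = [p for se in se_calls[name_b].superenhancers for p in se.constituents]
        track_a = tracks[(name_a, config.master_tf, "E2")]
        track_b = tracks[(name_b, config.master_tf, "E2")]
        rpkm_a = compute_rpkm(track_a, cons_a, cfg.rpkm_halfwidth_bp, cfg.read_count_mode)
        rpkm_b = compute_rpkm(track_b, cons_b, cfg.rpkm_halfwidth_bp, cfg.read_count_mode)
        labeled = compare.classify_constituents(cons_a, cons_b, rpkm_a, rpkm_b)
        sort_keys = compare.constituent_sort_keys(
            labeled, track_a, track_b, cfg.rpkm_halfwidth_bp,
            cfg.fpkm_pseudocount, cfg.read_count_mode
        )
        order = np.argsort(sort_keys, kind="stable")
        labeled = [labeled[i] for i in order]
        sort_keys = sort_keys[order]
        label_counts = {
            lab: sum(1 for c in labeled if c.label == lab)
            for lab in (compare.A_SPECIFIC, compare.SHARED, compare.B_SPECIFIC)
        }
        pd.DataFrame(
            {
                "name": [c.peak.name for c in labeled],
                "chrom": [c.peak.chrom for c in labeled],
                "start": [c.peak.start for c in labeled],
                "end": [c.peak.end for c in labeled],
                "summit": [c.peak.summit for c in labeled],
                "label": [c.label for c in labeled],
                "sort_key": np.round(sort_keys, 6),
            }
        ).to_csv(outdir / "constituent_labels.tsv", sep="\t", index=False)
        record("classify", t0, **{k.lower(): v for k, v in label_counts.items()})
        results["label_counts"] = label_counts
        results["labeled_constituents"] = labeled

        # ---- motif landscape ---------------------------------------------------
        current_stage = "motifs"
        t0 = time.time()
        genome = _load_genome(config.genome)
        pwms = {mid: mot.read_pfm(path, id=mid) for mid, path in sorted(config.motifs.items())}
        rng = np.random.default_rng([config.seed, 101])
        background = _sample_background_regions(
            genome, config.n_background_regions, 2 * cfg.motif_halfwidth_bp, rng
        )
        all_peaks = [c.peak for c in labeled]
        region_ids = [f"r{i}" for i in range(len(all_peaks))]
        named = [
            Peak(pk.interval, pk.summit, pk.score, rid)
            for pk, rid in zip(all_peaks, region_ids)
        ]
        top = {}  # pwm -> np.ndarray over constituents
        top_bg = {}
        thresholds = {}
        for mid, pwm in pwms.items():
            top[mid] = mot.top_scores_for_regions(named, genome, pwm, cfg.motif_halfwidth_bp)
            top_bg[mid] = mot.top_scores_for_regions(
                background, genome, pwm, cfg.motif_halfwidth_bp
            )
            pooled = np.concatenate([top[mid], top_bg[mid]])
            thresholds[mid] = mot.select_score_threshold(
                pooled, mid, manual=config.motif_thresholds.get(mid)
            )
        pd.DataFrame(
            {
                "pwm": list(thresholds),
                "threshold_bits": [t.threshold for t in thresholds.values()],
                "provenance": [t.provenance for t in thresholds.values()],
            }
        ).to_csv(outdir / "motif_thresholds.tsv", sep="\t", index=False)

        # presence by top score in the summit window; hits in the 1.5-kb frame
        presence = {
            rid: {mid for mid in pwms if top[mid][i] >= thresholds[mid].threshold}
            for i, rid in enumerate(region_ids)
        }
        frame_half = cfg.motif_frame_bp // 2
        hits_by_region: Dict[str, List[mot.MotifHit]] = {rid: [] for rid in region_ids}
        frame_peaks = []
        for pk, rid in zip(named, region_ids):
            fs = max(0, pk.summit - frame_half)
            fe = pk.summit + frame_half
            seq = str(genome[pk.chrom][fs:fe])
            frame_peaks.append(Peak(GenomicInterval(pk.chrom, fs, fe), pk.summit, 0.0, rid))
            for mid, pwm in pwms.items():
                thr = thresholds[mid].threshold
                hits_by_region[rid].extend(
                    h for h in mot.scan(seq, pwm, rid) if h.score >= thr
                )
        dist = mot.motif_distribution(
            frame_peaks, hits_by_region, list(pwms.values()),
            cfg.motif_frame_bp, cfg.motif_window_bp,
        )
        label_by_rid = {rid: c.label for rid, c in zip(region_ids, labeled)}
        _write_distribution(
            dist, region_ids, list(pwms), label_by_rid,
            cfg.motif_frame_bp, cfg.motif_window_bp, outdir / "motif_distribution.tsv",
        )
        subclusters = mot.cluster_by_motif_presence(
            region_ids, hits_by_region, list(pwms)
        )
        enrich_rows = []
        rids_by_label = {
            lab: [rid for rid in region_ids if label_by_rid[rid] == lab]
            for lab in (compare.A_SPECIFIC, compare.SHARED, compare.B_SPECIFIC)
        }
        idx_of = {rid: i for i, rid in enumerate(region_ids)}
        enrichment: Dict[Tuple[str, str], Tuple[float, float, float]] = {}
        for lab, rids in rids_by_label.items():
            if not rids:
                continue
            sel = [idx_of[r] for r in rids]
            for mid in pwms:
                res = mot.enrichment_test(
                    top[mid][sel], top_bg[mid], thresholds[mid].threshold
                )
                enrichment[(lab, mid)] = res
                enrich_rows.append(
                    {"cluster": lab, "pwm": mid, "target_fraction": round(res[0], 4),
                     "background_fraction": round(res[1], 4), "p_value": res[2]}
                )
        pd.DataFrame(enrich_rows).to_csv(
            outdir / "motif_enrichment.tsv", sep="\t", index=False
        )
        record("motifs", t0, n_pwms=len(pwms), n_background=len(background))
        results["enrichment"] = enrichment
        results["presence"] = presence
        results["region_ids"] = region_ids
        results["thresholds"] = thresholds
        results["subclusters"] = subclusters

        # ---- density / correlation / co-binding --------------------------------
        current_stage = "density"
        t0 = time.time()
        for cell_cfg in (config.cell_a, config.cell_b):
            for tf in cell_cfg.peaks:
                if (tf, "E2") not in cell_cfg.tracks:
                    raise ValueError(
                        f"{cell_cfg.name}: declared TF {tf!r} has no E2 coverage "
                        "track; the density matrix needs one column per TF"
                    )
        track_map = {
            (tf, trt, cell): tracks[(cell, tf, trt)]
            for (cell, tf, trt) in tracks
        }
        density = compare.build_density_matrix(
            labeled, track_map, cfg.rpkm_halfwidth_bp, cfg.read_count_mode
        )
        density.index = region_ids
        density.round(4).to_csv(outdir / "density_matrix.tsv", sep="\t")
        averages = compare.subcluster_averages(
            density, [label_by_rid[r] for r in region_ids]
        )
        averages.round(4).to_csv(outdir / "density_subcluster_means.tsv", sep="\t")
        corr = compare.correlation_matrix(
            density, cfg.fpkm_pseudocount, log_scale=not config.raw_correlation_scale
        )
        corr.round(4).to_csv(outdir / "correlation_matrix.tsv", sep="\t")
        record("density", t0, n_tracks=len(track_map))
        results["density"] = density
        results["correlation"] = corr

        # ---- shared SEs, breakdown, co-binding, composition ---------------------
        current_stage = "shared_se"
        t0 = time.time()
        pairs, hulls = compare.overlap_se_regions(
            se_calls[name_a].superenhancers, se_calls[name_b].superenhancers
        )
        breakdown, totals = compare.shared_se_constituent_breakdown(hulls, labeled)
        breakdown.to_csv(outdir / "shared_se_breakdown.tsv", sep="\t", index=False)
        in_hull = [
            c
            for c in labeled
            if any(
                c.peak.chrom == h.chrom and h.start <= c.peak.summit < h.end
                for h in hulls
            )
        ]
        collab_a = {
            tf: peaks[(name_a, tf)]
            for tf in config.cell_a.peaks
            if tf != config.master_tf
        }
        collab_b = {
            tf: peaks[(name_b, tf)]
            for tf in config.cell_b.peaks
            if tf != config.master_tf
        }
        cobind = {}
        for lab, collab in ((compare.A_SPECIFIC, collab_a), (compare.B_SPECIFIC, collab_b)):
            subset = [c for c in in_hull if c.label == lab]
            cobind[lab] = compare.count_cobound(
                subset, collab, cfg.min_cobind_tfs, cfg.motif_halfwidth_bp
            )
        pd.DataFrame(cobind).T.to_csv(outdir / "cobinding.tsv", sep="\t")
        rid_by_id = {id(c): rid for c, rid in zip(labeled, region_ids)}
        comp_input = {
            lab: [rid_by_id[id(c)] for c in in_hull if c.label == lab]
            for lab in (compare.A_SPECIFIC, compare.SHARED, compare.B_SPECIFIC)
        }
        composition, combos = compare.motif_composition(
            comp_input, presence, list(pwms)
        )
        composition.round(2).to_csv(outdir / "motif_composition.tsv", sep="\t")
        with open(outdir / "motif_combinations.tsv", "w") as fh:
            fh.write("cluster\tcombination\tcount\n")
            for lab, counter in sorted(combos.items()):
                for combo, n in counter.most_common():
                    fh.write(f"{lab}\t{combo}\t{n}\n")
        record("shared_se", t0, n_shared_se_pairs=len(pairs), n_hulls=len(hulls),
               shared_constituents_in_hulls=totals[compare.SHARED])
        results.update(
            shared_pairs=pairs, hulls=hulls, breakdown_totals=totals,
            cobind=cobind, composition=composition,
        )

        # ---- annotation -----------------------------------------------------------
        current_stage = "annotate"
        t0 = time.time()
        genes = ann.read_gene_models(config.genes)
        expr = ann.ExpressionMatrix.from_files(config.fpkm, config.samples)
        mean_a = {
            g.gene_id: expr.mean_fpkm(g.gene_id, name_a, config.cell_a.timepoint_min)
            for g in genes
        }
        mean_b = {
            g.gene_id: expr.mean_fpkm(g.gene_id, name_b, config.cell_b.timepoint_min)
            for g in genes
        }
        mean_both = {g: (mean_a[g] + mean_b[g]) / 2 for g in mean_a}
        shared_region_set = {
            (a.region.chrom, a.region.start, a.region.end) for a, _ in pairs
        } | {(b.region.chrom, b.region.start, b.region.end) for _, b in pairs}

        def specific_ses(call):
            return [
                se for se in call.superenhancers
                if (se.region.chrom, se.region.start, se.region.end)
                not in shared_region_set
            ]

        annot_rows = []
        annotations: Dict[str, List[Tuple[str, Optional[str]]]] = {
            compare.A_SPECIFIC: [], compare.SHARED: [], compare.B_SPECIFIC: []
        }
        se_sets = [
            (compare.A_SPECIFIC, [se.region for se in specific_ses(se_calls[name_a])], mean_a),
            (compare.SHARED, hulls, mean_both),
            (compare.B_SPECIFIC, [se.region for se in specific_ses(se_calls[name_b])], mean_b),
        ]
        for lab, regions, means in se_sets:
            for i, region in enumerate(regions):
                gene_id, rule = ann.annotate_se(region, genes, means, cfg)
                annotations[lab].append((f"{lab}_{i}", gene_id))
                annot_rows.append(
                    {"se_label": lab, "se_id": f"{lab}_{i}", "chrom": region.chrom,
                     "start": region.start, "end": region.end,
                     "gene_id": gene_id or "NA", "rule": rule}
                )
        pd.DataFrame(annot_rows).to_csv(outdir / "se_annotations.tsv", sep="\t", index=False)
        record("annotate", t0, n_annotated=sum(1 for r in annot_rows if r["gene_id"] != "NA"))

        # ---- expression classes ------------------------------------------------------
        current_stage = "expression"
        t0 = time.time()
        classes_by_label = {}
        class_rows = []
        for lab, items in annotations.items():
            classes = []
            for se_id, gene_id in items:
                if gene_id is None:
                    continue
                c = ann.classify_expression(
                    expr, gene_id, name_a, name_b,
                    config.cell_a.timepoint_min, config.cell_b.timepoint_min,
                    cfg.fold_threshold, cfg.fpkm_pseudocount,
                    compare.A_SPECIFIC, compare.B_SPECIFIC,
                )
                classes.append(c)
                class_rows.append(
                    {"se_label": lab, "se_id": se_id, "gene_id": gene_id,
                     "class": c.label,
                     "min_fold": round(min(c.pair_folds), 4),
                     "max_fold": round(max(c.pair_folds), 4)}
                )
            classes_by_label[lab] = classes
        pd.DataFrame(class_rows).to_csv(
            outdir / "expression_classes.tsv", sep="\t", index=False
        )
        summary_table = ann.expression_summary(
            classes_by_label, compare.A_SPECIFIC, compare.B_SPECIFIC
        )
        summary_table.round(2).to_csv(outdir / "expression_summary.tsv", sep="\t")
        record("expression", t0, n_classified=len(class_rows))
        results["expression_summary"] = summary_table
        results["classes_by_label"] = classes_by_label
        results["se_calls"] = se_calls

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current_stage}: {exc}\n")
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc

    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"config_hash={summary['config_hash']}\n")
        fh.write("parameters=" + json.dumps(summary["parameters"], sort_keys=True) + "\n")
        fh.write("\n".join(log_lines) + "\n")
    results["summary"] = summary
    results["outdir"] = outdir
    return results


def _write_se_call(call: secall.SECall, tsv: Path, bed: Path, cons_bed: Path) -> None:
    with open(tsv, "w") as fh:
        fh.write("chrom\tstart\tend\tn_constituents\ttag_density\trank\tis_super\n")
        for rank, (cand, sup) in enumerate(zip(call.candidates, call.is_super)):
            fh.write(
                f"{cand.region.chrom}\t{cand.region.start}\t{cand.region.end}\t"
                f"{cand.n_constituents}\t{cand.tag_density:.6g}\t{rank}\t"
                f"{int(sup)}\n"
            )
    with open(bed, "w") as fh:
        for i, se in enumerate(call.superenhancers):
            fh.write(f"{se.region.chrom}\t{se.region.start}\t{se.region.end}\tSE_{i}\n")
    with open(cons_bed, "w") as fh:
        for i, se in enumerate(call.superenhancers):
            for p in se.constituents:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\tSE_{i}\n")


def _write_distribution(
    dist: np.ndarray,
    region_ids: Sequence[str],
    pwm_ids: Sequence[str],
    label_by_rid: Dict[str, str],
    frame: int,
    window: int,
    path: Path,
) -> None:
    """Per-cluster, per-motif binned hit counts (summed over regions)."""
    n_bins = frame // window
    headers = [f"bin_{int(-frame / 2 + i * window)}" for i in range(n_bins)]
    labels = sorted({label_by_rid[r] for r in region_ids})
    with open(path, "w") as fh:
        fh.write("cluster\tpwm\t" + "\t".join(headers) + "\n")
        for lab in labels:
            sel = [i for i, r in enumerate(region_ids) if label_by_rid[r] == lab]
            for mi, mid in enumerate(pwm_ids):
                counts = dist[sel, :, mi].sum(axis=0)
                fh.write(lab + "\t" + mid + "\t" + "\t".join(map(str, counts)) + "\n")
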