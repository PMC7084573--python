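"""Two-cistrome comparison: constituent classification, shared-SE overlap,
TF density/correlation matrices, co-binding and motif composition.

Constituents from the two cell lines are classified SHARED when peaks
overlap (>=1 bp, half-open) across lines — overlapping peaks merge into one
shared constituent — and cell-line-specific otherwise. The RPKM log-ratio
between the lines serves only as the heat-map sort key. Shared SEs are
overlapping called SE regions; their merged hulls support the constituent
breakdown, co-binding fractions and motif composition tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import CoverageTrack, GenomicInterval, Peak, compute_rpkm, overlaps
from .secall import SECandidate

__all__ = [
    "A_SPECIFIC",
    "SHARED",
    "B_SPECIFIC",
    "LabeledConstituent",
    "classify_constituents",
    "constituent_sort_keys",
    "overlap_se_regions",
    "shared_se_constituent_breakdown",
    "build_density_matrix",
    "subcluster_averages",
    "correlation_matrix",
    "count_cobound",
    "motif_composition",
    "cluster_abundance_ratios",
]

A_SPECIFIC = "A_SPECIFIC"
SHARED = "SHARED"
B_SPECIFIC = "B_SPECIFIC"


@dataclass(frozen=True)
class LabeledConstituent:
    peak: Peak  # merged peak for SHARED (hull, summit of stronger member)
    label: str
    members_a: Tuple[Peak, ...] = ()
    members_b: Tuple[Peak, ...] = ()


def _overlap_components(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> Tuple[List[Tuple[List[Peak], List[Peak]]], Set[int], Set[int]]:
    """Connected components of the cross-line overlap graph.

    Returns the components (as lists of A and B member peaks) plus the index
    sets of A and B peaks involved in any overlap.
    """
    events = []  # (chrom, start, end, side, idx)
    for i, p in enumerate(peaks_a):
        events.append((p.chrom, p.start, p.end, 0, i))
    for j, p in enumerate(peaks_b):
        events.append((p.chrom, p.start, p.end, 1, j))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    parent: Dict[Tuple[int, int], Tuple[int, int]] = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    overlapped_a: Set[int] = set()
    overlapped_b: Set[int] = set()
    active: List[Tuple[str, int, int, int, int]] = []
    for ev in events:
        chrom, start, end, side, idx = ev
        active = [a for a in active if a[0] == chrom and a[2] > start]
        for a in active:
            if a[3] != side:
                union((a[3], a[4]), (side, idx))
                if side == 0:
                    overlapped_a.add(idx)
                    overlapped_b.add(a[4])
                else:
                    overlapped_b.add(idx)
                    overlapped_a.add(a[4])
        active.append(ev)
    comps: Dict[Tuple[int, int], Tuple[List[Peak], List[Peak]]] = {}
    for i in overlapped_a:
        comps.setdefault(find((0, i)), ([], []))[0].append(peaks_a[i])
    for j in overlapped_b:
        comps.setdefault(find((1, j)), ([], []))[1].append(peaks_b[j])
    ordered = sorted(
        comps.values(),
        key=lambda ab: min((p.chrom, p.start) for p in ab[0] + ab[1]),
    )
    return ordered, overlapped_a, overlapped_b


def classify_constituents(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    rpkm_a: Optional[Sequence[float]] = None,
    rpkm_b: Optional[Sequence[float]] = None,
) -> List[LabeledConstituent]:
    """Label the union of two cell lines' constituents.

    SHARED iff a peak in one line overlaps (>=1 bp) a peak in the other;
    overlapping peaks merge transitively into a single shared constituent
    whose region is the hull and whose summit comes from the stronger member
    (by the supplied RPKM, falling back to peak score). Remaining peaks are
    A_SPECIFIC / B_SPECIFIC by origin. Output order: (chrom, start).
    """
    ra = list(rpkm_a) if rpkm_a is not None else [p.score for p in peaks_a]
    rb = list(rpkm_b) if rpkm_b is not None else [p.score for p in peaks_b]
    strength_a = {id(p): v for p, v in zip(peaks_a, ra)}
    strength_b = {id(p): v for p, v in zip(peaks_b, rb)}
    comps, hit_a, hit_b = _overlap_components(peaks_a, peaks_b)
    out: List[LabeledConstituent] = []
    for members_a, members_b in comps:
        members = members_a + members_b
        hull = GenomicInterval(
            members[0].chrom,
            min(p.start for p in members),
            max(p.end for p in members),
        )
        best = max(
            members,
            key=lambda p: (
                strength_a.get(id(p), strength_b.get(id(p), 0.0)),
                -p.start,
            ),
        )
        merged = Peak(hull, best.summit, best.score, best.name)
        out.append(
            LabeledConstituent(merged, SHARED, tuple(members_a), tuple(members_b))
        )
    for i, p in enumerate(peaks_a):
        if i not in hit_a:
            out.append(LabeledConstituent(p, A_SPECIFIC, (p,), ()))
    for j, p in enumerate(peaks_b):
        if j not in hit_b:
            out.append(LabeledConstituent(p, B_SPECIFIC, (), (p,)))
    out.sort(key=lambda c: (c.peak.chrom, c.peak.start, c.peak.end))
    return out


def constituent_sort_keys(
    constituents: Sequence[LabeledConstituent],
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    halfwidth: int = 50,
    eps: float = 0.1,
    mode: str = "overlap",
) -> np.ndarray:
    """Heat-map sort key log2(RPKM_B + eps) - log2(RPKM_A + eps) per row."""
    peaks = [c.peak for c in constituents]
    ra = compute_rpkm(track_a, peaks, halfwidth, mode)
    rb = compute_rpkm(track_b, peaks, halfwidth, mode)
    return np.log2(rb + eps) - np.log2(ra + eps)


def overlap_se_regions(
    ses_a: Sequence[SECandidate], ses_b: Sequence[SECandidate]
) -> Tuple[List[Tuple[SECandidate, SECandidate]], List[GenomicInterval]]:
    """Shared SEs between the two cell lines.

    Returns every overlapping (A, B) region pair, plus one merged hull per
    connected overlap component (an A region overlapping two B regions gives
    two pairs but a single hull). Regions with no cross-line overlap do not
    contribute a hull.
    """
    pairs = [
        (a, b)
        for a in ses_a
        for b in ses_b
        if overlaps(a.region, b.region)
    ]
    fake_a = [
        Peak(a.region, a.region.center) for a in ses_a
    ]
    fake_b = [Peak(b.region, b.region.center) for b in ses_b]
    comps, _, _ = _overlap_components(fake_a, fake_b)
    hulls = []
    for members_a, members_b in comps:
        members = members_a + members_b
        hulls.append(
            GenomicInterval(
                members[0].chrom,
                min(p.start for p in members),
                max(p.end for p in members),
            )
        )
    hulls.sort(key=lambda h: (h.chrom, h.start))
    return pairs, hulls


def shared_se_constituent_breakdown(
    hulls: Sequence[GenomicInterval],
    constituents: Sequence[LabeledConstituent],
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Count A-specific / shared / B-specific constituents per shared hull.

    A constituent belongs to a hull iff its summit lies in [start, end).
    Returns a per-hull table and the totals over all hulls.
    """
    rows = []
    totals = {A_SPECIFIC: 0, SHARED: 0, B_SPECIFIC: 0}
    for hull in hulls:
        counts = {A_SPECIFIC: 0, SHARED: 0, B_SPECIFIC: 0}
        for c in constituents:
            if c.peak.chrom == hull.chrom and hull.start <= c.peak.summit < hull.end:
                counts[c.label] += 1
        for k, v in counts.items():
            totals[k] += v
        rows.append(
            {
                "chrom": hull.chrom,
                "start": hull.start,
                "end": hull.end,
                "n_a_specific": counts[A_SPECIFIC],
                "n_shared": counts[SHARED],
                "n_b_specific": counts[B_SPECIFIC],
            }
        )
    return pd.DataFrame(rows), totals


def build_density_matrix(
    constituents: Sequence[LabeledConstituent],
    tracks: Dict[Tuple[str, str, str], CoverageTrack],
    halfwidth: int = 50,
    mode: str = "overlap",
) -> pd.DataFrame:
    """RPKM of every constituent in every (TF, treatment, cell line) track.

    Columns are named "tf|treatment|cell_line"; rows follow the input
    constituent order and are indexed by constituent name.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    peaks = [c.peak for c in constituents]
    cols = {}
    for (tf, treatment, cell), track in sorted(tracks.items()):
        cols[f"{tf}|{treatment}|{cell}"] = compute_rpkm(track, peaks, halfwidth, mode)
    index = [c.peak.name if c.peak.name != "." else f"c{i}" for i, c in enumerate(constituents)]
    return pd.DataFrame(cols, index=index)


def subcluster_averages(
    density: pd.DataFrame, labels: Sequence[str]
) -> pd.DataFrame:
    """Mean density per sub-cluster label (rows aligned with the matrix)."""
    return density.groupby(pd.Series(list(labels), index=density.index)).mean()


def correlation_matrix(
    density: pd.DataFrame, eps: float = 0.1, log_scale: bool = True
) -> pd.DataFrame:
    """Pearson correlation between track columns on log2(RPKM + eps).

    The diagonal is exactly 1; columns with zero variance yield NaN
    off-diagonal entries (undefined, deliberately not 0).
    """
    if len(density) < 3:
        raise ValueError("need >=3 rows to correlate")
    x = np.log2(density.to_numpy() + eps) if log_scale else density.to_numpy()
    sd = x.std(axis=0)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(x).max(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=np.float64)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=density.columns, columns=density.columns)


def count_cobound(
    constituents: Sequence[LabeledConstituent],
    collaborator_peaks: Dict[str, Sequence[Peak]],
    min_tfs: int = 2,
    halfwidth: int = 100,
) -> Dict[str, float]:
    """Fraction of constituents bound by >= min_tfs collaborating TFs.

    A collaborator binds a constituent iff one of its peaks overlaps the
    summit +/- halfwidth window. Returns fractions for >= min_tfs and for
    the complement (<= min_tfs - 1); the two always sum to 1.
    """
    if not constituents:
        return {"frac_cobound": 0.0, "frac_below": 0.0, "n": 0}
    sorted_peaks = {
        tf: sorted(ps, key=lambda p: (p.chrom, p.start))
        for tf, ps in collaborator_peaks.items()
    }
    n_cobound = 0
    for c in constituents:
        window = GenomicInterval(
            c.peak.chrom, max(0, c.peak.summit - halfwidth), c.peak.summit + halfwidth
        )
        n_tfs = sum(
            any(overlaps(window, p.interval) for p in ps)
            for ps in sorted_peaks.values()
        )
        if n_tfs >= min_tfs:
            n_cobound += 1
    frac = n_cobound / len(constituents)
    return {"frac_cobound": frac, "frac_below": 1.0 - frac, "n": len(constituents)}


def motif_composition(
    constituents_by_label: Dict[str, Sequence[str]],
    presence: Dict[str, Set[str]],
    pwm_ids: Sequence[str],
) -> Tuple[pd.DataFrame, Dict[str, Counter]]:
    """Single-motif / multiple / none composition per constituent label.

    Each constituent falls in exactly one category: the motif's own name if
    exactly one of ``pwm_ids`` has a (thresholded) hit, "multiple" if >= 2
    (the combination is recorded), "none" if 0. Percentages sum to 100 per
    label. Returns the composition table and per-label combination counters.
    """
    categories = list(pwm_ids) + ["multiple", "none"]
    rows = {}
    combos: Dict[str, Counter] = {}
    for label, rids in constituents_by_label.items():
        counter = Counter()
        combo = Counter()
        for rid in rids:
            present = sorted(presence.get(rid, set()) & set(pwm_ids))
            if len(present) == 0:
                counter["none"] += 1
            elif len(present) == 1:
                counter[present[0]] += 1
            else:
                counter["multiple"] += 1
                combo["+".join(present)] += 1
        total = max(1, sum(counter.values()))
        rows[label] = {c: 100.0 * counter.get(c, 0) / total for c in categories}
        rows[label]["n"] = sum(counter.values())
        combos[label] = combo
    table = pd.DataFrame(rows).T
    return table, combos


def cluster_abundance_ratios(
    n_a_specific: int, n_shared: int, n_b_specific: int
) -> Tuple[float, float]:
    """Cell-line-specific over shared constituent-count ratios (A/shared,
    B/shared) — the headline abundance comparison between the clusters."""
    if n_shared <= 0:
        raise ValueError("shared count must be positive")
    return n_a_specific / n_shared, n_b_specific / n_shared
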