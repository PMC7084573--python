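"""Super-enhancer calling by peak stitching and the slope-1 rank cutoff.

Enhancer peaks closer than a stitch gap (default 12.5 kb, edge-to-edge,
strict "closer than") merge into candidate regions. Candidates are ranked by
tag density (rpm/bp) on the master-TF coverage track, the curve is scaled to
the unit square, and super-enhancers are the candidates strictly above the
point where a slope-1 line is tangent to the curve — the discrete argmin of
(y_scaled - x_scaled), ties broken toward the largest index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .core import CoverageTrack, GenomicInterval, Peak

__all__ = [
    "SECandidate",
    "RankedCurve",
    "SECall",
    "stitch_peaks",
    "rank_candidates",
    "call_superenhancers",
    "slope_cutoff_index",
]


@dataclass
class SECandidate:
    """A stitched enhancer region with its constituent peaks."""

    region: GenomicInterval
    constituents: List[Peak]
    tag_density: float = 0.0  # rpm/bp once ranked

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass
class RankedCurve:
    """Candidates sorted by ascending tag density, scaled to the unit square."""

    candidates: List[SECandidate]
    x_scaled: np.ndarray
    y_scaled: np.ndarray

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass
class SECall:
    candidates: List[SECandidate]  # in rank order
    is_super: np.ndarray  # bool per candidate
    cutoff_index: int

    @property
    def superenhancers(self) -> List[SECandidate]:
        return [c for c, s in zip(self.candidates, self.is_super) if s]


def stitch_peaks(peaks: Sequence[Peak], max_gap: int) -> List[SECandidate]:
    """Merge peaks whose edge-to-edge gap is strictly below ``max_gap``.

    Merging is transitive per chromosome; the candidate region is the hull of
    its constituents. Output is ordered by (chrom, start). Stitching its own
    output is a no-op.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    by_chrom = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    candidates: List[SECandidate] = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        group: List[Peak] = []
        group_end = None
        for p in chrom_peaks:
            if group and p.start - group_end >= max_gap:
                candidates.append(_make_candidate(group))
                group = []
            group.append(p)
            group_end = p.end if group_end is None or p.end > group_end else group_end
            if len(group) == 1:
                group_end = p.end
        if group:
            candidates.append(_make_candidate(group))
    return candidates


def _make_candidate(group: List[Peak]) -> SECandidate:
    region = GenomicInterval(
        group[0].chrom, min(p.start for p in group), max(p.end for p in group)
    )
    return SECandidate(region=region, constituents=list(group))


def rank_candidates(
    candidates: Sequence[SECandidate], track: CoverageTrack, mode: str = "overlap"
) -> RankedCurve:
    """Rank candidates by tag density on the master-TF track.

    tag_density = (reads in region / region length in bp) / (library / 1e6),
    i.e. reads per million per bp. Sorting is ascending with deterministic
    ties (region start, then chrom).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to rank")
    per_million = track.total_mapped_reads / 1e6
    cands = []
    for c in candidates:
        reads = track.reads_in(c.region.chrom, c.region.start, c.region.end, mode)
        density = (reads / len(c.region)) / per_million
        cands.append(SECandidate(c.region, c.constituents, density))
    cands.sort(key=lambda c: (c.tag_density, c.region.start, c.region.chrom))
    dens = np.array([c.tag_density for c in cands], dtype=np.float64)
    if dens[-1] <= 0:
        raise ValueError("all candidate tag densities are zero — no signal")
    n = len(cands)
    x = np.arange(n, dtype=np.float64) / (n - 1)
    y = dens / dens[-1]
    return RankedCurve(cands, x, y)


def slope_cutoff_index(x_scaled: np.ndarray, y_scaled: np.ndarray) -> int:
    """Index where a slope-1 line is tangent to the scaled rank curve.

    Discrete argmin of (y - x); ties resolved to the largest index so a flat
    tail yields zero super-enhancers.
    """
    diff = np.asarray(y_scaled) - np.asarray(x_scaled)
    return int(len(diff) - 1 - np.argmin(diff[::-1]))


def call_superenhancers(curve: RankedCurve) -> SECall:
    """Flag candidates strictly above the slope-1 tangent point as SEs."""
    cutoff = slope_cutoff_index(curve.x_scaled, curve.y_scaled)
    is_super = np.arange(len(curve)) > cutoff
    return SECall(curve.candidates, is_super, cutoff)
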