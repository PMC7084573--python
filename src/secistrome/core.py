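"""Genomic interval/peak/coverage data model, standard-format I/O and RPKM.

All coordinates are 0-based half-open (BED/narrowPeak native). A window of
half-width ``h`` around a summit ``s`` is ``[s - h, s + h)`` — length ``2h``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Dict, Iterable, List, Literal, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "CoverageTrack",
    "AnalysisConfig",
    "overlaps",
    "read_peaks",
    "write_peaks",
    "read_bed_intervals",
    "filter_blacklist",
    "compute_rpkm",
    "PeakParseError",
]


class PeakParseError(ValueError):
    """Raised on a malformed peak/BED record; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A called TF binding site with a summit position.

    The summit is an absolute base position inside the interval; it anchors
    every summit-centred window downstream (RPKM, motif frames).
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValueError("peak score must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap: true iff same chrom and the intervals share >=1 bp."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class CoverageTrack:
    """Stepwise read-count track: sorted disjoint intervals per chromosome.

    Interval values are read counts (reads whose 5' start falls in the
    interval, as emitted by the simulator and typical bedGraph pileups of
    read starts). ``total_mapped_reads`` is the library size used for rpm
    normalisation; it is supplied separately because library size comes from
    the alignment, not from the track contents.
    """

    def __init__(
        self,
        data: Dict[str, tuple],
        total_mapped_reads: int,
    ) -> None:
        if total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")
        self.total_mapped_reads = int(total_mapped_reads)
        self._data: Dict[str, tuple] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: ragged track arrays")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative coverage values")
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted interval")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: intervals overlap or are unsorted")
            self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> List[str]:
        return list(self._data)

    def reads_in(
        self, chrom: str, start: int, end: int, mode: str = "overlap"
    ) -> float:
        """Reads attributed to window ``[start, end)``.

        mode="overlap": a track interval contributes its full count if it
        overlaps the window by >=1 bp. mode="five_prime": an interval
        contributes iff its start (the binned read 5' position) lies in the
        window.
        """
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        if mode == "overlap":
            lo = int(np.searchsorted(ends, start, side="right"))
            hi = int(np.searchsorted(starts, end, side="left"))
        elif mode == "five_prime":
            lo = int(np.searchsorted(starts, start, side="left"))
            hi = int(np.searchsorted(starts, end, side="left"))
        else:
            raise ValueError(f"unknown read-counting mode {mode!r}")
        return float(values[lo:hi].sum()) if hi > lo else 0.0

    @classmethod
    def from_bedgraph(cls, path, total_mapped_reads: int) -> "CoverageTrack":
        per_chrom: Dict[str, List[List]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise PeakParseError(f"{path}:{lineno}: need 4 bedGraph columns")
                chrom = parts[0]
                try:
                    s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
                except ValueError as exc:
                    raise PeakParseError(f"{path}:{lineno}: {exc}") from None
                per_chrom.setdefault(chrom, [[], [], []])
                per_chrom[chrom][0].append(s)
                per_chrom[chrom][1].append(e)
                per_chrom[chrom][2].append(v)
        data = {}
        for chrom, (ss, ee, vv) in per_chrom.items():
            order = np.argsort(np.asarray(ss, dtype=np.int64), kind="stable")
            data[chrom] = (
                np.asarray(ss, dtype=np.int64)[order],
                np.asarray(ee, dtype=np.int64)[order],
                np.asarray(vv, dtype=np.float64)[order],
            )
        return cls(data, total_mapped_reads)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._data):
                starts, ends, values = self._data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


@dataclass
class AnalysisConfig:
    """Every numeric analysis parameter, with the published defaults.

    stitch_gap_bp: peaks closer than this merge into one SE candidate.
    rpkm_halfwidth_bp: RPKM window half-width around summits.
    motif_halfwidth_bp: half-width of the summit window for top motif scores
        and collaborator co-binding.
    motif_window_bp / motif_frame_bp: bin width and frame for motif
        distribution matrices (50 bins at defaults).
    annot_halfwidth_bp: SE centre extension for gene annotation.
    min_fpkm: expression floor for the nearest-gene annotation fallback.
    fold_threshold: expression fold band separating SIMILAR from specific.
    fpkm_pseudocount: added to FPKM before fold ratios.
    promoter_upstream_bp / promoter_downstream_bp: strand-aware promoter
        extent around the TSS.
    min_cobind_tfs: collaborating-TF count defining "co-bound".
    """

    stitch_gap_bp: int = 12500
    rpkm_halfwidth_bp: int = 50
    motif_halfwidth_bp: int = 100
    motif_window_bp: int = 30
    motif_frame_bp: int = 1500
    annot_halfwidth_bp: int = 100000
    min_fpkm: float = 1.0
    fold_threshold: float = 2.0
    fpkm_pseudocount: float = 0.1
    promoter_upstream_bp: int = 1000
    promoter_downstream_bp: int = 100
    min_cobind_tfs: int = 2
    read_count_mode: str = "overlap"  # or "five_prime"

    def validate(self) -> List[str]:
        """Return a list of problems (empty when valid)."""
        problems = []
        for f in fields(self):
            if f.name in ("read_count_mode",):
                continue
            value = getattr(self, f.name)
            if value <= 0:
                problems.append(f"{f.name} must be positive (got {value})")
        if self.fold_threshold <= 1:
            problems.append("fold_threshold must be > 1")
        if self.motif_frame_bp % self.motif_window_bp != 0:
            problems.append("motif_frame_bp must be divisible by motif_window_bp")
        if self.read_count_mode not in ("overlap", "five_prime"):
            problems.append(f"unknown read_count_mode {self.read_count_mode!r}")
        return problems


def _parse_int(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise PeakParseError(
            f"{path}:{lineno}: non-integer {what} {token!r}"
        ) from None


def read_peaks(path, format: Literal["narrowPeak", "bed6"] = "narrowPeak") -> List[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) or BED6 file into Peak records.

    narrowPeak summits come from column 10 (offset from start); an offset of
    -1 means unspecified and falls back to the interval midpoint, as does
    BED6 input. Records whose stored summit falls outside the interval are
    rejected with a warning rather than aborting the run.
    """
    peaks: List[Peak] = []
    min_cols = 10 if format == "narrowPeak" else 4
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise PeakParseError(
                    f"{path}:{lineno}: expected >={min_cols} columns, got {len(parts)}"
                )
            chrom = parts[0]
            start = _parse_int(parts[1], path, lineno, "start")
            end = _parse_int(parts[2], path, lineno, "end")
            if start >= end:
                raise PeakParseError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 and parts[3] else "."
            try:
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            except ValueError:
                raise PeakParseError(
                    f"{path}:{lineno}: non-numeric score {parts[4]!r}"
                ) from None
            if format == "narrowPeak":
                offset = _parse_int(parts[9], path, lineno, "summit offset")
                summit = (start + end) // 2 if offset == -1 else start + offset
                try:
                    score = float(parts[6])  # signalValue is the usual strength
                except ValueError:
                    pass
            else:
                summit = (start + end) // 2
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end), summit, max(score, 0.0), name)
                )
            except ValueError as exc:
                import warnings

                warnings.warn(f"{path}:{lineno}: record rejected ({exc})")
    return peaks


def write_peaks(peaks: Iterable[Peak], path, format: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if format == "narrowPeak":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                    f"{p.score:g}\t-1\t-1\t{p.summit - p.start}\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\n")


def read_bed_intervals(path) -> List[GenomicInterval]:
    """Read BED3+ into plain intervals (used for blacklists and SE regions)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PeakParseError(f"{path}:{lineno}: expected >=3 columns")
            out.append(
                GenomicInterval(
                    parts[0],
                    _parse_int(parts[1], path, lineno, "start"),
                    _parse_int(parts[2], path, lineno, "end"),
                )
            )
    return out


def filter_blacklist(
    peaks: Sequence[Peak], blacklist: Sequence[GenomicInterval]
) -> List[Peak]:
    """Drop peaks overlapping any blacklisted region by >=1 bp; order kept."""
    if not blacklist:
        return list(peaks)
    by_chrom: Dict[str, List[tuple]] = {}
    for iv in blacklist:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    kept = []
    for p in peaks:
        ivs = by_chrom.get(p.chrom)
        if ivs is None:
            kept.append(p)
            continue
        # first blacklist interval whose end > peak.start
        idx = bisect.bisect_right([e for _, e in ivs], p.start)
        if idx >= len(ivs) or ivs[idx][0] >= p.end:
            kept.append(p)
    return kept


def compute_rpkm(
    track: CoverageTrack,
    peaks: Sequence[Peak],
    halfwidth: int,
    mode: str = "overlap",
) -> np.ndarray:
    """Summit-window RPKM for each peak.

    The window is ``[summit - halfwidth, summit + halfwidth)`` (length 2h);
    RPKM = reads_in_window / ((window_kb) * (library_size / 1e6)). Reads are
    counted whole when their stored interval overlaps the window (default) or
    when their 5' start lies inside it (mode="five_prime").
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if track.total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    length_kb = (2 * halfwidth) / 1000.0
    per_million = track.total_mapped_reads / 1e6
    out = np.empty(len(peaks), dtype=np.float64)
    for i, p in enumerate(peaks):
        reads = track.reads_in(p.chrom, p.summit - halfwidth, p.summit + halfwidth, mode)
        out[i] = reads / (length_kb * per_million)
    return out
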