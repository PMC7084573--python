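"""PWM motif scanning, score thresholds, distribution matrices and enrichment.

Motifs are position probability matrices over (A, C, G, T) scored as summed
log2-odds against a background composition (uniform by default). Scanning
covers both strands; the minus strand scores the reverse complement of each
window. Downstream analyses use the top score per summit-centred window, a
score threshold per motif (heuristic or manual), binned hit-position
matrices in 30-bp windows within 1.5-kb frames, presence/absence
sub-clustering, and a binomial known-motif enrichment test against
background regions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import Peak

__all__ = [
    "PWM",
    "MotifHit",
    "MotifScoreThreshold",
    "read_pfm",
    "scan",
    "top_motif_score",
    "motif_distribution",
    "cluster_by_motif_presence",
    "enrichment_test",
    "select_score_threshold",
    "NEG_INF",
]

NEG_INF = float("-inf")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0], dtype=np.int64)


@dataclass(frozen=True)
class PWM:
    """Probability matrix (L x 4 over A,C,G,T) with background frequencies."""

    id: str
    matrix: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        bg = np.asarray(self.background, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if np.any(m <= 0):
            raise ValueError("PWM entries must be positive after regularization")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(
        cls,
        id: str,
        counts: Sequence[Sequence[float]],
        background: Optional[Sequence[float]] = None,
        pseudocount: float = 0.001,
    ) -> "PWM":
        """Build from a count (or probability) matrix, rows = positions.

        Counts are normalised per row, a small pseudocount is added and the
        row renormalised so every entry is strictly positive.
        """
        c = np.asarray(counts, dtype=np.float64)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError("count matrix must be L x 4 (A,C,G,T columns)")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        sums = c.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValueError("a PWM row has zero total count")
        p = c / sums + pseudocount
        p /= p.sum(axis=1, keepdims=True)
        bg = (
            np.full(4, 0.25) if background is None else np.asarray(background, float)
        )
        return cls(id, p, bg)


@dataclass(frozen=True)
class MotifHit:
    """A scored, stranded motif occurrence within a region."""

    pwm_id: str
    region_id: str
    offset: int  # from region start, 0-based
    strand: str  # '+' or '-'
    score: float  # bits


@dataclass(frozen=True)
class MotifScoreThreshold:
    pwm_id: str
    threshold: float
    provenance: str  # 'manual' or 'heuristic'


def read_pfm(path_or_handle, id: Optional[str] = None) -> PWM:
    """Read one JASPAR-style PFM (4-row count or probability matrix).

    Accepts the JASPAR layout with a ``>`` header and ``A [ ... ]`` rows, or
    a bare 4-row matrix (rows in A, C, G, T order). Parsing goes through
    Bio.motifs; regularisation (pseudocount 0.001) is applied here.
    """
    from Bio import motifs as bio_motifs

    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
        name = id or "pfm"
    else:
        with open(path_or_handle) as fh:
            text = fh.read()
        name = id or str(path_or_handle)
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    fmt = "jaspar" if any(ln.startswith(">") for ln in lines) else "pfm"
    n_rows = len([ln for ln in lines if not ln.startswith(">")])
    if n_rows != 4:
        raise ValueError(f"expected 4 matrix rows, got {n_rows}")
    motif = bio_motifs.read(io.StringIO(text), fmt)
    counts = np.array([list(motif.counts[b]) for b in _BASES], dtype=np.float64).T
    motif_id = getattr(motif, "matrix_id", None) or motif.name or name
    return PWM.from_counts(str(motif_id), counts)


def _encode(sequence: str) -> np.ndarray:
    """Map a DNA string to indices 0-3; anything not ACGT becomes -1 (N)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        idx[arr == ord(base)] = i
    return idx


def scan(sequence: str, pwm: PWM, region_id: str = ".") -> List[MotifHit]:
    """Score every offset on both strands; windows containing N are skipped.

    Scores are summed log2-odds in bits. All valid positions are reported;
    thresholding is the caller's job.
    """
    L = pwm.length
    idx = _encode(sequence)
    n = len(idx) - L + 1
    if n <= 0:
        return []
    lom = pwm.log_odds
    rc_lom = lom[::-1, ::-1]  # scanning with this == scoring the revcomp window
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = ~np.any(windows < 0, axis=1)
    pos = np.arange(L)
    safe = np.where(windows < 0, 0, windows)
    plus = lom[pos, safe].sum(axis=1)
    minus = rc_lom[pos, safe].sum(axis=1)
    hits: List[MotifHit] = []
    for o in np.nonzero(valid)[0]:
        hits.append(MotifHit(pwm.id, region_id, int(o), "+", float(plus[o])))
        hits.append(MotifHit(pwm.id, region_id, int(o), "-", float(minus[o])))
    return hits


def top_motif_score(
    peak: Peak, genome, pwm: PWM, halfwidth: int
) -> float:
    """Best scan score (both strands) in the summit +/- halfwidth window.

    ``genome`` is any mapping of chromosome name to sequence supporting
    slicing (a ``pyfaidx.Fasta`` or a plain dict of strings). Returns -inf
    when no valid window exists (short region or all-N sequence).
    """
    start = max(0, peak.summit - halfwidth)
    end = peak.summit + halfwidth
    seq = str(genome[peak.chrom][start:end])
    hits = scan(seq, pwm)
    if not hits:
        return NEG_INF
    return max(h.score for h in hits)


def top_scores_for_regions(
    peaks: Sequence[Peak], genome, pwm: PWM, halfwidth: int
) -> np.ndarray:
    return np.array([top_motif_score(p, genome, pwm, halfwidth) for p in peaks])


def motif_distribution(
    regions: Sequence[Peak],
    hits_by_region: Dict[str, List[MotifHit]],
    pwms: Sequence[PWM],
    frame: int = 1500,
    window: int = 30,
) -> np.ndarray:
    """Hit-count matrix: regions x (frame/window) bins x motifs.

    A hit's centre is region_start + offset + L//2; its bin is
    floor((centre - (summit - frame/2)) / window). Hits outside the frame
    are dropped. Input hits are expected to be pre-thresholded.
    """
    if frame % window != 0:
        raise ValueError("frame must be divisible by window")
    n_bins = frame // window
    pwm_index = {p.id: i for i, p in enumerate(pwms)}
    lengths = {p.id: p.length for p in pwms}
    out = np.zeros((len(regions), n_bins, len(pwms)), dtype=np.int64)
    for ri, region in enumerate(regions):
        for hit in hits_by_region.get(region.name, []):
            if hit.pwm_id not in pwm_index:
                continue
            center = region.start + hit.offset + lengths[hit.pwm_id] // 2
            b = (center - (region.summit - frame // 2)) // window
            if 0 <= b < n_bins:
                out[ri, b, pwm_index[hit.pwm_id]] += 1
    return out


def cluster_by_motif_presence(
    region_ids: Sequence[str],
    hits_by_region: Dict[str, List[MotifHit]],
    pwm_order: Sequence[str],
) -> Dict[str, str]:
    """Presence/absence pattern per region over an ordered motif subset.

    The label is a binary string ('10' = first motif present, second absent);
    sorting region ids lexicographically by pattern reproduces the
    sub-cluster blocks of the distribution heat maps.
    """
    labels = {}
    for rid in region_ids:
        present = {h.pwm_id for h in hits_by_region.get(rid, [])}
        labels[rid] = "".join("1" if p in present else "0" for p in pwm_order)
    return labels


def enrichment_test(
    target_top_scores: Sequence[float],
    background_top_scores: Sequence[float],
    threshold: float,
) -> Tuple[float, float, float]:
    """Known-motif enrichment of target regions over background regions.

    A region "has" the motif iff its top score >= threshold. Returns
    (target fraction, background fraction, one-sided binomial upper-tail
    p-value of the target hit count at the background rate). An empty-hit
    background with target hits uses rate 1/(n_background + 1).
    """
    t = np.asarray(target_top_scores, dtype=np.float64)
    b = np.asarray(background_top_scores, dtype=np.float64)
    if len(t) == 0:
        raise ValueError("empty target set")
    if len(b) == 0:
        raise ValueError("empty background set")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    k = int((t >= threshold).sum())
    n = len(t)
    bg_frac = float((b >= threshold).mean())
    rate = bg_frac if (bg_frac > 0 or k == 0) else 1.0 / (len(b) + 1)
    p = float(stats.binom.sf(k - 1, n, rate)) if k > 0 else 1.0
    return k / n, bg_frac, p


def select_score_threshold(
    scores: Sequence[float],
    pwm_id: str = ".",
    bin_width: float = 1.0,
    peak_height_factor: float = 2.0,
    manual: Optional[float] = None,
) -> MotifScoreThreshold:
    """Pick a score threshold just below the last high mode of the score
    distribution.

    Heuristic: histogram the finite scores with fixed-width bins, find local
    maxima whose height is at least ``peak_height_factor`` x the median bin
    height, and return the left edge of the rightmost such bin. A manual
    per-motif override takes precedence.
    """
    if manual is not None:
        return MotifScoreThreshold(pwm_id, float(manual), "manual")
    s = np.asarray([x for x in scores if np.isfinite(x)], dtype=np.float64)
    if len(s) < 20:
        raise ValueError(
            f"{pwm_id}: need >=20 finite scores to fit a threshold "
            "(set a manual threshold instead)"
        )
    lo, hi = s.min(), s.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(s, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    padded = np.concatenate([[-1], counts, [-1]])
    local_max = [
        i
        for i in range(len(counts))
        if counts[i] > 0
        and padded[i] <= padded[i + 1]
        and padded[i + 1] >= padded[i + 2]
    ]
    floor = peak_height_factor * float(np.median(counts))
    candidates = [i for i in local_max if counts[i] >= floor]
    if not candidates:
        candidates = [int(np.argmax(counts))]
    chosen = max(candidates)
    return MotifScoreThreshold(pwm_id, float(edges[chosen]), "heuristic")
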