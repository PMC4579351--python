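"""Smoothed peak calling, opposite-strand pairing, background normalization.

Peaks are called per strand on a Gaussian-smoothed pileup by greedy
maximum selection with an exclusion zone (sigma = 5, exclusion = 20 by
default).  A forward/reverse peak couple within the pairing span
represents one cross-link point; the pair midpoint estimates the
binding coordinate.  Cross-condition comparisons are put on a common
scale by equalizing tag totals outside peak-pair neighborhoods.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from exoarch.tagio import TagDataset

__all__ = [
    "Peak",
    "PeakPair",
    "NormalizationError",
    "smooth",
    "call_peaks",
    "pair_peaks",
    "filter_pairs",
    "normalize_background",
]


class NormalizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Peak:
    chrom: str
    coordinate: int
    strand: str
    height: float
    tag_count: int


@dataclass(frozen=True)
class PeakPair:
    fwd: Peak
    rev: Peak
    midpoint: float
    span: int
    count: int


def gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete Gaussian kernel, unit mass, truncated at ±truncate*sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = max(1, int(np.ceil(truncate * sigma)))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth(counts: np.ndarray, sigma: float = 5.0, truncate: float = 4.0) -> np.ndarray:
    """Mass-conserving Gaussian smoothing of a per-base count array.

    The kernel sums to 1; near the array edges the kernel is truncated
    and renormalized per source position, so every count contributes
    exactly unit mass to the output wherever it sits.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be 1-D")
    kernel = gaussian_kernel(sigma, truncate)
    # fraction of the kernel that stays in-bounds when centered at i
    coverage = convolve1d(np.ones_like(counts), kernel, mode="constant", cval=0.0)
    return convolve1d(counts / coverage, kernel, mode="constant", cval=0.0)


def call_peaks(
    density: np.ndarray,
    exclusion: int = 20,
    min_height: float = 0.0,
    *,
    offset: int = 0,
    chrom: str = "",
    strand: str = ".",
    raw_counts: np.ndarray | None = None,
) -> list[Peak]:
    """Greedy exclusion-zone peak calling on a density array.

    Repeatedly takes the global maximum (ties broken to the lower
    coordinate), emits a peak, and suppresses every position closer
    than ``exclusion`` bp center-to-center; stops once the remaining
    maximum is <= ``min_height``.  Retained peaks are therefore always
    >= ``exclusion`` bp apart.

    ``raw_counts``, when given, fills each peak's ``tag_count`` with the
    unsmoothed tag total within ``exclusion // 2`` bp of the summit.
    ``offset`` translates array indices to genomic coordinates.
    """
    if exclusion < 1:
        raise ValueError("exclusion must be >= 1")
    density = np.asarray(density, dtype=float)
    n = len(density)
    # process candidates in order of descending height, ascending index;
    # a candidate is kept iff no higher kept peak lies within the zone
    candidates = np.nonzero(density > min_height)[0]
    if len(candidates) == 0:
        return []
    order = candidates[np.lexsort((candidates, -density[candidates]))]
    blocked = np.zeros(n, dtype=bool)
    summits: list[int] = []
    for i in order:
        if blocked[i]:
            continue
        summits.append(int(i))
        lo = max(0, i - exclusion + 1)
        hi = min(n, i + exclusion)
        blocked[lo:hi] = True
    summits.sort()
    half = exclusion // 2
    peaks = []
    for i in summits:
        if raw_counts is not None:
            lo = max(0, i - half)
            hi = min(n, i + half + 1)
            tag_count = int(np.asarray(raw_counts)[lo:hi].sum())
        else:
            tag_count = 0
        peaks.append(
            Peak(
                chrom=chrom,
                coordinate=i + offset,
                strand=strand,
                height=float(density[i]),
                tag_count=tag_count,
            )
        )
    return peaks


def pair_peaks(
    fwd_peaks: list[Peak], rev_peaks: list[Peak], max_span: int = 100
) -> list[PeakPair]:
    """Pair forward peaks with downstream reverse peaks within max_span.

    Candidate couples have the reverse peak at a coordinate >= the
    forward peak's and within ``max_span`` bp in the 3' direction.
    Matching is one-to-one and greedy by ascending span (ties to the
    left-most forward peak); unpaired peaks are dropped.
    """
    candidates = []
    for fi, f in enumerate(fwd_peaks):
        for ri, r in enumerate(rev_peaks):
            span = r.coordinate - f.coordinate
            if 0 <= span <= max_span:
                candidates.append((span, f.coordinate, r.coordinate, fi, ri))
    candidates.sort()
    used_f: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for span, _, _, fi, ri in candidates:
        if fi in used_f or ri in used_r:
            continue
        used_f.add(fi)
        used_r.add(ri)
        f, r = fwd_peaks[fi], rev_peaks[ri]
        pairs.append(
            PeakPair(
                fwd=f,
                rev=r,
                midpoint=(f.coordinate + r.coordinate) / 2.0,
                span=span,
                count=f.tag_count + r.tag_count,
            )
        )
    pairs.sort(key=lambda p: p.midpoint)
    return pairs


def filter_pairs(pairs: list[PeakPair], min_count: int = 2) -> list[PeakPair]:
    """Keep pairs whose tag count strictly exceeds ``min_count``."""
    return [p for p in pairs if p.count > min_count]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def _background_total(tags: TagDataset, excluded: dict[str, list[tuple[int, int]]]) -> float:
    """Weighted tag total outside the excluded intervals."""
    in_bg = np.ones(len(tags), dtype=bool)
    for chrom, intervals in excluded.items():
        on_chrom = tags.chroms == chrom
        for s, e in intervals:
            in_bg &= ~(on_chrom & (tags.pos >= s) & (tags.pos < e))
    return float(in_bg.sum()) * tags.weight


def normalize_background(
    tags_a: TagDataset,
    tags_b: TagDataset,
    pairs: list[PeakPair],
    flank: int = 100,
) -> tuple[float, TagDataset]:
    """Scale dataset B so background tag totals match dataset A.

    Background is everything outside the ``2 * flank`` bp interval
    centered on each peak-pair midpoint.  Returns the scale factor and
    B with its per-tag weight multiplied by it.
    """
    excluded: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        mid = int(round(p.midpoint))
        excluded.setdefault(p.fwd.chrom, []).append((mid - flank, mid + flank))
    excluded = {c: _merge_intervals(iv) for c, iv in excluded.items()}
    bg_a = _background_total(tags_a, excluded)
    bg_b = _background_total(tags_b, excluded)
    if bg_b <= 0:
        raise NormalizationError("dataset B has zero background total")
    scale = bg_a / bg_b
    scaled = dataclasses.replace(tags_b, weight=tags_b.weight * scale)
    return scale, scaled
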