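"""Factor occupancy quantification and normalization.

Occupancies are tag sums over orientation-corrected windows relative to
the TSS (upstream factors 0 to -400, PIC -200 to +200, polymerase 0 to
+400), normalized per factor to the cohort median and log2-transformed,
with percent ranks over the cohort.  Also: binding-breadth measurement
and classification, heat-shock fold changes, ectopic PIC fractions, and
the factor-factor Pearson matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from exoarch.peakcall import smooth
from exoarch.tagio import TagDataset, pileup

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyTable",
    "BreadthRecord",
    "DEFAULT_WINDOWS",
    "window_sum",
    "occupancy_table",
    "normalize_table",
    "rap1_site_occupancy",
    "hmo1_breadth",
    "classify_breadth",
    "heatshock_fold_change",
    "ectopic_fraction",
    "correlation_matrix",
]

#: default orientation-corrected occupancy windows per factor group
DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    "upstream": (-400, 0),   # activator / coactivators / HMG-box
    "pic": (-200, 200),      # TFIIB, TFIIA, TAFs
    "polymerase": (0, 400),  # Pol II
}


@dataclass
class OccupancyTable:
    """Genes x factors occupancy with raw, log2 and percent-rank layers."""

    raw: pd.DataFrame
    log2: pd.DataFrame | None = None
    percent_rank: pd.DataFrame | None = None


@dataclass(frozen=True)
class BreadthRecord:
    gene_id: str
    breadth: int
    group: str = "unassigned"


def _oriented_mask(
    tags: TagDataset, chrom: str, tss: int, strand: str, lo: int, hi: int
) -> np.ndarray:
    """Boolean mask of tags inside the oriented half-open window [lo, hi)."""
    on = tags.chroms == chrom
    if strand == "+":
        off = tags.pos - tss
    else:
        off = tss - tags.pos
    return on & (off >= lo) & (off < hi)


def window_sum(
    tags: TagDataset,
    chrom: str,
    tss: int,
    strand: str,
    window: tuple[int, int],
) -> float:
    """Weighted tag count inside an oriented TSS-relative window.

    ``window`` is half-open [lo, hi) in gene orientation; reverse-strand
    genes mirror it.  Tags should already be shifted to cross-link
    coordinates.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    mask = _oriented_mask(tags, chrom, tss, strand, lo, hi)
    return float(mask.sum()) * tags.weight


def occupancy_table(
    tag_sets: dict[str, TagDataset],
    genes: pd.DataFrame,
    windows: dict[str, tuple[int, int]],
) -> OccupancyTable:
    """Raw occupancy for several factors over a gene table.

    ``genes`` needs gene_id, chrom, tss, strand columns; ``windows``
    maps each factor to its oriented window.
    """
    data = {}
    for factor, tags in tag_sets.items():
        win = windows[factor]
        data[factor] = [
            window_sum(tags, r.chrom, r.tss, r.strand, win)
            for r in genes.itertuples()
        ]
    raw = pd.DataFrame(data, index=pd.Index(genes["gene_id"], name="gene_id"))
    return OccupancyTable(raw=raw)


def normalize_table(table: OccupancyTable, pseudocount: float = 1.0) -> OccupancyTable:
    """Add log2 median-normalized and percent-rank layers.

    Per factor column: value -> log2(raw / median over the cohort);
    zeros are lifted by ``pseudocount`` first (logged).  Percent rank =
    average rank / n * 100, ties averaged.
    """
    raw = table.raw
    if len(raw) < 2:
        raise ValueError("need >= 2 genes to normalize")
    adj = raw.copy().astype(float)
    n_zero = int((adj <= 0).to_numpy().sum())
    if n_zero:
        logger.info("normalize_table: lifting %d zero entries by +%g", n_zero, pseudocount)
        adj = adj.mask(adj <= 0, pseudocount)
    med = adj.median(axis=0)
    if (med <= 0).any():
        bad = list(med.index[med <= 0])
        raise ValueError(f"all-zero occupancy column(s): {bad}")
    log2 = np.log2(adj / med)
    pct = raw.rank(axis=0, method="average", pct=True) * 100.0
    return OccupancyTable(raw=raw, log2=log2, percent_rank=pct)


def rap1_site_occupancy(
    tags: TagDataset,
    chrom: str,
    site: int,
    orientation: str,
    at_window: tuple[int, int] = (-40, 40),
    downstream_window: tuple[int, int] = (60, 180),
    normalize: str | None = "flank",
    flank_windows: tuple[tuple[int, int], ...] = ((-220, -80), (220, 360)),
) -> tuple[float, float]:
    """Tag sums at a bound site and in the downstream region.

    Windows are inclusive on both ends and oriented toward the site's
    gene.  With ``normalize="flank"`` each sum is divided by the
    expected count at the flanking background rate over the same width;
    ``normalize=None`` returns raw sums.
    """

    def inclusive_sum(lo: int, hi: int) -> float:
        return window_sum(tags, chrom, site, orientation, (lo, hi + 1))

    at = inclusive_sum(*at_window)
    down = inclusive_sum(*downstream_window)
    if normalize is None:
        return at, down
    if normalize != "flank":
        raise ValueError(f"unknown normalization {normalize!r}")
    flank_total = sum(inclusive_sum(lo, hi) for lo, hi in flank_windows)
    flank_width = sum(hi - lo + 1 for lo, hi in flank_windows)
    rate = flank_total / flank_width
    if rate <= 0:
        return at, down
    at_w = at_window[1] - at_window[0] + 1
    dn_w = downstream_window[1] - downstream_window[0] + 1
    return at / (rate * at_w), down / (rate * dn_w)


def hmo1_breadth(
    hmo1_tags: TagDataset,
    gene_id: str,
    chrom: str,
    tss: int,
    strand: str,
    rap1_site: int,
    *,
    sigma: float = 5.0,
    threshold_rule: str = "3x_background",
    background_rate: float | None = None,
) -> BreadthRecord:
    """Number of above-threshold positions between the bound site and TSS.

    The smoothed tag density between the most upstream bound site and
    the TSS is thresholded; the breadth is the count of positions above
    threshold.  Rules: ``3x_background`` (3x the genome-wide tag rate),
    ``half_max`` (half the regional maximum), or ``combined`` (the max
    of the two, robust for signal-free genes).
    """
    lo, hi = (rap1_site, tss) if rap1_site <= tss else (tss, rap1_site)
    if hi <= lo:
        raise ValueError(f"{gene_id}: bound site and TSS coincide")
    pad = int(4 * sigma) + 1
    p = pileup(hmo1_tags, chrom, max(0, lo - pad), hi + pad)
    dens = smooth(p.counts_all.astype(float), sigma=sigma)
    region = dens[lo - p.start : hi - p.start]

    if background_rate is None:
        span = hmo1_tags.pos.max() - hmo1_tags.pos.min() + 1 if len(hmo1_tags) else 1
        background_rate = len(hmo1_tags) / max(span, 1)
    thr_bg = 3.0 * background_rate
    thr_hm = 0.5 * region.max() if len(region) else np.inf
    if threshold_rule == "3x_background":
        thr = thr_bg
    elif threshold_rule == "half_max":
        thr = thr_hm
    elif threshold_rule == "combined":
        thr = max(thr_bg, thr_hm)
    elif threshold_rule == "infinite":
        thr = np.inf
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    breadth = int((region > thr).sum())
    return BreadthRecord(gene_id=gene_id, breadth=breadth)


def classify_breadth(
    records: list[BreadthRecord],
    mode: str = "rank",
    group_sizes: tuple[int, int, int] = (30, 30, 58),
    bp_cutoffs: tuple[int, int] = (55, 135),
) -> list[BreadthRecord]:
    """Attach broad/narrow/none groups to breadth records.

    ``rank`` mode sorts by breadth descending and takes the top
    ``group_sizes[0]`` as broad, the next as narrow and the following as
    none, with any remainder left unassigned.  ``bp`` mode applies fixed
    cutoffs: breadth >= cutoffs[1] is broad, >= cutoffs[0] narrow,
    otherwise none.
    """
    if mode == "bp":
        narrow_min, broad_min = bp_cutoffs
        out = []
        for r in records:
            group = "broad" if r.breadth >= broad_min else (
                "narrow" if r.breadth >= narrow_min else "none"
            )
            out.append(BreadthRecord(r.gene_id, r.breadth, group))
        return out
    if mode != "rank":
        raise ValueError(f"unknown mode {mode!r}")
    n_broad, n_narrow, n_none = group_sizes
    ordered = sorted(records, key=lambda r: (-r.breadth, r.gene_id))
    out = []
    for i, r in enumerate(ordered):
        if i < n_broad:
            group = "broad"
        elif i < n_broad + n_narrow:
            group = "narrow"
        elif i < n_broad + n_narrow + n_none:
            group = "none"
        else:
            group = "unassigned"
        out.append(BreadthRecord(r.gene_id, r.breadth, group))
    order = {r.gene_id: r for r in out}
    return [order[r.gene_id] for r in records]


def heatshock_fold_change(
    occ_mock: pd.Series,
    occ_hs: pd.Series,
    breadth: pd.Series,
    n_groups: int = 4,
    pseudocount: float = 1.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene log2(hs/mock) and per-breadth-quartile summaries.

    Inputs must already be on a common scale (see background
    normalization).  Zero mock occupancies are lifted by the pseudocount
    (logged).  Returns (per-gene log2 FC, group table with mean/sd/n,
    quartile 1 = broadest).
    """
    occ_mock, occ_hs = occ_mock.align(occ_hs, join="inner")
    m = occ_mock.astype(float)
    h = occ_hs.astype(float)
    n_zero = int(((m <= 0) | (h <= 0)).sum())
    if n_zero:
        logger.info("heatshock_fold_change: %d zero entries lifted", n_zero)
    m = m.mask(m <= 0, pseudocount)
    h = h.mask(h <= 0, pseudocount)
    fc = np.log2(h / m)
    b = breadth.reindex(fc.index)
    # quartile 1 = broadest
    ranks = b.rank(method="first", ascending=False)
    quart = np.ceil(ranks / len(ranks) * n_groups).astype(int)
    groups = fc.groupby(quart).agg(["mean", "std", "count"])
    groups.index.name = "breadth_quartile"
    return fc, groups


def ectopic_fraction(
    pic_tags: TagDataset,
    chrom: str,
    tss: int,
    strand: str,
    ectopic_window: tuple[int, int] = (-200, -70),
    total_window: tuple[int, int] = (-200, 60),
) -> float | None:
    """Fraction of PIC signal in the ectopic upstream window.

    Sum over (TSS-200, TSS-70) divided by the sum over (TSS-200,
    TSS+60), orientation-corrected.  None when the denominator is zero.
    """
    total = window_sum(pic_tags, chrom, tss, strand, total_window)
    if total <= 0:
        return None
    ect = window_sum(pic_tags, chrom, tss, strand, ectopic_window)
    return ect / total


def correlation_matrix(table: OccupancyTable, layer: str = "log2") -> pd.DataFrame:
    """Factor x factor Pearson matrix on the chosen layer.

    Constant columns yield NaN rows/columns (correlation undefined).
    """
    df = getattr(table, layer)
    if df is None:
        raise ValueError(f"layer {layer!r} not computed")
    if len(df) < 3:
        raise ValueError("need >= 3 genes for correlations")
    return df.corr(method="pearson")
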