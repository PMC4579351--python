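"""Nucleosome dyad estimation and +1-nucleosome shift detection.

Dyads come from either size-selected MNase fragment midpoints or from
smoothed shifted histone ChIP-exo tags (histone cross-links flank the
dyad symmetrically, so the strand-collapsed mode approximates it).  The
+1 nucleosome is the density mode in a search window around the TSS;
condition-to-condition dyad shifts are signed in gene orientation
(negative = upstream).  A 147-bp core is assumed, i.e. edges at
dyad ± 73 bp.
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
    "DyadCall",
    "ShiftEstimate",
    "NUC_HALF_WIDTH",
    "dyads_from_fragments",
    "dyads_from_exo",
    "plus_one",
    "estimate_shift",
    "tss_burial",
]

NUC_HALF_WIDTH = 73  # 147-bp core


@dataclass(frozen=True)
class DyadCall:
    gene_id: str
    condition: str
    dyad: int
    support: float
    method: str


@dataclass(frozen=True)
class ShiftEstimate:
    gene_id: str
    delta: float
    method: str
    n_support: int


def dyads_from_fragments(
    starts: np.ndarray,
    ends: np.ndarray,
    region: tuple[int, int],
    size_range: tuple[int, int] = (120, 180),
) -> tuple[np.ndarray, int, int]:
    """Per-base dyad density from fragment midpoints inside a region.

    Fragments outside the size range are discarded (counted).  Odd
    lengths round the midpoint toward the 5' end.  Returns (density
    over [region), n kept, n discarded); kept + discarded = input.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    lo, hi = region
    lengths = ends - starts
    ok = (lengths >= size_range[0]) & (lengths <= size_range[1])
    n_discarded = int((~ok).sum())
    mids = (starts[ok] + ends[ok] - 1) // 2
    inside = (mids >= lo) & (mids < hi)
    density = np.bincount(mids[inside] - lo, minlength=hi - lo).astype(float)
    if n_discarded:
        logger.info(
            "dyads_from_fragments: discarded %d/%d fragments outside %s",
            n_discarded, len(starts), size_range,
        )
    return density, int(ok.sum()), n_discarded


def dyads_from_exo(
    histone_tags: TagDataset,
    chrom: str,
    region: tuple[int, int],
    sigma: float = 20.0,
) -> np.ndarray:
    """Smoothed strand-collapsed density of shifted histone tags.

    With symmetric cross-link points flanking the dyad, the mode of the
    smoothed density approximates the dyad.
    """
    if not histone_tags.shifted:
        raise ValueError("histone tags must be shifted first")
    lo, hi = region
    p = pileup(histone_tags, chrom, lo, hi)
    return smooth(p.counts_all.astype(float), sigma=sigma)


def plus_one(
    dyad_density: np.ndarray,
    region_start: int,
    tss: int,
    strand: str,
    search: tuple[int, int] = (-50, 150),
    gene_id: str = "",
    condition: str = "",
    method: str = "mnase_midpoint",
) -> DyadCall | None:
    """Call the +1 dyad as the density argmax in an oriented TSS window.

    Ties break toward the lower oriented offset (closer to / upstream of
    the search window's downstream end).  Support is the density mass
    within ±73 bp of the call.  Returns None for an empty window.
    """
    lo_off, hi_off = search
    best_off: int | None = None
    best_val = 0.0
    n = len(dyad_density)
    for off in range(lo_off, hi_off + 1):
        g = tss + off if strand == "+" else tss - off
        i = g - region_start
        if i < 0 or i >= n:
            continue
        v = dyad_density[i]
        if v > best_val:
            best_val = v
            best_off = off
    if best_off is None or best_val <= 0:
        return None
    dyad = tss + best_off if strand == "+" else tss - best_off
    i = dyad - region_start
    lo = max(0, i - NUC_HALF_WIDTH)
    hi = min(n, i + NUC_HALF_WIDTH + 1)
    support = float(dyad_density[lo:hi].sum())
    return DyadCall(
        gene_id=gene_id, condition=condition, dyad=int(dyad),
        support=support, method=method,
    )


def estimate_shift(
    calls_a: dict[str, DyadCall],
    calls_b: dict[str, DyadCall],
    genes: pd.DataFrame,
    group_by: pd.Series | None = None,
) -> tuple[list[ShiftEstimate], pd.DataFrame | None]:
    """Per-gene dyad shift b - a in gene orientation, plus group means.

    ``genes`` needs gene_id/strand columns (and optionally tss).  Genes
    missing a call in either condition are skipped (logged).  Negative
    delta = upstream shift.  ``group_by`` (gene_id -> label) adds a
    group table of mean/sd/n.
    """
    strands = dict(zip(genes["gene_id"], genes["strand"]))
    estimates: list[ShiftEstimate] = []
    skipped = 0
    for gene_id, strand in strands.items():
        a = calls_a.get(gene_id)
        b = calls_b.get(gene_id)
        if a is None or b is None:
            skipped += 1
            continue
        delta = b.dyad - a.dyad
        if strand == "-":
            delta = -delta
        estimates.append(
            ShiftEstimate(
                gene_id=gene_id,
                delta=float(delta),
                method=b.method,
                n_support=int(min(a.support, b.support)),
            )
        )
    if skipped:
        logger.info("estimate_shift: skipped %d genes missing a call", skipped)
    groups = None
    if group_by is not None and estimates:
        df = pd.DataFrame(
            {"delta": [e.delta for e in estimates]},
            index=[e.gene_id for e in estimates],
        )
        df["group"] = group_by.reindex(df.index)
        groups = df.groupby("group")["delta"].agg(["mean", "std", "count"])
    return estimates, groups


def tss_burial(dyad: int, tss: int, orientation: str, half_width: int = NUC_HALF_WIDTH) -> int:
    """Signed distance of the TSS from the nucleosome's upstream edge.

    Positive = TSS inside the nucleosome, measured from the upstream
    (5', gene orientation) edge at dyad - 73; negative = TSS outside.
    """
    d = dyad - tss if orientation == "+" else tss - dyad
    return int(half_width - d)
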