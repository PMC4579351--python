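"""Tag and fragment I/O, 3' shifting, and per-base pileups.

The universal currency of the pipeline is the :class:`TagDataset`: the
5' end coordinates of sequence tags on each strand, i.e. exonuclease
stop sites.  Stop sites sit a few bp 5' of the protein-DNA cross-link
on each strand, so downstream analyses either keep the two strands
separate (peak pairing) or shift every tag 3' by the exonuclease
headroom and collapse strands (occupancy, composites).

Coordinates are 0-based and intervals half-open throughout; BED is the
native on-disk format.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TagDataset",
    "Pileup",
    "BedParseError",
    "shift_tags",
    "pileup",
    "read_bed",
    "write_bed",
    "read_fragments_bed",
    "write_fragments_bed",
    "write_bedgraph",
]


class BedParseError(ValueError):
    """Malformed BED input; message carries the 1-based line number."""


@dataclass
class TagDataset:
    """Strand-specific tag 5'-end coordinates for one factor/condition.

    Parameters
    ----------
    factor, condition
        Labels carried through to outputs.
    chroms
        Chromosome name per tag (object dtype).
    pos
        0-based 5'-end coordinate per tag.
    fwd
        True for forward-strand tags.
    shifted
        Whether the 3' headroom shift has been applied.  Guarded so it
        can be applied exactly once.
    weight
        Scalar per-tag weight, set by cross-condition background
        normalization; raw simulated/parsed data has weight 1.
    """

    factor: str
    condition: str
    chroms: np.ndarray
    pos: np.ndarray
    fwd: np.ndarray
    shifted: bool = False
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.fwd = np.asarray(self.fwd, dtype=bool)
        if not (len(self.chroms) == len(self.pos) == len(self.fwd)):
            raise ValueError("chroms, pos and fwd must have equal length")
        if len(self.pos) and self.pos.min() < 0:
            raise ValueError("tag coordinates must be >= 0")

    def __len__(self) -> int:
        return len(self.pos)

    def subset(self, mask: np.ndarray) -> "TagDataset":
        return dataclasses.replace(
            self, chroms=self.chroms[mask], pos=self.pos[mask], fwd=self.fwd[mask]
        )

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, int, str]],
        factor: str = "",
        condition: str = "",
        shifted: bool = False,
    ) -> "TagDataset":
        """Build from (chrom, coordinate, strand) tuples."""
        if records:
            chroms, pos, strands = zip(*records)
        else:
            chroms, pos, strands = (), (), ()
        return cls(
            factor=factor,
            condition=condition,
            chroms=np.array(chroms, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            fwd=np.array([s == "+" for s in strands], dtype=bool),
            shifted=shifted,
        )

    def records(self) -> list[tuple[str, int, str]]:
        return [
            (c, int(p), "+" if f else "-")
            for c, p, f in zip(self.chroms, self.pos, self.fwd)
        ]


@dataclass
class Pileup:
    """Per-base tag 5'-end counts over a window, per strand and collapsed."""

    chrom: str
    start: int
    end: int
    counts_fwd: np.ndarray
    counts_rev: np.ndarray
    counts_all: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts_all = self.counts_fwd + self.counts_rev

    @property
    def total(self) -> int:
        return int(self.counts_all.sum())


def shift_tags(tags: TagDataset, shift: int = 6) -> TagDataset:
    """Shift every tag 3' by ``shift`` bp (strand-aware).

    Forward tags move to ``p + shift``, reverse tags to ``p - shift``,
    so that stop sites flanking one cross-link converge on it.  Tags
    shifted below 0 are dropped (counted and logged).  The result is
    flagged shifted; shifting twice is a state error.
    """
    if tags.shifted:
        raise ValueError("tags are already shifted; refusing to shift twice")
    new_pos = np.where(tags.fwd, tags.pos + shift, tags.pos - shift)
    keep = new_pos >= 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "shift_tags: dropped %d/%d tags shifted below coordinate 0",
            n_dropped,
            len(tags),
        )
    return dataclasses.replace(
        tags,
        chroms=tags.chroms[keep],
        pos=new_pos[keep],
        fwd=tags.fwd[keep],
        shifted=True,
    )


def unshift_tags(tags: TagDataset, shift: int = 6) -> TagDataset:
    """Inverse of :func:`shift_tags` (for round-trip checks)."""
    if not tags.shifted:
        raise ValueError("tags are not shifted")
    new_pos = np.where(tags.fwd, tags.pos - shift, tags.pos + shift)
    return dataclasses.replace(tags, pos=new_pos, shifted=False)


def pileup(tags: TagDataset, chrom: str, start: int, end: int) -> Pileup:
    """Count tag 5' ends per base per strand inside [start, end)."""
    if end <= start:
        raise ValueError(f"empty window [{start}, {end})")
    n = end - start
    counts = []
    for want_fwd in (True, False):
        mask = (
            (tags.chroms == chrom)
            & (tags.fwd == want_fwd)
            & (tags.pos >= start)
            & (tags.pos < end)
        )
        counts.append(
            np.bincount(tags.pos[mask] - start, minlength=n).astype(np.int64)
        )
    return Pileup(
        chrom=chrom, start=start, end=end, counts_fwd=counts[0], counts_rev=counts[1]
    )


# ---------------------------------------------------------------------------
# BED I/O.  Tags are single-bp BED6 intervals; the score column carries
# multiplicity so identical stop sites collapse to one line on disk.
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, factor: str = "", condition: str = "") -> TagDataset:
    """Read single-bp BED6 tag records, expanding score as multiplicity."""
    chroms: list[str] = []
    pos: list[int] = []
    fwd: list[bool] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                mult = int(float(fields[4]))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            strand = fields[5]
            if start < 0:
                raise BedParseError(f"{path}:{lineno}: negative coordinate {start}")
            if end != start + 1:
                raise BedParseError(f"{path}:{lineno}: tag interval must be 1 bp")
            if strand not in "+-":
                raise BedParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if mult < 1:
                raise BedParseError(f"{path}:{lineno}: multiplicity {mult} < 1")
            chroms.extend([fields[0]] * mult)
            pos.extend([start] * mult)
            fwd.extend([strand == "+"] * mult)
    return TagDataset(
        factor=factor,
        condition=condition,
        chroms=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        fwd=np.array(fwd, dtype=bool),
    )


def write_bed(tags: TagDataset, path: str | Path) -> int:
    """Write tags as single-bp BED6, score = multiplicity. Returns line count."""
    # collapse identical (chrom, pos, strand) records
    seen: dict[tuple[str, int, bool], int] = {}
    for c, p, f in zip(tags.chroms, tags.pos, tags.fwd):
        key = (c, int(p), bool(f))
        seen[key] = seen.get(key, 0) + 1
    name = tags.factor or "tag"
    n = 0
    with open(path, "w") as fh:
        for (c, p, f), mult in sorted(seen.items()):
            fh.write(f"{c}\t{p}\t{p + 1}\t{name}\t{mult}\t{'+' if f else '-'}\n")
            n += 1
    return n


def read_fragments_bed(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read fragment intervals (BED, >=3 columns) as (chroms, starts, ends)."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if s < 0 or e <= s:
                raise BedParseError(f"{path}:{lineno}: bad interval [{s}, {e})")
            chroms.append(fields[0])
            starts.append(s)
            ends.append(e)
    return (
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )


def write_fragments_bed(
    chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for c, s, e in zip(chroms, starts, ends):
            fh.write(f"{c}\t{int(s)}\t{int(e)}\tfrag\t0\t+\n")


def write_bedgraph(
    values: np.ndarray, chrom: str, start: int, path: str | Path
) -> None:
    """Export a per-base track as bedGraph, merging equal-valued runs."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                v = values[run_start]
                if v != 0:
                    fh.write(
                        f"{chrom}\t{start + run_start}\t{start + i}\t{v:g}\n"
                    )
                run_start = i
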