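"""Synthetic genome, promoter architectures, ChIP-exo tags, and MNase
fragments with the statistical structure the analysis assumes.

Each promoter carries 0-2 upstream activator (Rap1) sites, a coactivator
(Fhl1) core ~100 bp downstream of the most upstream site, an optional
G+C-elevated zone of broad HMG-box (Hmo1) binding, a preinitiation
complex at the core promoter, and positioned nucleosomes.  Three
conditions are modeled (normal, heat shock, hmo1-null) and every emitted
dataset retains its ground-truth architecture so recovery tests can
compare estimates to truth.

ChIP-exo stop-site model: the exonuclease stops a fixed "headroom" 5' of
each cross-link point on both strands, so a cross-link at x emits
forward-strand 5' ends near x - headroom and reverse-strand 5' ends near
x + headroom.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from exoarch.motifscan import IUPAC, reverse_complement
from exoarch.tagio import TagDataset

__all__ = [
    "PromoterArchitecture",
    "ExoModel",
    "ConditionSpec",
    "condition",
    "build_genome",
    "simulate_chipexo",
    "simulate_mnase",
    "crosslink_points_for",
    "plus1_dyad",
    "nucleosome_dyads",
    "paralog_pair_count",
    "write_fasta",
    "annotation_table",
    "save_truth",
    "load_truth",
    "RAP1_CONSENSUS",
    "FHL1_CONSENSUS",
    "IFHL_CONSENSUS",
    "FACTORS",
    "TAF_OFFSETS",
]

RAP1_CONSENSUS = "ACACCCATACAT"  # synthetic stand-in; 12 bp
FHL1_CONSENSUS = "YKYGCGTC"
IFHL_CONSENSUS = "GGCNG"

CHROM = "chrS"

# oriented crosslink offsets of general factors relative to the TSS;
# the two printed extremes span the TFIID/TFIIA footprint
TAF_OFFSETS: dict[str, int] = {
    "Taf1": -12,
    "Taf2": 33,
    "Taf4": -28,
    "Taf5": -8,
    "Taf8": -18,
    "Taf10": -42,
    "Taf12": -33,
}

FIS_SCALE = {"Fhl1": 1.0, "Ifh1": 0.5, "Sfp1": 0.25}
HISTONES = ("H2A", "H2B", "H3", "H4")
PIC_SHIFT_FACTORS = {"Sua7", "Rpb3"}

FACTORS = (
    "Rap1", "Fhl1", "Ifh1", "Sfp1", "Hmo1",
    "Sua7", "Toa2", "Rpb3", "H4",
    *sorted(TAF_OFFSETS),
)

#: default none/narrow/broad proportions (58/30/30 over 118 classified genes)
CLASS_PROPORTIONS = (58 / 118, 30 / 118, 30 / 118)

# oriented promoter geometry (bp relative to TSS, upstream negative)
UPSTREAM_RAP1_OFFSET = -280
FHL1_DOWNSTREAM_OF_RAP1 = 100
HMO1_ZONE_START_AFTER_RAP1 = 90
PIC_OFFSET = -20
PLUS1_ACTIVE_DYAD_OFFSET = 58  # TSS 15 bp inside the 147-bp core's edge
REPRESSED_SHIFT = 20  # upstream dyad shift in hmo1-null geometry
NUC_SPACING = 165


class FactorLookupError(KeyError):
    pass


class LayoutError(ValueError):
    pass


@dataclass
class PromoterArchitecture:
    """Ground-truth layout of one synthetic promoter (genomic coords)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    rap1_sites: list[tuple[int, str]]
    rap1_spacing: int | None
    fhl1_core_center: int | None
    hmo1_class: str  # none | narrow | broad
    hmo1_breadth: int
    hmo1_zone: tuple[int, int] | None
    pic_center: int
    plus1_dyad_active: int
    plus1_dyad_repressed: int
    paralog_id: str | None = None

    def pos_at(self, offset: int) -> int:
        """Genomic coordinate of an oriented offset (upstream negative)."""
        return self.tss + offset if self.strand == "+" else self.tss - offset

    def offset_of(self, pos: int | float) -> float:
        """Oriented offset of a genomic coordinate."""
        return pos - self.tss if self.strand == "+" else self.tss - pos

    def upstream_rap1(self) -> int | None:
        """Genomic midpoint of the most upstream (5'-most oriented) site."""
        if not self.rap1_sites:
            return None
        return min((m for m, _ in self.rap1_sites), key=self.offset_of)


@dataclass
class ExoModel:
    """Exonuclease stop-site emission model.

    ``depth`` is the expected tag count per unit-efficiency cross-link
    point.  ``crosslink_points``, when given, overrides the per-factor
    point sets derived from the architecture (maps factor name to a list
    of (genomic coordinate, relative efficiency) pairs).
    """

    headroom: int = 6
    stop_jitter_sd: float = 1.0
    depth: float = 50.0
    background_rate: float = 0.01
    piggyback_fraction: dict[str, float] = field(
        default_factory=lambda: {"Fhl1": 0.10, "Ifh1": 0.15, "Sfp1": 0.30}
    )
    crosslink_points: dict[str, list[tuple[int, float]]] | None = None

    def __post_init__(self) -> None:
        if self.headroom < 0:
            raise ValueError("headroom must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for f, v in self.piggyback_fraction.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"piggyback fraction for {f} outside [0, 1]")


@dataclass
class ConditionSpec:
    """One experimental condition: retentions, geometry, ectopic PIC."""

    name: str
    factor_retention: dict[str, float] = field(default_factory=dict)
    fhl1_breadth_override: int | None = None
    pic_ectopic_fraction: float = 0.0
    dyad_choice: str = "active"

    def __post_init__(self) -> None:
        for f, v in self.factor_retention.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"retention for {f} outside [0, 1]")
        if not 0.0 <= self.pic_ectopic_fraction <= 1.0:
            raise ValueError("pic_ectopic_fraction outside [0, 1]")

    def retention(self, factor: str) -> float:
        return self.factor_retention.get(factor, 1.0)


def condition(name: str) -> ConditionSpec:
    """Default specs for the three modeled conditions."""
    if name == "normal":
        return ConditionSpec(name="normal")
    if name == "heat_shock":
        # all but Rap1/Fhl1 largely dissociate; ~70% of Hmo1 lost
        retention = {"Hmo1": 0.3, "Ifh1": 0.15, "Sfp1": 0.15,
                     "Sua7": 0.3, "Toa2": 0.3, "Rpb3": 0.25}
        retention.update({taf: 0.3 for taf in TAF_OFFSETS})
        return ConditionSpec(
            name="heat_shock", factor_retention=retention, dyad_choice="repressed"
        )
    if name == "hmo1_null":
        return ConditionSpec(
            name="hmo1_null",
            factor_retention={"Hmo1": 0.0},
            fhl1_breadth_override=80,
            pic_ectopic_fraction=0.23,
            dyad_choice="repressed",
        )
    raise ValueError(f"unknown condition {name!r}")


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, p=(0.31, 0.19, 0.19, 0.31)) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=p)


def _expand_iupac(rng: np.random.Generator, consensus: str) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in consensus.upper())


def _plant(seq: np.ndarray, arch: PromoterArchitecture, oriented_start: int, motif: str) -> None:
    """Write an oriented motif into the genome at an oriented offset."""
    w = len(motif)
    if arch.strand == "+":
        g = arch.tss + oriented_start
        seq[g : g + w] = list(motif)
    else:
        g = arch.tss - oriented_start - (w - 1)
        seq[g : g + w] = list(reverse_complement(motif))


def build_genome(
    n_genes: int,
    class_proportions: tuple[float, float, float] = CLASS_PROPORTIONS,
    seed: int = 0,
    *,
    spacing: int = 2500,
    margin: int = 1000,
    frac_minus: float = 0.35,
    rap1_site_counts: list[int] | None = None,
    classes: list[str] | None = None,
    n_singles: int | None = None,
) -> tuple[dict[str, str], list[PromoterArchitecture]]:
    """Generate a single synthetic chromosome plus ground-truth layouts.

    Promoters sit >= ``spacing`` bp apart on one chromosome; roughly
    ``frac_minus`` of genes are on the reverse strand.  Classes are a
    multinomial draw from ``class_proportions`` (none, narrow, broad).
    ``rap1_site_counts`` optionally fixes the per-gene number of bound
    sites (0-2); genes forced to 0 sites carry no downstream apparatus
    and are classed "none".
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    props = np.asarray(class_proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("class proportions must sum to 1")
    if spacing < 1800:
        raise LayoutError("promoter spacing too small for the layout")
    if rap1_site_counts is not None and len(rap1_site_counts) != n_genes:
        raise ValueError("rap1_site_counts must have one entry per gene")

    rng = np.random.default_rng(seed)
    length = 2 * margin + n_genes * spacing
    seq = _random_seq(rng, length)

    if classes is not None:
        if len(classes) != n_genes or not set(classes) <= {"none", "narrow", "broad"}:
            raise ValueError("classes must name none/narrow/broad per gene")
        classes = np.asarray(classes, dtype=object)
    else:
        classes = rng.choice(["none", "narrow", "broad"], size=n_genes, p=props)
    strands = np.where(rng.random(n_genes) < frac_minus, "-", "+")
    if n_singles is None:
        n_singles = n_genes % 2

    arches: list[PromoterArchitecture] = []
    n_paired = n_genes - n_singles
    for i in range(n_genes):
        gene_id = f"gene{i:04d}"
        strand = str(strands[i])
        cls = str(classes[i])
        slot_center = margin + i * spacing + spacing // 2
        tss = slot_center

        if rap1_site_counts is not None:
            n_sites = int(rap1_site_counts[i])
        else:
            n_sites = 2 if cls != "none" else int(rng.integers(1, 3))
        if n_sites == 0:
            cls = "none"

        def pos_at(off: int) -> int:
            return tss + off if strand == "+" else tss - off

        arch = PromoterArchitecture(
            gene_id=gene_id,
            chrom=CHROM,
            tss=tss,
            strand=strand,
            rap1_sites=[],
            rap1_spacing=None,
            fhl1_core_center=None,
            hmo1_class=cls,
            hmo1_breadth=0,
            hmo1_zone=None,
            pic_center=pos_at(PIC_OFFSET),
            plus1_dyad_active=pos_at(PLUS1_ACTIVE_DYAD_OFFSET),
            plus1_dyad_repressed=pos_at(PLUS1_ACTIVE_DYAD_OFFSET - REPRESSED_SHIFT),
            paralog_id=None,
        )
        if i < n_paired:
            partner = i + 1 if i % 2 == 0 else i - 1
            if partner < n_paired:
                arch.paralog_id = f"gene{partner:04d}"

        if n_sites >= 1:
            w = len(RAP1_CONSENSUS)
            up_off = UPSTREAM_RAP1_OFFSET + int(rng.integers(-15, 16))
            site_offsets = [up_off]
            if n_sites == 2:
                gap = int(rng.integers(5, 16))
                arch.rap1_spacing = gap
                site_offsets.append(up_off + w + gap)
            for s_off in site_offsets:
                start = s_off - w // 2
                _plant(seq, arch, start, RAP1_CONSENSUS)
                arch.rap1_sites.append((arch.pos_at(s_off), strand))

            # poly(dA:dT) tract between the site and the core
            tract_len = int(rng.integers(6, 10))
            _plant(seq, arch, up_off + 40, "A" * tract_len)

            if cls != "none":
                lo, hi = (100, 121) if cls == "narrow" else (150, 171)
                breadth = int(rng.integers(lo, hi))
                z0 = up_off + HMO1_ZONE_START_AFTER_RAP1
                arch.hmo1_breadth = breadth
                g0, g1 = arch.pos_at(z0), arch.pos_at(z0 + breadth)
                arch.hmo1_zone = (min(g0, g1), max(g0, g1))
                # G+C-elevated zone sequence mirroring the binding breadth
                zone_seq = rng.choice(_BASES, size=breadth, p=(0.2, 0.3, 0.3, 0.2))
                _plant(seq, arch, z0, "".join(zone_seq))
                # degenerate GC sites tiled through the zone, clear of the
                # coactivator motif planted below
                for m_off in range(z0 + 20, z0 + breadth - 5, 20):
                    _plant(seq, arch, m_off, _expand_iupac(rng, IFHL_CONSENSUS))

            # coactivator core ~100 bp downstream of the upstream site;
            # planted after the zone so the instance survives verbatim
            core_off = up_off + FHL1_DOWNSTREAM_OF_RAP1
            arch.fhl1_core_center = arch.pos_at(core_off)
            fhl1_instance = _expand_iupac(rng, FHL1_CONSENSUS)
            _plant(seq, arch, core_off - len(fhl1_instance) // 2, fhl1_instance)
        if arch.tss - spacing // 2 < 0 or arch.tss + spacing // 2 > length:
            raise LayoutError(f"{gene_id}: promoter outside chromosome bounds")
        arches.append(arch)

    return {CHROM: "".join(seq)}, arches


# ---------------------------------------------------------------------------
# cross-link point sets
# ---------------------------------------------------------------------------


def crosslink_points_for(
    arch: PromoterArchitecture, factor: str, cond: ConditionSpec
) -> list[tuple[int, float]]:
    """Deterministic (genomic coordinate, relative efficiency) points."""
    out: list[tuple[int, float]] = []

    def add(off: float, eff: float) -> None:
        out.append((arch.pos_at(int(round(off))), eff))

    rap1_offs = sorted(arch.offset_of(m) for m, _ in arch.rap1_sites)

    if factor == "Rap1":
        for off in rap1_offs:
            add(off, 1.0)
    elif factor in FIS_SCALE:
        if arch.fhl1_core_center is None:
            return []
        scale = FIS_SCALE[factor]
        core = arch.offset_of(arch.fhl1_core_center)
        add(core, 1.0 * scale)
        add(core - 35, 0.5 * scale)
        add(core + 35, 0.5 * scale)
        broadened = (
            arch.hmo1_class != "none"
            and cond.fhl1_breadth_override is None
            and cond.retention("Hmo1") > 0
        )
        if broadened:
            # extension tracking the Hmo1 zone, stopping 25 bp short
            z0 = min(rap1_offs) + HMO1_ZONE_START_AFTER_RAP1
            end = z0 + arch.hmo1_breadth - 25
            off = core + 55
            while off <= end:
                add(off, 0.35 * scale)
                off += 20
    elif factor == "Hmo1":
        if arch.hmo1_class == "none" or arch.hmo1_zone is None:
            return []
        # two molecules per ~26 bp unit -> points tiled every 13 bp
        z0 = min(rap1_offs) + HMO1_ZONE_START_AFTER_RAP1
        for off in range(z0, z0 + arch.hmo1_breadth + 1, 13):
            add(off, 1.0)
    elif factor in ("Sua7", "Toa2"):
        add(arch.offset_of(arch.pic_center), 1.0)
    elif factor == "Rpb3":
        add(10, 1.0)
        add(150, 0.4)
    elif factor in HISTONES:
        for dyad in nucleosome_dyads(arch, cond):
            d_off = arch.offset_of(dyad)
            for rel, eff in ((-50, 0.5), (-25, 0.8), (0, 1.0), (25, 0.8), (50, 0.5)):
                add(d_off + rel, eff)
    elif factor in TAF_OFFSETS:
        add(TAF_OFFSETS[factor], 1.0)
    else:
        raise FactorLookupError(factor)

    # hmo1-null: the primary PIC shifts ~15 bp upstream at Hmo1 genes
    if (
        cond.name == "hmo1_null"
        and factor in PIC_SHIFT_FACTORS
        and arch.hmo1_class != "none"
    ):
        out = [(arch.pos_at(int(round(arch.offset_of(p) - 15))), e) for p, e in out]
    return out


def plus1_dyad(arch: PromoterArchitecture, cond: ConditionSpec) -> int:
    """Condition-dependent +1 nucleosome dyad (genomic)."""
    if cond.dyad_choice == "active":
        return arch.plus1_dyad_active
    if cond.name == "hmo1_null":
        # geometry changes only where the HMG-box factor was bound
        if arch.hmo1_class == "none":
            return arch.plus1_dyad_active
        return arch.plus1_dyad_repressed
    if cond.name == "heat_shock":
        if arch.hmo1_class == "none":
            return arch.plus1_dyad_repressed
        # further upstream by the zone's extension beyond the core
        ext = int(np.clip(arch.hmo1_breadth - 90, 20, 50))
        off = arch.offset_of(arch.plus1_dyad_repressed) - ext
        return arch.pos_at(int(off))
    return arch.plus1_dyad_repressed


def nucleosome_dyads(arch: PromoterArchitecture, cond: ConditionSpec) -> list[int]:
    """All modeled dyads: +1 (condition-dependent), +2, +3, upstream."""
    p1 = plus1_dyad(arch, cond)
    p1_off = arch.offset_of(p1)
    dyads = [p1, arch.pos_at(int(p1_off + NUC_SPACING)), arch.pos_at(int(p1_off + 2 * NUC_SPACING))]
    up = arch.upstream_rap1()
    anchor = arch.offset_of(up) if up is not None else -350.0
    dyads.append(arch.pos_at(int(anchor - 120)))
    dyads.append(arch.pos_at(int(anchor - 120 - NUC_SPACING)))
    return dyads


# ---------------------------------------------------------------------------
# ChIP-exo simulation
# ---------------------------------------------------------------------------


def _emit_stop_sites(
    rng: np.random.Generator,
    x: int,
    n: int,
    headroom: int,
    jitter_sd: float,
    pos: list[int],
    fwd: list[bool],
) -> None:
    if n <= 0:
        return
    strands = rng.integers(0, 2, size=n).astype(bool)
    if jitter_sd > 0:
        eps = np.rint(rng.normal(0.0, jitter_sd, size=n)).astype(int)
    else:
        eps = np.zeros(n, dtype=int)
    p = np.where(strands, x - headroom, x + headroom) + eps
    pos.extend(int(v) for v in p)
    fwd.extend(bool(s) for s in strands)


def simulate_chipexo(
    arches: list[PromoterArchitecture],
    exo: ExoModel,
    cond: ConditionSpec,
    factor: str,
    seed: int = 0,
    *,
    background_span: tuple[int, int] = (-600, 400),
) -> TagDataset:
    """Simulate unshifted stop-site tags for one factor and condition.

    Per cross-link point of efficiency e, the tag count is
    Poisson(depth * e * retention); each tag lands on a random strand at
    the point minus/plus the headroom with discretized Gaussian jitter.
    Background tags fall uniformly over each promoter's span.  A
    configured fraction of coactivator tags is emitted at the activator
    point set (piggybacking); under the hmo1-null condition a fraction of
    PIC tags is drawn uniformly from the ectopic upstream window
    (TSS-200 to TSS-70) at genes that normally carry the HMG-box factor.
    """
    rng = np.random.default_rng(seed)
    retention = cond.retention(factor)
    pos: list[int] = []
    fwd: list[bool] = []
    chrom_per_gene: list[tuple[str, int]] = []

    for arch in arches:
        n_before = len(pos)
        if exo.crosslink_points is not None:
            if factor not in exo.crosslink_points:
                raise FactorLookupError(factor)
            points = exo.crosslink_points[factor]
        else:
            points = crosslink_points_for(arch, factor, cond)

        ectopic = (
            cond.pic_ectopic_fraction
            if (
                cond.name == "hmo1_null"
                and factor in PIC_SHIFT_FACTORS
                and arch.hmo1_class != "none"
            )
            else 0.0
        )

        for x, eff in points:
            n = int(rng.poisson(exo.depth * eff * retention))
            if ectopic > 0.0 and n > 0:
                n_ect = int(rng.binomial(n, ectopic))
                n -= n_ect
                offs = rng.integers(-200, -70, size=n_ect)
                for off in offs:
                    _emit_stop_sites(
                        rng, arch.pos_at(int(off)), 1, exo.headroom,
                        exo.stop_jitter_sd, pos, fwd,
                    )
            _emit_stop_sites(rng, x, n, exo.headroom, exo.stop_jitter_sd, pos, fwd)

        pig = exo.piggyback_fraction.get(factor, 0.0)
        if pig > 0.0:
            for x, eff in crosslink_points_for(arch, "Rap1", cond):
                n = int(rng.poisson(exo.depth * pig * eff * retention))
                _emit_stop_sites(rng, x, n, exo.headroom, exo.stop_jitter_sd, pos, fwd)

        if exo.background_rate > 0.0:
            lo = arch.pos_at(background_span[0])
            hi = arch.pos_at(background_span[1])
            lo, hi = min(lo, hi), max(lo, hi)
            n_bg = int(rng.poisson(exo.background_rate * (hi - lo)))
            bg_pos = rng.integers(lo, hi, size=n_bg)
            bg_fwd = rng.integers(0, 2, size=n_bg).astype(bool)
            pos.extend(int(v) for v in bg_pos)
            fwd.extend(bool(s) for s in bg_fwd)
        chrom_per_gene.append((arch.chrom, len(pos) - n_before))

    chroms = np.concatenate(
        [np.full(k, c, dtype=object) for c, k in chrom_per_gene]
    ) if chrom_per_gene else np.array([], dtype=object)
    pos_arr = np.array(pos, dtype=np.int64)
    fwd_arr = np.array(fwd, dtype=bool)
    keep = pos_arr >= 0
    return TagDataset(
        factor=factor,
        condition=cond.name,
        chroms=chroms[keep],
        pos=pos_arr[keep],
        fwd=fwd_arr[keep],
        shifted=False,
    )


# ---------------------------------------------------------------------------
# MNase simulation
# ---------------------------------------------------------------------------


def simulate_mnase(
    arches: list[PromoterArchitecture],
    cond: ConditionSpec,
    protect_nonhistone: bool = False,
    seed: int = 0,
    *,
    frags_per_nuc: float = 50.0,
    frag_len_mean: float = 147.0,
    frag_len_sd: float = 8.0,
    dyad_jitter_sd: float = 5.0,
    background_rate: float = 0.005,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Emit nucleosome-sized fragment intervals as (chroms, starts, ends).

    Fragments are ~147 bp, centered on dyads with Gaussian jitter.  With
    ``protect_nonhistone`` (plain MNase, no histone ChIP), additional
    nucleosome-sized fragments cover the coactivator/HMG-box zone -
    MNase resistance without ChIP is not proof of a nucleosome.  Without
    it (histone-ChIP mode), only dyad-centered fragments are emitted.
    """
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []

    def emit(center: int, k: int) -> None:
        if k <= 0:
            return
        c = center + np.rint(rng.normal(0, dyad_jitter_sd, size=k)).astype(int)
        ln = np.clip(np.rint(rng.normal(frag_len_mean, frag_len_sd, size=k)), 80, 250).astype(int)
        s = c - (ln - 1) // 2
        for si, li in zip(s, ln):
            if si >= 0:
                starts.append(int(si))
                ends.append(int(si + li))

    for arch in arches:
        n0 = len(starts)
        for dyad in nucleosome_dyads(arch, cond):
            emit(dyad, int(rng.poisson(frags_per_nuc)))
        if protect_nonhistone:
            if arch.hmo1_zone is not None:
                z_lo, z_hi = arch.hmo1_zone
            elif arch.fhl1_core_center is not None:
                z_lo, z_hi = arch.fhl1_core_center - 40, arch.fhl1_core_center + 40
            else:
                z_lo = z_hi = 0
            if z_hi > z_lo:
                k = int(rng.poisson(frags_per_nuc * (z_hi - z_lo) / frag_len_mean))
                centers = rng.integers(z_lo, z_hi, size=k)
                for c in centers:
                    emit(int(c), 1)
        if background_rate > 0.0:
            lo, hi = sorted((arch.pos_at(-700), arch.pos_at(500)))
            k = int(rng.poisson(background_rate * (hi - lo)))
            for c in rng.integers(lo, hi, size=k):
                emit(int(c), 1)
        chroms.extend([arch.chrom] * (len(starts) - n0))

    return (
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# cohort arithmetic and I/O
# ---------------------------------------------------------------------------


def paralog_pair_count(n_total: int, n_single: int) -> int:
    """Number of gene pairs when all non-single genes occur in pairs."""
    if n_single > n_total or (n_total - n_single) % 2:
        raise ValueError("non-single genes must be evenly pairable")
    return (n_total - n_single) // 2


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def annotation_table(arches: list[PromoterArchitecture]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in arches],
            "chrom": [a.chrom for a in arches],
            "tss": [a.tss for a in arches],
            "strand": [a.strand for a in arches],
            "hmo1_class": [a.hmo1_class for a in arches],
            "paralog_id": [a.paralog_id or "." for a in arches],
        }
    )


def save_truth(arches: list[PromoterArchitecture], path: str | Path) -> None:
    payload = []
    for a in arches:
        d = dataclasses.asdict(a)
        d["rap1_sites"] = [[int(m), s] for m, s in a.rap1_sites]
        d["hmo1_zone"] = list(a.hmo1_zone) if a.hmo1_zone else None
        payload.append(d)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_truth(path: str | Path) -> list[PromoterArchitecture]:
    with open(path) as fh:
        payload = json.load(fh)
    arches = []
    for d in payload:
        d["rap1_sites"] = [(int(m), s) for m, s in d["rap1_sites"]]
        d["hmo1_zone"] = tuple(d["hmo1_zone"]) if d["hmo1_zone"] else None
        arches.append(PromoterArchitecture(**d))
    return arches
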