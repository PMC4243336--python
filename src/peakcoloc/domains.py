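"""TSS-relative domain construction and region-to-gene association.

Genes are anchored at a single TSS coordinate with a strand.  Window
specifications are TSS-relative and strand-aware: negative offsets are
upstream.  Region-to-gene association follows the basal-plus-extension rule:
each gene owns a basal window (default 5 kb upstream / 1 kb downstream of the
TSS) extended on each side up to 1,000 kb or to the adjacent gene's basal
boundary, whichever is nearer, never shrinking below its own basal window.
A region associates with every gene whose regulatory interval contains the
region midpoint; the association is proximal when the midpoint lies in the
basal window, distal otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .intervals import (
    BedParseError,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
)
from .proximity import DomainSet

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000

DISTANCE_BINS_KB = ((0, 5), (5, 50), (50, 500), (500, None))


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


class GeneAnnotation:
    """Unique-id gene records with TSS positions, bounded by a layout."""

    def __init__(self, genes: Iterable[Gene], layout: GenomeLayout):
        self.layout = layout
        self.genes: list[Gene] = []
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            if g.chrom not in layout:
                raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom!r} not in layout")
            if g.tss >= layout.length_of(g.chrom):
                raise ValueError(f"gene {g.gene_id}: TSS beyond chromosome end")
            seen.add(g.gene_id)
            self.genes.append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_chromosome(self) -> dict[str, list[Gene]]:
        """Genes grouped per chromosome, sorted by (tss, gene_id)."""
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for chrom in out:
            out[chrom].sort(key=lambda g: (g.tss, g.gene_id))
        return out

    @classmethod
    def read_tss_table(cls, path, layout: GenomeLayout) -> "GeneAnnotation":
        """Read the native 4-column table: gene id, chrom, strand, tss."""
        genes: list[Gene] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise BedParseError("expected 4 tab-separated columns", lineno)
                try:
                    tss = int(parts[3])
                except ValueError as exc:
                    raise BedParseError(f"non-integer TSS {parts[3]!r}", lineno) from exc
                genes.append(Gene(parts[0], parts[1], parts[2], tss))
        return cls(genes, layout)

    @classmethod
    def from_bed6(cls, s: IntervalSet) -> "GeneAnnotation":
        """Convert BED6 gene records: TSS = start for + strand, end - 1 for -."""
        genes = []
        for iv in s:
            if iv.strand not in ("+", "-"):
                raise ValueError(f"gene record {iv.name!r} lacks a +/- strand")
            tss = iv.start if iv.strand == "+" else iv.end - 1
            genes.append(Gene(iv.name or f"{iv.chrom}:{iv.start}", iv.chrom, iv.strand, tss))
        return cls(genes, s.layout)

    def write_tss_table(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


@dataclass(frozen=True)
class WindowSpec:
    """TSS-relative, strand-aware half-open windows; negative = upstream."""

    windows: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.windows:
            raise ValueError("WindowSpec requires at least one window")
        for rel_start, rel_end in self.windows:
            if rel_start >= rel_end:
                raise ValueError(f"window ({rel_start}, {rel_end}) is empty")

    @classmethod
    def single(cls, rel_start: int, rel_end: int) -> "WindowSpec":
        return cls(((rel_start, rel_end),))


def build_tss_domain(
    genes: GeneAnnotation,
    spec: WindowSpec,
    layout: GenomeLayout,
    name: str = "tss_windows",
) -> DomainSet:
    """Merged domain of strand-aware TSS windows over all genes.

    For a + strand gene the window (a, b) maps to [tss + a, tss + b); for a
    - strand gene to [tss - b, tss - a).  Windows are clamped to chromosome
    bounds; windows entirely off-chromosome are dropped with a warning.
    """
    out: list[GenomicInterval] = []
    n_dropped = 0
    for g in genes:
        clen = layout.length_of(g.chrom)
        for rel_start, rel_end in spec.windows:
            if g.strand == "+":
                a, b = g.tss + rel_start, g.tss + rel_end
            else:
                a, b = g.tss - rel_end, g.tss - rel_start
            a = max(0, a)
            b = min(clen, b)
            if a >= b:
                n_dropped += 1
                continue
            out.append(GenomicInterval(g.chrom, a, b))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} TSS window(s) entirely off-chromosome")
    if not out:
        raise ValueError("no TSS window survived clamping")
    return DomainSet(IntervalSet(out, layout), name=name)


@dataclass(frozen=True)
class RegulatoryDomain:
    """One gene's basal window and extended regulatory interval."""

    gene: Gene
    basal_start: int
    basal_end: int
    start: int
    end: int


def _basal(g: Gene, basal_up: int, basal_down: int, clen: int) -> tuple[int, int]:
    if g.strand == "+":
        a, b = g.tss - basal_up, g.tss + basal_down
    else:
        a, b = g.tss - basal_down, g.tss + basal_up
    return max(0, a), min(clen, b)


def great_domains(
    genes: GeneAnnotation,
    layout: GenomeLayout,
    basal_up: int = BASAL_UPSTREAM,
    basal_down: int = BASAL_DOWNSTREAM,
    max_ext: int = MAX_EXTENSION,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory interval per gene.

    Extensions run to the nearer of (max_ext from the gene's TSS) and the
    adjacent gene's basal boundary, and never shrink below the gene's own
    basal window.  TSS ties are broken by gene id (the sort order).
    """
    out: list[RegulatoryDomain] = []
    for chrom, chrom_genes in genes.by_chromosome().items():
        clen = layout.length_of(chrom)
        basals = [_basal(g, basal_up, basal_down, clen) for g in chrom_genes]
        for i, g in enumerate(chrom_genes):
            b_start, b_end = basals[i]
            left_limit = max(0, g.tss - max_ext)
            if i > 0:
                left_limit = max(left_limit, basals[i - 1][1])
            right_limit = min(clen, g.tss + max_ext)
            if i + 1 < len(chrom_genes):
                right_limit = min(right_limit, basals[i + 1][0])
            start = min(b_start, left_limit)
            end = max(b_end, right_limit)
            out.append(RegulatoryDomain(g, b_start, b_end, start, end))
    return out


@dataclass
class Association:
    region: GenomicInterval
    gene_id: str
    signed_distance: int  # midpoint - TSS, positive downstream of the gene
    klass: str  # proximal | distal
    orientation: str  # upstream | downstream | at_tss


@dataclass
class RegionGeneAssociation:
    associations: list[Association]
    genes_per_region: dict[str, int]  # keys "0", "1", "2", ">2"
    distance_bins: dict[str, int]
    orientation_counts: dict[str, int]
    n_regions: int


def _distance_bin(abs_bp: int) -> str:
    kb = abs_bp / 1000.0
    for lo, hi in DISTANCE_BINS_KB:
        if hi is None:
            return f">{lo} kb"
        in_bin = (kb <= hi) if lo == 0 else (lo < kb <= hi)
        if in_bin:
            return f"{lo}-{hi} kb"
    raise AssertionError("unreachable")


def associate_regions(
    regions: IntervalSet,
    genes: GeneAnnotation,
    layout: Optional[GenomeLayout] = None,
    basal_up: int = BASAL_UPSTREAM,
    basal_down: int = BASAL_DOWNSTREAM,
    max_ext: int = MAX_EXTENSION,
) -> RegionGeneAssociation:
    """Associate each region (by midpoint) with genes whose regulatory
    interval contains it, with proximal/distal classes and summary bins."""
    layout = layout or regions.layout
    domains = great_domains(genes, layout, basal_up, basal_down, max_ext)
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.gene.chrom, []).append(d)
    assoc: list[Association] = []
    gpr_hist = {"0": 0, "1": 0, "2": 0, ">2": 0}
    distance_bins: dict[str, int] = {}
    orientation_counts: dict[str, int] = {}
    for region in regions:
        mid = region.midpoint
        n_genes = 0
        for d in by_chrom.get(region.chrom, []):
            if not (d.start <= mid < d.end):
                continue
            n_genes += 1
            klass = "proximal" if d.basal_start <= mid < d.basal_end else "distal"
            signed = mid - d.gene.tss if d.gene.strand == "+" else d.gene.tss - mid
            if signed > 0:
                orientation = "downstream"
            elif signed < 0:
                orientation = "upstream"
            else:
                orientation = "at_tss"
            assoc.append(Association(region, d.gene.gene_id, signed, klass, orientation))
            b = _distance_bin(abs(signed))
            distance_bins[b] = distance_bins.get(b, 0) + 1
            orientation_counts[orientation] = orientation_counts.get(orientation, 0) + 1
        key = str(n_genes) if n_genes <= 2 else ">2"
        gpr_hist[key] += 1
    return RegionGeneAssociation(
        associations=assoc,
        genes_per_region=gpr_hist,
        distance_bins=distance_bins,
        orientation_counts=orientation_counts,
        n_regions=len(regions),
    )
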