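"""Genomic interval data model, BED / chrom.sizes I/O and size summaries.

Coordinates are 0-based half-open throughout: an interval ``[start, end)``
covers ``end - start`` base pairs.  Interval sets are kept sorted per
chromosome by ``(start, end)`` and are validated against a
:class:`GenomeLayout` (chromosome name -> length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

from . import _coverage as cov


class BedParseError(ValueError):
    """Raised for malformed BED / chrom.sizes content; carries the line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class LayoutMismatchError(ValueError):
    """Raised when interval sets do not share a genome layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome name -> length (bp) table bounding all coordinates."""

    entries: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "entries", dict(self.entries))
        for name, length in self.entries.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.entries)

    def length_of(self, chrom: str) -> int:
        return int(self.entries[chrom])

    @property
    def total_bp(self) -> int:
        return int(sum(self.entries.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and dict(self.entries) == dict(other.entries)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open region ``chrom:[start, end)`` with optional BED metadata."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    summit_offset: Optional[int] = None
    strand: Optional[str] = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside interval of length "
                f"{self.end - self.start}"
            )
        if self.strand is not None and self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def summit(self) -> int:
        """Summit position if annotated, else the midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return self.midpoint


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a half-open interval (``end - start``)."""
    return iv.length


class IntervalSet:
    """A per-chromosome sorted collection of :class:`GenomicInterval`.

    Parameters
    ----------
    intervals:
        Any iterable of intervals; stored sorted by ``(start, end)`` within
        each chromosome, chromosomes ordered as in ``layout``.
    layout:
        The coordinate space.  Every interval must fit inside its chromosome.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], layout: GenomeLayout):
        self.layout = layout
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            if iv.chrom not in layout:
                raise LayoutMismatchError(f"chromosome {iv.chrom!r} not in layout")
            if iv.end > layout.length_of(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {layout.length_of(iv.chrom)}"
                )
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._by_chrom = {
            chrom: sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
            for chrom in layout.chromosomes
            if chrom in by_chrom
        }
        self._arrays_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_arrays(
        cls,
        layout: GenomeLayout,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        names: Optional[Sequence[str]] = None,
    ) -> "IntervalSet":
        ivs = [
            GenomicInterval(
                c, int(s), int(e), name=None if names is None else names[i]
            )
            for i, (c, s, e) in enumerate(zip(chroms, starts, ends))
        ]
        return cls(ivs, layout)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def intervals_on(self, chrom: str) -> list[GenomicInterval]:
        return self._by_chrom.get(chrom, [])

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """``(starts, ends)`` int64 arrays for one chromosome (cached)."""
        if chrom not in self._arrays_cache:
            ivs = self._by_chrom.get(chrom, [])
            self._arrays_cache[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
        return self._arrays_cache[chrom]

    def midpoints(self, chrom: str) -> np.ndarray:
        s, e = self.arrays(chrom)
        return (s + e) // 2

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.layout == other.layout and list(self) == list(other)

    def covered_bp(self) -> int:
        total = 0
        for chrom in self.chromosomes:
            s, e = self.arrays(chrom)
            total += cov.union_length(s, e)
        return total

    def same_layout(self, other: "IntervalSet") -> bool:
        return self.layout == other.layout


# ---------------------------------------------------------------------------
# I/O

def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column tab-separated name/length table."""
    entries: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError("expected two tab-separated columns", lineno)
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise BedParseError(f"non-integer length {parts[1]!r}", lineno) from exc
            if name in entries:
                raise BedParseError(f"duplicate chromosome {name!r}", lineno)
            if length <= 0:
                raise BedParseError(f"non-positive length {length}", lineno)
            entries[name] = length
    return GenomeLayout(entries)


_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(
    path,
    layout: GenomeLayout,
    unknown_chrom: str = "reject",
) -> IntervalSet:
    """Read BED3/BED6 or the 10-column narrowPeak-like dialect.

    Column 10, when present and non-negative, is interpreted as the summit
    offset from the region start (-1 meaning absent).

    ``unknown_chrom`` is "reject" (default) or "drop"; "drop" discards
    records on chromosomes absent from the layout with a warning.
    """
    if unknown_chrom not in ("reject", "drop"):
        raise ValueError("unknown_chrom must be 'reject' or 'drop'")
    intervals: list[GenomicInterval] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if any(line.startswith(p) for p in _SKIP_PREFIXES):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError("fewer than 3 tab-separated columns", lineno)
            chrom = parts[0]
            try:
                start = int(parts[1])
                end = int(parts[2])
            except ValueError as exc:
                raise BedParseError(
                    f"non-integer coordinates {parts[1]!r}/{parts[2]!r}", lineno
                ) from exc
            if start >= end:
                raise BedParseError(
                    f"empty or inverted interval {chrom}:{start}-{end}", lineno
                )
            if start < 0:
                raise BedParseError(f"negative start {start}", lineno)
            if chrom not in layout:
                if unknown_chrom == "reject":
                    raise BedParseError(f"chromosome {chrom!r} not in layout", lineno)
                n_dropped += 1
                continue
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score: Optional[float] = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise BedParseError(f"non-numeric score {parts[4]!r}", lineno) from exc
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-", ".") else None
            summit: Optional[int] = None
            if len(parts) >= 10:
                try:
                    summit_raw = int(parts[9])
                except ValueError as exc:
                    raise BedParseError(
                        f"non-integer summit offset {parts[9]!r}", lineno
                    ) from exc
                if summit_raw >= 0:
                    if summit_raw >= end - start:
                        raise BedParseError(
                            f"summit offset {summit_raw} outside region", lineno
                        )
                    summit = summit_raw
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, summit, strand)
                )
            except ValueError as exc:
                raise BedParseError(str(exc), lineno) from exc
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} record(s) on chromosomes absent from layout")
    return IntervalSet(intervals, layout)


def write_bed(s: IntervalSet, path) -> None:
    """Write tab-separated BED; emits as many columns as are populated."""
    with open(path, "w") as fh:
        for iv in s:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            has_extra = (
                iv.name is not None or iv.score is not None or iv.strand is not None
            )
            if has_extra:
                cols.append(iv.name if iv.name is not None else ".")
                cols.append("%g" % iv.score if iv.score is not None else "0")
                cols.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Transformations

def merge_set(s: IntervalSet) -> IntervalSet:
    """Union overlapping or book-ended intervals into maximal runs."""
    merged: list[GenomicInterval] = []
    for chrom in s.chromosomes:
        starts, ends = s.arrays(chrom)
        ms, me = cov.merge_presorted(starts, ends)
        merged.extend(
            GenomicInterval(chrom, int(a), int(b)) for a, b in zip(ms, me)
        )
    return IntervalSet(merged, s.layout)


def resize_fixed_width(s: IntervalSet, flank: int) -> IntervalSet:
    """Replace each region by ``[c - flank, c + flank)`` around its summit.

    ``c`` is ``start + summit_offset`` when a summit is annotated, else the
    midpoint.  Results are clamped to chromosome bounds; the rare region that
    becomes empty after clamping is dropped with a warning.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out: list[GenomicInterval] = []
    n_dropped = 0
    for iv in s:
        c = iv.summit
        clen = s.layout.length_of(iv.chrom)
        start = max(0, c - flank)
        end = min(clen, c + flank)
        if start >= end:
            n_dropped += 1
            continue
        out.append(replace(iv, start=start, end=end, summit_offset=None))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} region(s) empty after clamping")
    return IntervalSet(out, s.layout)


# ---------------------------------------------------------------------------
# Size summaries

@dataclass
class SizeSummary:
    """Descriptive statistics of region lengths."""

    n: int
    mean: float
    median: float
    histogram: list[tuple[int, int, int]] = field(default_factory=list)
    fraction_above: dict[int, float] = field(default_factory=dict)


def size_summary(
    s: IntervalSet,
    bin_width: int = 100,
    thresholds: Sequence[int] = (1000,),
) -> SizeSummary:
    """Mean/median/histogram of region lengths plus tail fractions.

    The median of an even count is the mean of the two central values.
    """
    lengths = np.array([iv.length for iv in s], dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("size_summary of an empty interval set")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(lengths.max() // bin_width) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    histogram = [
        (int(edges[i]), int(edges[i + 1]), int(c)) for i, c in enumerate(counts)
    ]
    fraction_above = {
        int(t): float((lengths > t).mean()) for t in thresholds
    }
    return SizeSummary(
        n=int(lengths.size),
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        histogram=histogram,
        fraction_above=fraction_above,
    )
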