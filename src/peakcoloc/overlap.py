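"""Overlap detection and decomposition between two interval sets.

Intersection requires at least one shared base pair, so book-ended half-open
intervals do NOT overlap.  "Sections" are the maximal intervals of the bp
intersection of the two sets' merged coverages: one long region spanning k
disjoint regions of the other set contributes k sections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _coverage as cov
from .intervals import GenomicInterval, IntervalSet, LayoutMismatchError


@dataclass
class OverlapSummary:
    """Venn-style counts for a query-vs-reference comparison."""

    n_query: int
    n_reference: int
    n_query_overlapped: int
    n_reference_overlapped: int
    n_sections: int
    query_overlap_fraction: float


@dataclass
class GapDistanceTable:
    """Per-query-region nearest gap (bp) to the reference set.

    ``gaps[i]`` is the edge-to-edge distance from query region ``i`` (in
    IntervalSet iteration order) to its nearest same-chromosome reference
    region, 0 when they intersect, NaN when the chromosome carries no
    reference region.
    """

    gaps: np.ndarray
    query_order: list[GenomicInterval]

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.gaps)


def _check_layout(query: IntervalSet, reference: IntervalSet) -> None:
    if not query.same_layout(reference):
        raise LayoutMismatchError("query and reference use different genome layouts")


def find_overlap_pairs(
    query: IntervalSet, reference: IntervalSet
) -> list[tuple[int, int]]:
    """All (query index, reference index) pairs sharing >= 1 bp.

    Indices refer to IntervalSet iteration order.  Pairs are ordered by
    chromosome, then query start, then reference start.  Uses a per-chromosome
    sweep over start-sorted arrays with an end-pruned active window.
    """
    _check_layout(query, reference)
    pairs: list[tuple[int, int]] = []
    q_offset = 0
    offsets_r: dict[str, int] = {}
    pos = 0
    for chrom in reference.chromosomes:
        offsets_r[chrom] = pos
        pos += len(reference.intervals_on(chrom))
    for chrom in query.chromosomes:
        qs, qe = query.arrays(chrom)
        n_q = qs.size
        if chrom not in offsets_r:
            q_offset += n_q
            continue
        rs, re = reference.arrays(chrom)
        r_off = offsets_r[chrom]
        # candidate refs start before the query ends; filter by end > q start
        hi = np.searchsorted(rs, qe, side="left")
        for i in range(n_q):
            cand = np.flatnonzero(re[: hi[i]] > qs[i])
            pairs.extend((q_offset + i, r_off + int(j)) for j in cand)
        q_offset += n_q
    return pairs


def common_sections(query: IntervalSet, reference: IntervalSet) -> IntervalSet:
    """Maximal intervals covered by both sets' merged coverages."""
    _check_layout(query, reference)
    out: list[GenomicInterval] = []
    for chrom in query.chromosomes:
        if chrom not in reference.chromosomes:
            continue
        qs, qe = cov.merge_presorted(*query.arrays(chrom))
        rs, re = cov.merge_presorted(*reference.arrays(chrom))
        ss, se = cov.intersect_merged(qs, qe, rs, re)
        out.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(ss, se))
    return IntervalSet(out, query.layout)


def venn_counts(query: IntervalSet, reference: IntervalSet) -> OverlapSummary:
    """Full overlap summary (region counts each way plus section count)."""
    _check_layout(query, reference)
    pairs = find_overlap_pairs(query, reference)
    n_q_over = len({q for q, _ in pairs})
    n_r_over = len({r for _, r in pairs})
    n_sections = len(common_sections(query, reference))
    n_q = len(query)
    frac = round(n_q_over / n_q, 3) if n_q else 0.0
    return OverlapSummary(
        n_query=n_q,
        n_reference=len(reference),
        n_query_overlapped=n_q_over,
        n_reference_overlapped=n_r_over,
        n_sections=n_sections,
        query_overlap_fraction=frac,
    )


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Edge-to-edge bp gap; 0 for any intersection; None across chromosomes."""
    if a.chrom != b.chrom:
        return None
    return max(0, b.start - a.end, a.start - b.end)


def gap_distances(query: IntervalSet, reference: IntervalSet) -> GapDistanceTable:
    """Nearest edge-to-edge gap from every query region to the reference set."""
    _check_layout(query, reference)
    gaps: list[float] = []
    order: list[GenomicInterval] = []
    for chrom in query.chromosomes:
        qs, qe = query.arrays(chrom)
        ivs = query.intervals_on(chrom)
        order.extend(ivs)
        rs, re = reference.arrays(chrom)
        if rs.size == 0:
            gaps.extend([math.nan] * qs.size)
            continue
        re_cummax = np.maximum.accumulate(re)
        for i in range(qs.size):
            # overlap check: any ref with start < q end and end > q start
            lo = np.searchsorted(rs, qe[i], side="left")
            if lo > 0 and re_cummax[lo - 1] > qs[i]:
                # a candidate might still end before q start; verify cheaply
                if np.any(re[:lo] > qs[i]):
                    gaps.append(0.0)
                    continue
            best = math.inf
            # nearest ref entirely to the left: maximise end among starts < qs
            j = np.searchsorted(rs, qs[i], side="right")
            if j > 0:
                best = min(best, qs[i] - re_cummax[j - 1])
            # nearest ref to the right: minimal start >= q end
            k = np.searchsorted(rs, qe[i], side="left")
            if k < rs.size:
                best = min(best, rs[k] - qe[i])
            gaps.append(float(max(0, best)))
        # note: a ref straddling [qs, qe) without the two probes above is
        # impossible -- it would have been caught by the overlap check
    return GapDistanceTable(gaps=np.array(gaps, dtype=float), query_order=order)
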