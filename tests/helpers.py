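"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive (quadratic scans, per-bp boolean
coverage, exhaustive placement enumeration) and shares no code with the
package's sweep/searchsorted/interval-arithmetic paths.
"""

from __future__ import annotations

import math

import numpy as np

from peakcoloc.intervals import GenomeLayout, GenomicInterval, IntervalSet


def brute_pairs(query: IntervalSet, reference: IntervalSet) -> list[tuple[int, int]]:
    """All-pairs overlap scan; >= 1 shared bp required."""
    q = list(query)
    r = list(reference)
    pairs = []
    for i, a in enumerate(q):
        for j, b in enumerate(r):
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                pairs.append((i, j))
    pairs.sort(key=lambda p: (q[p[0]].chrom, q[p[0]].start, p[0], r[p[1]].start, p[1]))
    return pairs


def coverage_mask(s: IntervalSet, layout: GenomeLayout) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(layout.length_of(c), dtype=bool) for c in layout.chromosomes}
    for iv in s:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def brute_sections(query: IntervalSet, reference: IntervalSet) -> list[tuple[str, int, int]]:
    """Maximal runs of per-bp AND of the two coverages."""
    layout = query.layout
    out = []
    qm = coverage_mask(query, layout)
    rm = coverage_mask(reference, layout)
    for chrom in layout.chromosomes:
        both = qm[chrom] & rm[chrom]
        padded = np.concatenate(([False], both, [False])).astype(np.int8)
        diff = np.diff(padded)
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        out.extend((chrom, int(a), int(b)) for a, b in zip(starts, ends))
    return out


def brute_gap(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return math.inf
    return max(0, b.start - a.end, a.start - b.end)


def brute_gap_table(query: IntervalSet, reference: IntervalSet) -> list[float]:
    out = []
    for q in query:
        best = math.inf
        for r in reference:
            best = min(best, brute_gap(q, r))
        out.append(math.nan if math.isinf(best) else float(best))
    return out


def brute_jaccard(query: IntervalSet, reference: IntervalSet) -> float:
    layout = query.layout
    qm = coverage_mask(query, layout)
    rm = coverage_mask(reference, layout)
    inter = sum(int((qm[c] & rm[c]).sum()) for c in layout.chromosomes)
    union = sum(int((qm[c] | rm[c]).sum()) for c in layout.chromosomes)
    return inter / union


def enumerate_region_pvalue(
    q: GenomicInterval,
    reference: IntervalSet,
    domain_intervals: IntervalSet,
    layout: GenomeLayout,
) -> float:
    """Exhaustive placement enumeration of the proximity p-value.

    Placements are all integer starts keeping an L-length interval on its
    chromosome with its midpoint inside the domain, pooled over chromosomes.
    """
    L = q.end - q.start
    d = min((brute_gap(q, r) for r in reference), default=math.inf)
    if math.isinf(d):
        return 1.0
    total = 0
    favorable = 0
    for chrom in layout.chromosomes:
        clen = layout.length_of(chrom)
        dom = [(iv.start, iv.end) for iv in domain_intervals if iv.chrom == chrom]
        refs = [(iv.start, iv.end) for iv in reference if iv.chrom == chrom]
        for s in range(0, clen - L + 1):
            mid = s + L // 2
            if not any(a <= mid < b for a, b in dom):
                continue
            total += 1
            gap = min(
                (max(0, a - (s + L), s - b) for a, b in refs), default=math.inf
            )
            if gap <= d:
                favorable += 1
    if total == 0:
        raise ValueError("no valid placement")
    return favorable / total


def random_interval_set(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n: int,
    max_len: int = 200,
    names: bool = False,
) -> IntervalSet:
    chroms = layout.chromosomes
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = layout.length_of(chrom)
        L = int(rng.integers(1, max_len + 1))
        if L >= clen:
            L = clen - 1
        start = int(rng.integers(0, clen - L + 1))
        ivs.append(
            GenomicInterval(chrom, start, start + L, name=f"iv{i}" if names else None)
        )
    return IntervalSet(ivs, layout)
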