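"""Low-level vectorised interval arithmetic on numpy arrays.

All functions operate on half-open integer intervals [start, end).  They are
the shared substrate for coverage, Jaccard and placement-null computations;
the public data model lives in :mod:`peakcoloc.intervals`.
"""

from __future__ import annotations

import numpy as np

_NEG = np.iinfo(np.int64).min // 4  # sentinel well below any coordinate


def as_int64(a) -> np.ndarray:
    return np.asarray(a, dtype=np.int64)


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of arbitrary intervals as merged, disjoint, sorted arrays.

    Book-ended intervals (end == next start) are coalesced.
    """
    starts = as_int64(starts)
    ends = as_int64(ends)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.lexsort((ends, starts))
    lo = starts[order]
    hi = ends[order]
    return merge_presorted(lo, hi)


def merge_presorted(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge intervals whose starts are already sorted ascending."""
    if lo.size == 0:
        return lo.copy(), hi.copy()
    hicm = np.maximum.accumulate(hi)
    prev = np.concatenate(([_NEG], hicm[:-1]))
    newrun = lo > prev  # strict: book-ended runs coalesce
    newrun[0] = True
    idx = np.flatnonzero(newrun)
    m_start = lo[idx]
    last = np.append(idx[1:] - 1, lo.size - 1)
    m_end = hicm[last]
    return m_start, m_end


def union_length_presorted(lo: np.ndarray, hi: np.ndarray) -> int:
    """Total bp covered by intervals with starts sorted ascending."""
    if lo.size == 0:
        return 0
    hicm = np.maximum.accumulate(hi)
    prev = np.concatenate(([_NEG], hicm[:-1]))
    contrib = hicm - np.maximum(lo, prev)
    return int(np.clip(contrib, 0, None).sum())


def union_length(starts, ends) -> int:
    starts = as_int64(starts)
    ends = as_int64(ends)
    if starts.size == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    return union_length_presorted(starts[order], ends[order])


def intersection_length(a_start, a_end, b_start, b_end) -> int:
    """bp shared by two merged/disjoint/sorted interval lists."""
    a_start = as_int64(a_start)
    b_start = as_int64(b_start)
    a_end = as_int64(a_end)
    b_end = as_int64(b_end)
    if a_start.size == 0 or b_start.size == 0:
        return 0
    # for each A interval, B intervals j with b_start[j] < a_end and b_end[j] > a_start
    j0 = np.searchsorted(b_end, a_start, side="right")
    j1 = np.searchsorted(b_start, a_end, side="left")
    total = 0
    cum = np.concatenate(([0], np.cumsum(b_end - b_start)))
    for i in range(a_start.size):
        lo, hi = j0[i], j1[i]
        if hi <= lo:
            continue
        full = cum[hi] - cum[lo]
        # clip the two edge intervals against A
        full -= max(0, a_start[i] - b_start[lo])
        full -= max(0, b_end[hi - 1] - a_end[i])
        total += full
    return int(total)


def intersect_merged(a_start, a_end, b_start, b_end) -> tuple[np.ndarray, np.ndarray]:
    """Interval intersection of two merged/disjoint/sorted lists."""
    a_start = as_int64(a_start)
    a_end = as_int64(a_end)
    b_start = as_int64(b_start)
    b_end = as_int64(b_end)
    out_s: list[int] = []
    out_e: list[int] = []
    i = j = 0
    while i < a_start.size and j < b_start.size:
        s = max(a_start[i], b_start[j])
        e = min(a_end[i], b_end[j])
        if s < e:
            out_s.append(int(s))
            out_e.append(int(e))
        if a_end[i] <= b_end[j]:
            i += 1
        else:
            j += 1
    return as_int64(out_s), as_int64(out_e)


def row_coverage(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Union bp per row for 2-D arrays of intervals (one replicate per row)."""
    if starts.size == 0:
        return np.zeros(starts.shape[0], dtype=np.int64)
    order = np.argsort(starts, axis=1, kind="stable")
    s = np.take_along_axis(starts, order, axis=1)
    e = np.take_along_axis(ends, order, axis=1)
    ecm = np.maximum.accumulate(e, axis=1)
    prev = np.concatenate(
        (np.full((s.shape[0], 1), _NEG, dtype=np.int64), ecm[:, :-1]), axis=1
    )
    contrib = np.clip(ecm - np.maximum(s, prev), 0, None)
    return contrib.sum(axis=1)


def nearest_point_distance(points: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest anchor (anchors sorted).

    Works on 1-D or 2-D ``points`` (rows are replicates).
    """
    pad = np.concatenate(([_NEG], anchors, [-_NEG]))
    idx = np.searchsorted(pad, points, side="left")
    left = points - pad[idx - 1]
    right = pad[idx] - points
    return np.minimum(left, right)
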