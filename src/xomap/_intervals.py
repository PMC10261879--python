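"""Merged-interval arithmetic on plain numpy arrays.

All coordinates are 0-based, half-open ``[start, end)``.  A *merged set* is a
pair of equal-length arrays ``(starts, ends)`` that is sorted by start,
strictly non-overlapping and non-adjacent.  Keeping feature classes in this
form lets every query used by the pipeline (point membership, any-overlap,
overlap bp, k-fold coverage) run as a searchsorted/prefix-sum, which is what
makes the 10,000-replicate Monte Carlo loop cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge",
    "complement",
    "intersect",
    "union",
    "total_length",
    "overlap_bp",
    "overlaps_any",
    "points_in",
    "coverage_at_least",
]


def merge(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Sort and fuse overlapping or book-ended intervals into a merged set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    if np.any(ends < starts):
        raise ValueError("interval end < start")
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    run_end = np.maximum.accumulate(ends)
    # new block wherever a start exceeds the furthest end seen so far
    new_block = np.ones(starts.size, dtype=bool)
    new_block[1:] = starts[1:] > run_end[:-1]
    idx = np.flatnonzero(new_block)
    out_starts = starts[idx]
    out_ends = np.empty_like(out_starts)
    out_ends[:-1] = run_end[idx[1:] - 1]
    out_ends[-1] = run_end[-1]
    keep = out_ends > out_starts
    return out_starts[keep], out_ends[keep]


def complement(starts, ends, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Complement of a merged set within [0, length)."""
    starts, ends = merge(starts, ends)
    starts = np.clip(starts, 0, length)
    ends = np.clip(ends, 0, length)
    cs = np.concatenate(([0], ends))
    ce = np.concatenate((starts, [length]))
    keep = ce > cs
    return cs[keep], ce[keep]


def intersect(a: tuple, b: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Intersection of two merged sets."""
    sa, ea = a
    sb, eb = b
    if sa.size == 0 or sb.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    out_s, out_e = [], []
    i = j = 0
    while i < sa.size and j < sb.size:
        s = max(sa[i], sb[j])
        e = min(ea[i], eb[j])
        if e > s:
            out_s.append(s)
            out_e.append(e)
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def union(a: tuple, b: tuple) -> tuple[np.ndarray, np.ndarray]:
    return merge(np.concatenate((a[0], b[0])), np.concatenate((a[1], b[1])))


def total_length(starts, ends) -> int:
    return int(np.sum(np.asarray(ends) - np.asarray(starts)))


def _coverage_before(starts, ends, x):
    """Covered bp of the merged set in [0, x) for each x (vectorised)."""
    x = np.asarray(x, dtype=np.int64)
    prefix = np.concatenate(([0], np.cumsum(ends - starts)))
    i = np.searchsorted(starts, x, side="right")
    base = prefix[i]
    # subtract the part of the last entered interval that lies beyond x
    over = np.where(i > 0, np.maximum(ends[np.maximum(i - 1, 0)] - x, 0), 0)
    # ... but never more than that interval's length
    over = np.minimum(over, np.where(i > 0, (ends - starts)[np.maximum(i - 1, 0)], 0))
    return base - over


def overlap_bp(starts, ends, qstarts, qends) -> np.ndarray:
    """bp of the merged set falling inside each query window."""
    if len(starts) == 0:
        return np.zeros(np.asarray(qstarts).shape, dtype=np.int64)
    return _coverage_before(starts, ends, qends) - _coverage_before(starts, ends, qstarts)


def overlaps_any(starts, ends, qstarts, qends) -> np.ndarray:
    """Boolean: does each query interval intersect the merged set by >= 1 bp?"""
    qstarts = np.asarray(qstarts, dtype=np.int64)
    qends = np.asarray(qends, dtype=np.int64)
    if len(starts) == 0:
        return np.zeros(qstarts.shape, dtype=bool)
    j = np.searchsorted(ends, qstarts, side="right")
    hit = j < len(starts)
    safe = np.minimum(j, len(starts) - 1)
    return hit & (starts[safe] < qends)


def points_in(starts, ends, x) -> np.ndarray:
    """Boolean: does each point fall inside the merged set?"""
    x = np.asarray(x)
    if len(starts) == 0:
        return np.zeros(x.shape, dtype=bool)
    j = np.searchsorted(ends, x, side="right")
    hit = j < len(starts)
    safe = np.minimum(j, len(starts) - 1)
    return hit & (starts[safe] <= x)


def coverage_at_least(sets: list[tuple], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Regions covered by at least k of the given merged sets."""
    if not sets:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    pos = np.concatenate([s for s, _ in sets] + [e for _, e in sets])
    delta = np.concatenate(
        [np.ones(len(s), dtype=np.int64) for s, _ in sets]
        + [-np.ones(len(e), dtype=np.int64) for _, e in sets]
    )
    order = np.lexsort((-delta, pos))  # starts before ends at equal position
    pos, delta = pos[order], delta[order]
    cov = np.cumsum(delta)
    above = cov >= k
    out_s, out_e = [], []
    open_at = None
    for p, a in zip(pos, above):
        if a and open_at is None:
            open_at = p
        elif not a and open_at is not None:
            if p > open_at:
                out_s.append(open_at)
                out_e.append(p)
            open_at = None
    return merge(np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64))
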