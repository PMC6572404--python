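"""Sorted-interval utilities (0-based half-open) used by profiles and dmr."""

from __future__ import annotations

import numpy as np


def merge_intervals(intervals):
    """Merge possibly-overlapping (start, end) pairs into disjoint sorted arrays."""
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts, ends = [], []
    cs, ce = ivs[0]
    for s, e in ivs[1:]:
        if s <= ce:
            ce = max(ce, e)
        else:
            starts.append(cs)
            ends.append(ce)
            cs, ce = s, e
    starts.append(cs)
    ends.append(ce)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def covered_mask(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall inside the merged intervals."""
    pos = np.asarray(pos, dtype=np.int64)
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def overlap_len(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> int:
    """Total overlap in bp between [s, e) and the merged interval set."""
    if starts.size == 0 or e <= s:
        return 0
    i0 = int(np.searchsorted(ends, s, side="right"))
    i1 = int(np.searchsorted(starts, e, side="left"))
    total = 0
    for i in range(i0, i1):
        total += min(int(ends[i]), e) - max(int(starts[i]), s)
    return total
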