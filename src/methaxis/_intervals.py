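"""Interval-set arithmetic on sorted half-open intervals.

All functions operate on a single chromosome's worth of intervals
represented as an ``(N, 2)`` integer array of 0-based half-open
``[start, end)`` rows. Inputs need not be sorted or disjoint unless
stated; outputs are always sorted and merged (disjoint).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_array",
    "merge",
    "subtract",
    "intersect",
    "complement",
    "clip",
    "total_length",
    "overlap_length",
]


def as_array(intervals) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to an (N, 2) int64 array."""
    arr = np.asarray(list(intervals), dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return arr.reshape(-1, 2)


def merge(arr) -> np.ndarray:
    """Sort and merge overlapping or touching intervals."""
    arr = as_array(arr)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s <= cur_e:  # touching intervals coalesce
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return as_array(out)


def subtract(a, b) -> np.ndarray:
    """Set difference a \\ b; both merged internally."""
    a, b = merge(a), merge(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    for s, e in a:
        cur = s
        # b intervals overlapping [s, e)
        lo = np.searchsorted(b[:, 1], cur, side="right")
        for bs, be in b[lo:]:
            if bs >= e:
                break
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return as_array(out)


def intersect(a, b) -> np.ndarray:
    """Set intersection of two interval sets."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return as_array(out)


def complement(arr, length: int) -> np.ndarray:
    """Complement within [0, length)."""
    return subtract([(0, int(length))], arr)


def clip(arr, length: int) -> np.ndarray:
    """Clip intervals to [0, length), dropping any that become empty."""
    arr = as_array(arr)
    if len(arr) == 0:
        return arr
    arr = arr.copy()
    arr[:, 0] = np.clip(arr[:, 0], 0, length)
    arr[:, 1] = np.clip(arr[:, 1], 0, length)
    return arr[arr[:, 0] < arr[:, 1]]


def total_length(arr) -> int:
    arr = merge(arr)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


def overlap_length(query: tuple[int, int], arr) -> int:
    """Number of bases of the single interval ``query`` covered by ``arr``."""
    return total_length(intersect([query], arr))


def positions_in(positions: np.ndarray, arr) -> np.ndarray:
    """Boolean mask: which 0-based positions fall inside the interval set."""
    arr = merge(arr)
    positions = np.asarray(positions, dtype=np.int64)
    if len(arr) == 0 or len(positions) == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(positions), dtype=bool)
    inside[ok] = positions[ok] < arr[idx[ok], 1]
    return inside
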