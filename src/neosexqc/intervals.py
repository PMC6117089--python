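"""Half-open interval utilities (BED convention).

The distance-merge here backs the BAC locus caller, where the merge /
re-merge cascade is part of the published placement rule, so it is kept
as an explicit, oracle-testable primitive.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(
    intervals: list[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int, list[int]]]:
    """Merge [start, end) intervals whose gap is <= ``max_gap``.

    Returns (start, end, member_indices) triples, sorted by start; member
    indices refer to the input list so callers can re-merge constituents
    with a different distance.
    """
    if not intervals:
        return []
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i][0], intervals[i][1]))
    merged: list[tuple[int, int, list[int]]] = []
    cs, ce, members = intervals[order[0]][0], intervals[order[0]][1], [order[0]]
    for i in order[1:]:
        s, e = intervals[i]
        if s - ce <= max_gap:
            ce = max(ce, e)
            members.append(i)
        else:
            merged.append((cs, ce, members))
            cs, ce, members = s, e, [i]
    merged.append((cs, ce, members))
    return merged


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total number of bases covered by the union of [start, end) intervals."""
    total = 0
    for s, e, _ in merge_intervals(intervals):
        total += e - s
    return total


def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def majority_in(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    """True when more than half of [start, end) lies inside the interval union."""
    covered = sum(overlap((start, end), iv) for iv in merge_intervals(intervals))
    return covered * 2 > (end - start)


def window_partition(scaffold_lengths: dict[str, int], window: int):
    """Tile scaffolds with fixed windows (last window may be short).

    Returns (scaffold index array, start array, end array, names list).
    Scaffolds shorter than one window get a single ragged window.
    """
    refs, starts, ends = [], [], []
    names = list(scaffold_lengths)
    for i, name in enumerate(names):
        length = scaffold_lengths[name]
        n = max(1, -(-length // window))
        for w in range(n):
            refs.append(i)
            starts.append(w * window)
            ends.append(min((w + 1) * window, length))
    return (
        np.array(refs, dtype=np.int32),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        names,
    )
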