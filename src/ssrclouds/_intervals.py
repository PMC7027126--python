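"""Small shared helpers for 0-based half-open genomic intervals."""

from __future__ import annotations


def merge_intervals(
    intervals: list[tuple[int, int]], gap: int = 0
) -> list[tuple[int, int]]:
    """Union intervals whose separation is <= ``gap`` (strict overlap for
    gap < 0 is not meaningful; gap=0 merges touching/overlapping)."""
    if gap < 0:
        raise ValueError("gap must be non-negative")
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start - out[-1][1] <= gap:
            prev = out[-1]
            out[-1] = (prev[0], max(prev[1], end))
        else:
            out.append((start, end))
    return out


def intersect_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total bp of intersection between two interval lists (same chrom)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def overlaps_any(
    start: int, end: int, sorted_intervals: list[tuple[int, int]]
) -> bool:
    """Whether [start, end) overlaps any interval in a sorted, merged list."""
    import bisect

    idx = bisect.bisect_right(sorted_intervals, (start, float("inf"))) - 1
    if idx >= 0 and sorted_intervals[idx][1] > start:
        return True
    if idx + 1 < len(sorted_intervals) and sorted_intervals[idx + 1][0] < end:
        return True
    return False
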