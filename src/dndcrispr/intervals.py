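"""Interval arithmetic on 0-based half-open genomic intervals.

All coordinates inside the package are 0-based half-open ``[start, end)``.
GTF/VCF (1-based) are converted at the I/O boundary. Intervals are plain
``(start, end)`` tuples; interval *sets* are lists of such tuples, kept
sorted and merged by the helpers below.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]


def normalize(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort, drop empty, and merge overlapping/adjacent intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Intersection of two normalized interval sets (linear sweep)."""
    a, b = normalize(a), normalize(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(sets: Sequence[Sequence[Interval]]) -> List[Interval]:
    """Intersection of several interval sets; empty input -> empty result."""
    if not sets:
        return []
    acc = normalize(sets[0])
    for other in sets[1:]:
        acc = intersect(acc, other)
        if not acc:
            break
    return acc


def union(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    return normalize(list(a) + list(b))


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Positions in ``a`` not in ``b``."""
    a, b = normalize(a), normalize(b)
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals: Sequence[Interval], lo: int, hi: int) -> List[Interval]:
    """Clip an interval set to ``[lo, hi)``."""
    return [(max(s, lo), min(e, hi)) for s, e in normalize(intervals) if min(e, hi) > max(s, lo)]


def contains(intervals: Sequence[Interval], pos: int) -> bool:
    """Membership of a single position (linear scan; sets here are tiny)."""
    return any(s <= pos < e for s, e in intervals)
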