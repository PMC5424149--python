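"""Half-open interval arithmetic on 0-based genomic coordinates.

All intervals are ``(start, end)`` tuples with ``start < end``; lists of
intervals passed between functions are kept sorted and disjoint.
"""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or bookended intervals."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(span: Interval, holes: list[Interval]) -> list[Interval]:
    """Return ``span`` minus ``holes`` as sorted disjoint intervals."""
    s, e = span
    out: list[Interval] = []
    cur = s
    for hs, he in merge(holes):
        hs, he = max(hs, s), min(he, e)
        if hs >= he:
            continue
        if hs > cur:
            out.append((cur, hs))
        cur = max(cur, he)
    if cur < e:
        out.append((cur, e))
    return out


def intersect(a: Interval, b: Interval) -> Interval | None:
    s, e = max(a[0], b[0]), min(a[1], b[1])
    return (s, e) if s < e else None


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)
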