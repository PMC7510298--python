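"""Interval arithmetic shared by intergenic extraction and background sampling.

All coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of possibly overlapping intervals, sorted."""
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    merged: List[Interval] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def complement_intervals(length: int, intervals: Iterable[Interval]) -> List[Interval]:
    """Maximal intervals of [0, length) not covered by *intervals*.

    Includes the stretches before the first and after the last covered
    interval, so an empty annotation yields the whole [0, length).
    """
    if length <= 0:
        return []
    gaps: List[Interval] = []
    cursor = 0
    for a, b in merge_intervals(intervals):
        a = max(0, a)
        b = min(length, b)
        if a > cursor:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < length:
        gaps.append((cursor, length))
    return gaps
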