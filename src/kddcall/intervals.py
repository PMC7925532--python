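"""Half-open genomic interval arithmetic.

All coordinates in this package are 0-based, half-open (BED convention);
conversion to 1-based happens only at VCF output.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended half-open intervals into a sorted union."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of bases shared by two half-open intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def covered_bases(intervals: Sequence[tuple[int, int]], target: tuple[int, int]) -> int:
    """Bases of `target` covered by the union of `intervals`."""
    return sum(overlap_length(iv, target) for iv in merge_intervals(intervals))
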