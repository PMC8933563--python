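"""Interval algebra: overlaps, indexed range queries, point distances.

The index wraps one interval tree per chromosome; query semantics are
half-open, so adjacency (``a.end == b.start``) never counts as overlap.
"""

from __future__ import annotations

from typing import Any, Callable, Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import GenomicInterval


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two half-open intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff the intervals share at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    return overlap_length(a, b) >= min_bp


def distance_to_point(a: GenomicInterval, pos: int) -> int:
    """Distance from a half-open interval to a point on the same chromosome.

    Zero when the point lies inside the interval; otherwise the distance to
    the nearest covered base (the last base is ``end - 1``).
    """
    if a.start <= pos < a.end:
        return 0
    return min(abs(pos - (a.end - 1)), abs(pos - a.start))


class IntervalIndex:
    """Per-chromosome interval tree over arbitrary items carrying an interval.

    ``interval_of`` extracts the :class:`GenomicInterval` from each stored
    item (identity by default, so a plain collection of intervals works).
    """

    def __init__(
        self,
        items: Iterable[Any] = (),
        interval_of: Callable[[Any], GenomicInterval] | None = None,
    ):
        self._interval_of = interval_of or (lambda item: item)
        self._trees: dict[str, IntervalTree] = {}
        self._items: list[Any] = []
        self._by_chrom: dict[str, list[Any]] = {}
        for item in items:
            self.add(item)

    def add(self, item: Any) -> None:
        iv = self._interval_of(item)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, item)
        self._items.append(item)
        self._by_chrom.setdefault(iv.chrom, []).append(item)

    @property
    def items(self) -> list[Any]:
        return list(self._items)

    def items_on(self, chrom: str) -> list[Any]:
        return list(self._by_chrom.get(chrom, []))

    def query(self, probe: GenomicInterval) -> list[Any]:
        """All stored items whose interval overlaps the probe (>= 1 bp)."""
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(probe.start, probe.end)]

    def __len__(self) -> int:
        return len(self._items)


def build_index(intervals: Iterable[GenomicInterval]) -> IntervalIndex:
    return IntervalIndex(intervals)


def query(index: IntervalIndex, probe: GenomicInterval) -> list[Any]:
    return index.query(probe)


def brute_force_query(
    intervals: Sequence[GenomicInterval], probe: GenomicInterval
) -> list[GenomicInterval]:
    """Exhaustive all-pairs overlap scan; the oracle the index is tested against."""
    return [iv for iv in intervals if overlap_length(iv, probe) >= 1]
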