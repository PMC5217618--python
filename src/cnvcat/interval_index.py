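"""Fast overlap queries over large interval collections.

The contract is purely semantic: a query returns exactly what a linear scan
with :func:`cnvcat.core.overlaps` would return, sorted by (start, end) with
ties broken by insertion order.  The backing structure is an interval tree
per chromosome; duplicates are preserved because multiple probes may share
coordinates.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any, Iterable, Sequence

from intervaltree import IntervalTree

from .core import GenomicInterval, Track, overlaps, record_step

__all__ = ["IntervalIndex", "build_index", "query", "filter_tracks"]


class IntervalIndex:
    """Per-chromosome overlap index over (interval, payload) pairs."""

    def __init__(self, items: Iterable[tuple[GenomicInterval, Any]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._items: list[tuple[GenomicInterval, Any]] = []
        for interval, payload in items:
            self.add(interval, payload)

    def add(self, interval: GenomicInterval, payload: Any) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        # store only the insertion index; payloads need not be hashable
        tree.addi(interval.start, interval.end, len(self._items))
        self._items.append((interval, payload))

    @property
    def size(self) -> int:
        return len(self._items)

    def __len__(self) -> int:
        return self.size

    def query(self, q: GenomicInterval) -> list[tuple[GenomicInterval, Any]]:
        """All indexed items overlapping ``q``, sorted by (start, end, insertion)."""
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(q.start, q.end), key=lambda h: (h.begin, h.end, h.data))
        return [self._items[h.data] for h in hits]

    def query_all(self, chrom: str) -> list[tuple[GenomicInterval, Any]]:
        """Every item on ``chrom``, sorted by (start, end, insertion)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree, key=lambda h: (h.begin, h.end, h.data))
        return [self._items[h.data] for h in hits]


def build_index(items: Iterable[tuple[GenomicInterval, Any]]) -> IntervalIndex:
    return IntervalIndex(items)


def query(index: IntervalIndex, q: GenomicInterval) -> list[tuple[GenomicInterval, Any]]:
    return index.query(q)


def filter_tracks(tracks: Sequence[Track], region: GenomicInterval) -> list[Track]:
    """Restrict each track to measurements overlapping ``region``.

    Tracks left with no measurements are dropped; surviving tracks record
    the filter in their history.
    """
    out: list[Track] = []
    for t in tracks:
        kept = tuple(m for m in t.measurements if overlaps(m.interval, region))
        if not kept:
            continue
        filtered = replace(t, measurements=kept)
        out.append(record_step(filtered, "filter", {"region": str(region)}))
    return out
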