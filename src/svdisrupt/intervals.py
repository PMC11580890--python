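"""Genomic intervals and overlap arithmetic.

All coordinates inside the library are 0-based, half-open ``[start, end)``;
conversion to and from 1-based formats happens only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Interval:
    """A genomic interval on one chromosome.

    ``end - start`` is the length in bp.  ``strand`` is ``"+"``, ``"-"`` or
    ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def union_span(self, other: "Interval") -> "Interval":
        """Smallest interval containing both (same chromosome required)."""
        if self.chrom != other.chrom:
            raise ValueError("union_span across chromosomes")
        return Interval(self.chrom, min(self.start, other.start), max(self.end, other.end))


@dataclass
class IntervalSet:
    """A queryable collection of intervals, grouped by chromosome.

    Sized for annotation tracks of up to a few thousand entries; overlap
    queries are vectorised per chromosome.
    """

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[Interval]]] = {}
        for iv in self.intervals:
            self._by_chrom.setdefault(iv.chrom, ([], [], []))  # type: ignore[arg-type]
        groups: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            groups.setdefault(iv.chrom, []).append(iv)
        self._by_chrom = {
            chrom: (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
                ivs,
            )
            for chrom, ivs in groups.items()
        }

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def overlapping(self, query: Interval) -> list[Interval]:
        got = self._by_chrom.get(query.chrom)
        if got is None:
            return []
        starts, ends, ivs = got
        hit = (starts < query.end) & (ends > query.start)
        return [ivs[i] for i in np.nonzero(hit)[0]]

    def any_overlap(self, query: Interval) -> bool:
        got = self._by_chrom.get(query.chrom)
        if got is None:
            return False
        starts, ends, _ = got
        return bool(np.any((starts < query.end) & (ends > query.start)))

    def nearest_distance(self, query: Interval) -> int | None:
        """Distance in bp to the nearest interval on the same chromosome.

        Zero when overlapping; ``None`` when the chromosome has no entries.
        """
        got = self._by_chrom.get(query.chrom)
        if got is None:
            return None
        starts, ends, _ = got
        gap_right = starts - query.end  # positive when interval is downstream
        gap_left = query.start - ends
        dist = np.maximum(np.maximum(gap_right, gap_left), 0)
        return int(dist.min())


def merge_intervals(intervals: Sequence[Interval], gap: int = 0) -> list[Interval]:
    """Union of intervals, joining neighbours separated by ``<= gap`` bp."""
    out: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(chrom, cur_start, cur_end))
    return out


def total_covered_bp(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in merge_intervals(list(intervals)))
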