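"""Sorted, disjoint genomic interval sets with union/intersection arithmetic.

Intervals are 0-based half-open ``(chrom, start, end)`` triples, the
coordinate convention used throughout the package (BED-native).  Interval
sets back every region-level result: selective sweeps, BSA candidate
regions, QTL intersections, and the chromosome-1 divergent block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def interval_span(start: int, end: int) -> int:
    """Length in bp of a half-open breakpoint pair (end - start)."""
    if end < start:
        raise ValueError("end < start")
    return end - start


class IntervalSet:
    """Normalized (sorted, disjoint, merged) set of genomic intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int] | Interval] = ()):
        raw = [
            iv if isinstance(iv, Interval) else Interval(*iv) for iv in intervals
        ]
        self.intervals: list[Interval] = self._normalize(raw)

    @staticmethod
    def _normalize(raw: list[Interval]) -> list[Interval]:
        out: list[Interval] = []
        for iv in sorted(raw, key=lambda v: (v.chrom, v.start, v.end)):
            if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
                prev = out[-1]
                if iv.end > prev.end:
                    out[-1] = Interval(prev.chrom, prev.start, iv.end)
            else:
                out.append(iv)
        return out

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self.intervals)} intervals, {self.total_bp} bp)"

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self.intervals) + list(other.intervals))

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out: list[Interval] = []
        for a in self.intervals:
            for b in other.intervals:
                if a.chrom != b.chrom:
                    continue
                s, e = max(a.start, b.start), min(a.end, b.end)
                if e > s:
                    out.append(Interval(a.chrom, s, e))
        return IntervalSet(out)

    def intersect_bp(self, other: "IntervalSet") -> int:
        return self.intersection(other).total_bp

    def contains(self, chrom: str, pos: int) -> bool:
        return any(
            iv.chrom == chrom and iv.start <= pos < iv.end for iv in self.intervals
        )
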