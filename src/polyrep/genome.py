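"""Genome model and interval/point arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention —
on a genome declared up front as an ordered set of named chromosomes with
lengths.  Two container types carry every region-valued quantity in the
package:

* :class:`IntervalSet` — per-chromosome sorted, non-overlapping intervals
  (underreplicated regions, TADs, low-ORC-density domains, ...).
* :class:`PointSet` — per-chromosome sorted positions (ChIP peak summits).

The operations here (merge within a gap, base-exact intersection, complement,
coverage) are the primitives every analysis stage is built on, so they are
implemented directly on sorted integer arrays and are cross-checked against
per-base bitmap oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GInterval",
    "IntervalSet",
    "PointSet",
    "merge_within",
    "intersect",
    "complement",
]


class GInterval(NamedTuple):
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint position; for odd widths the half-base is floored."""
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths, plus an optional pericentric mask.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in bp (insertion order is the
        genome order).
    pericentric
        Optional :class:`IntervalSet` flagging pericentric heterochromatin;
        regions overlapping it can be excluded from geometry summaries.
    """

    chromosomes: Mapping[str, int]
    pericentric: "IntervalSet | None" = None

    def __post_init__(self) -> None:
        names = list(self.chromosomes)
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.pericentric is not None:
            for chrom, arr in self.pericentric.items():
                if chrom not in self.chromosomes:
                    raise ValueError(f"pericentric mask names unknown chromosome {chrom!r}")
                if len(arr) and arr[-1, 1] > self.chromosomes[chrom]:
                    raise ValueError(f"pericentric mask exceeds chromosome {chrom!r}")

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def check_interval(self, iv: GInterval) -> None:
        length = self.length_of(iv.chrom)
        if not (0 <= iv.start < iv.end <= length):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome "
                f"bounds [0, {length})"
            )


def _as_array(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    arr = np.asarray(list(intervals), dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return arr.reshape(-1, 2)


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Sort and union-merge strictly overlapping intervals.

    Book-ended (touching) intervals are kept distinct: adjacency is
    meaningful (e.g. TADs sharing a boundary); collapsing it is the job of
    ``merge_within(gap=0)``.
    """
    if len(arr) == 0:
        return arr
    if np.any(arr[:, 0] >= arr[:, 1]):
        bad = arr[arr[:, 0] >= arr[:, 1]][0]
        raise ValueError(f"empty or inverted interval [{bad[0]}, {bad[1]})")
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    keep_starts = [arr[0, 0]]
    keep_ends = [arr[0, 1]]
    for s, e in arr[1:]:
        if s < keep_ends[-1]:
            keep_ends[-1] = max(keep_ends[-1], e)
        else:
            keep_starts.append(s)
            keep_ends.append(e)
    return np.column_stack([keep_starts, keep_ends]).astype(np.int64)


class IntervalSet:
    """Per-chromosome sorted, non-overlapping half-open intervals.

    Construction normalizes: intervals are sorted and any overlapping or
    book-ended (touching) pair is unioned, so the invariant "sorted and
    pairwise non-overlapping with positive gaps" always holds.
    """

    def __init__(self, data: Mapping[str, np.ndarray] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if data:
            for chrom, arr in data.items():
                arr = _normalize(_as_array(arr))
                if len(arr):
                    self._data[chrom] = arr

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        return cls(by_chrom)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GInterval]) -> "IntervalSet":
        return cls.from_records((iv.chrom, iv.start, iv.end) for iv in intervals)

    # -- container protocol -------------------------------------------------
    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(sorted(self._data.items()))

    def chroms(self) -> list[str]:
        return sorted(self._data)

    def get(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return int(sum(len(a) for a in self._data.values()))

    def __iter__(self) -> Iterator[GInterval]:
        for chrom, arr in self.items():
            for s, e in arr:
                yield GInterval(chrom, int(s), int(e))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._data)} chromosomes)"

    # -- measures ------------------------------------------------------------
    @property
    def coverage_bp(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def widths(self) -> np.ndarray:
        if not self._data:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([a[:, 1] - a[:, 0] for _, a in self.items()])

    def midpoints(self) -> list[tuple[str, int]]:
        return [(iv.chrom, iv.midpoint) for iv in self]

    def to_records(self) -> list[tuple[str, int, int]]:
        return [(iv.chrom, iv.start, iv.end) for iv in self]

    # -- set algebra ---------------------------------------------------------
    def check_within(self, genome: GenomeLayout) -> None:
        for iv in self:
            genome.check_interval(iv)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom in set(self._data) & set(other._data):
            a, b = self._data[chrom], other._data[chrom]
            pieces = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    pieces.append((s, e))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if pieces:
                out[chrom] = np.asarray(pieces, dtype=np.int64)
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom in set(self._data) | set(other._data):
            out[chrom] = np.vstack([self.get(chrom), other.get(chrom)])
        return IntervalSet(out)

    def complement(self, genome: GenomeLayout) -> "IntervalSet":
        self.check_within(genome)
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, length in genome.chromosomes.items():
            arr = self.get(chrom)
            gaps: list[tuple[int, int]] = []
            prev = 0
            for s, e in arr:
                if s > prev:
                    gaps.append((prev, int(s)))
                prev = int(e)
            if prev < length:
                gaps.append((prev, length))
            if gaps:
                out[chrom] = np.asarray(gaps, dtype=np.int64)
        return IntervalSet(out)

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: does each position fall inside the set?"""
        arr = self.get(chrom)
        positions = np.asarray(positions)
        if len(arr) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < arr[idx[ok], 1]
        return out


class PointSet:
    """Per-chromosome sorted positions (peak summits)."""

    def __init__(self, data: Mapping[str, Sequence[int] | np.ndarray] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if data:
            for chrom, pos in data.items():
                arr = np.sort(np.asarray(pos, dtype=np.int64))
                if arr.size:
                    self._data[chrom] = arr

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int]]) -> "PointSet":
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in records:
            by_chrom.setdefault(chrom, []).append(int(pos))
        return cls(by_chrom)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(sorted(self._data.items()))

    def chroms(self) -> list[str]:
        return sorted(self._data)

    def get(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return int(sum(len(a) for a in self._data.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PointSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:
        return f"PointSet({len(self)} points on {len(self._data)} chromosomes)"

    def count_in(self, intervals: IntervalSet) -> int:
        """Total points falling inside the interval set."""
        total = 0
        for chrom, arr in intervals.items():
            pts = self.get(chrom)
            if len(pts):
                total += int(
                    (np.searchsorted(pts, arr[:, 1]) - np.searchsorted(pts, arr[:, 0])).sum()
                )
        return total

    def counts_per_interval(self, intervals: IntervalSet) -> np.ndarray:
        out = []
        for chrom, arr in intervals.items():
            pts = self.get(chrom)
            out.append(np.searchsorted(pts, arr[:, 1]) - np.searchsorted(pts, arr[:, 0]))
        if not out:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(out)


def merge_within(obj: IntervalSet | PointSet, gap: int) -> IntervalSet:
    """Merge intervals (or cluster points) separated by at most ``gap`` bp.

    Two intervals ``[a,b)`` and ``[c,d)`` with ``c >= b`` merge when
    ``c - b <= gap``; two summits merge when their distance is ``<= gap``
    (single linkage, so clusters chain).  A cluster of points becomes the
    interval from its first summit to one past its last (a singleton summit
    yields a 1-bp interval).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    out: dict[str, np.ndarray] = {}
    if isinstance(obj, PointSet):
        for chrom, pts in obj.items():
            breaks = np.flatnonzero(np.diff(pts) > gap)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(pts) - 1]])
            out[chrom] = np.column_stack([pts[starts], pts[ends] + 1])
        return IntervalSet(out)
    for chrom, arr in obj.items():
        if len(arr) == 0:
            continue
        gaps = arr[1:, 0] - arr[:-1, 1]
        breaks = np.flatnonzero(gaps > gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(arr) - 1]])
        out[chrom] = np.column_stack([arr[starts, 0], arr[ends, 1]])
    return IntervalSet(out)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-exact intersection of two interval sets."""
    return a.intersect(b)


def complement(s: IntervalSet, genome: GenomeLayout) -> IntervalSet:
    """Genome minus the set — e.g. the fully replicated fraction given URs."""
    return s.complement(genome)
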