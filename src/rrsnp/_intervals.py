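"""Merged-interval sets with fast point/overlap queries.

Coordinates are 0-based half-open throughout. Intervals are merged at
construction so starts/ends are strictly increasing and disjoint, which
lets every query reduce to a pair of ``searchsorted`` calls.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]


class IntervalSet:
    """An immutable set of disjoint, sorted half-open intervals on one sequence."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        merged: List[List[int]] = []
        for start, end in sorted((int(s), int(e)) for s, e in intervals):
            if end <= start:
                raise ValueError(f"invalid interval [{start}, {end})")
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        self.starts = np.array([m[0] for m in merged], dtype=np.int64)
        self.ends = np.array([m[1] for m in merged], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    @property
    def total_bases(self) -> int:
        return int((self.ends - self.starts).sum())

    def covers(self, pos: int) -> bool:
        """True when ``pos`` lies inside some interval."""
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        return bool(i >= 0 and pos < self.ends[i])

    def overlap_bases(self, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by the set."""
        if end <= start or len(self.starts) == 0:
            return 0
        lo = int(np.searchsorted(self.ends, start, side="right"))
        hi = int(np.searchsorted(self.starts, end, side="left"))
        total = 0
        for i in range(lo, hi):
            total += min(end, int(self.ends[i])) - max(start, int(self.starts[i]))
        return total

    def overlaps(self, start: int, end: int) -> bool:
        if end <= start or len(self.starts) == 0:
            return False
        lo = int(np.searchsorted(self.ends, start, side="right"))
        return lo < len(self.starts) and int(self.starts[lo]) < end


class GenomeIntervals:
    """Per-chromosome :class:`IntervalSet` collection (e.g. a repeat mask)."""

    def __init__(self, by_chrom: Dict[str, Iterable[Interval]] | None = None):
        self._sets: Dict[str, IntervalSet] = {}
        for chrom, ivals in (by_chrom or {}).items():
            self._sets[chrom] = ivals if isinstance(ivals, IntervalSet) else IntervalSet(ivals)

    @classmethod
    def empty(cls) -> "GenomeIntervals":
        return cls({})

    def get(self, chrom: str) -> IntervalSet:
        return self._sets.get(chrom, _EMPTY)

    def chroms(self) -> Sequence[str]:
        return list(self._sets)

    def covers(self, chrom: str, pos: int) -> bool:
        return self.get(chrom).covers(pos)

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        return self.get(chrom).overlap_bases(start, end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.get(chrom).overlaps(start, end)

    @property
    def total_bases(self) -> int:
        return sum(s.total_bases for s in self._sets.values())

    def to_bed_rows(self):
        for chrom in self._sets:
            for start, end in self._sets[chrom]:
                yield chrom, start, end


_EMPTY = IntervalSet()
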