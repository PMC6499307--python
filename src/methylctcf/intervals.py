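"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)``. These two classes are
the spine of every peak, site, island, TAD and annotation container in the
package; they deliberately cover only the operations the pipeline needs
(overlap tests, reciprocal overlap, merging, centers, distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Intersection length divided by the *longer* of the two intervals."""
        inter = self.intersection_length(other)
        return inter / max(len(self), len(other))

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval":
        if not self.overlaps(other):
            raise ValueError("intervals do not overlap")
        return replace(self, start=max(self.start, other.start), end=min(self.end, other.end))


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Backed by a list plus lazily built per-chromosome sorted arrays for fast
    overlap counting.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._intervals: list[GenomicInterval] = list(intervals)
        self._index: Optional[dict[str, tuple[np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def add(self, iv: GenomicInterval) -> None:
        self._intervals.append(iv)
        self._index = None

    # -- indexing -----------------------------------------------------------

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._index is None:
            idx: dict[str, list[tuple[int, int]]] = {}
            for iv in self._intervals:
                idx.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._index = {}
            for chrom, pairs in idx.items():
                pairs.sort()
                arr = np.asarray(pairs, dtype=np.int64)
                self._index[chrom] = (arr[:, 0], arr[:, 1])
        return self._index

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        return [iv for iv in self._intervals if iv.overlaps(query)]

    def any_overlap(self, query: GenomicInterval) -> bool:
        idx = self._build_index()
        if query.chrom not in idx:
            return False
        starts, ends = idx[query.chrom]
        # candidate intervals: start < query.end and end > query.start
        i = np.searchsorted(starts, query.end, side="left")
        return bool(np.any(ends[:i] > query.start))

    def nearest_distance(self, chrom: str, pos: int) -> float:
        """Distance from ``pos`` to the closest interval (0 if inside)."""
        idx = self._build_index()
        if chrom not in idx:
            return np.inf
        starts, ends = idx[chrom]
        inside = (starts <= pos) & (ends > pos)
        if inside.any():
            return 0.0
        d = np.minimum(np.abs(starts - pos), np.abs(ends - 1 - pos))
        return float(d.min())

    # -- set-level operations ----------------------------------------------

    def merged(self, gap: int = 0) -> "IntervalSet":
        """Union of intervals, merging runs closer than ``gap`` bp apart."""
        out: list[GenomicInterval] = []
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e + gap:
                    cur_e = max(cur_e, iv.end)
                else:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            out.append(GenomicInterval(chrom, cur_s, cur_e))
        return IntervalSet(out)

    def coverage_bp(self) -> int:
        return sum(len(iv) for iv in self.merged())

    def count_overlapping(self, features: "IntervalSet") -> int:
        """Number of elements of *self* overlapping >= 1 bp of *features*."""
        return sum(1 for iv in self._intervals if features.any_overlap(iv))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self._intervals],
                "start": [iv.start for iv in self._intervals],
                "end": [iv.end for iv in self._intervals],
                "name": [iv.name if iv.name is not None else "." for iv in self._intervals],
                "score": [iv.score if iv.score is not None else 0.0 for iv in self._intervals],
                "strand": [iv.strand for iv in self._intervals],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IntervalSet":
        ivs = []
        for row in df.itertuples(index=False):
            name = getattr(row, "name", None)
            score = getattr(row, "score", None)
            strand = getattr(row, "strand", ".")
            ivs.append(
                GenomicInterval(
                    str(row.chrom),
                    int(row.start),
                    int(row.end),
                    strand=str(strand) if strand in ("+", "-") else ".",
                    name=None if name in (".", None) else str(name),
                    score=None if score is None else float(score),
                )
            )
        return cls(ivs)
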