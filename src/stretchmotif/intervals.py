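"""Genomic interval primitives.

All coordinates in this package are BED-style: 0-based, half-open
``[start, end)``. SNP positions are represented as length-1 intervals
``[pos, pos + 1)``. Converters for 1-based inclusive records are provided
so external catalogs can be ingested without ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomeInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    @classmethod
    def from_one_based_inclusive(
        cls, chrom: str, start1: int, end1: int, strand: str = "."
    ) -> "GenomeInterval":
        """Convert a 1-based inclusive record (e.g. catalog rows) to internal form."""
        return cls(chrom, start1 - 1, end1, strand)

    def to_one_based_inclusive(self) -> tuple[str, int, int]:
        return self.chrom, self.start + 1, self.end


@dataclass(frozen=True)
class NarrowPeak:
    """An ENCODE narrowPeak record with its summit offset (column 10)."""

    interval: GenomeInterval
    summit_offset: int
    signal: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < self.interval.length):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position (0-based)."""
        return self.interval.start + self.summit_offset


def intervals_to_frame(intervals: Iterable[GenomeInterval]) -> pd.DataFrame:
    ivs = list(intervals)
    return pd.DataFrame(
        {
            "Chromosome": [i.chrom for i in ivs],
            "Start": np.asarray([i.start for i in ivs], dtype=np.int64),
            "End": np.asarray([i.end for i in ivs], dtype=np.int64),
        }
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomeInterval]:
    return [
        GenomeInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["Chromosome"], df["Start"], df["End"])
    ]


def _ranges(intervals: Sequence[GenomeInterval]) -> pr.PyRanges:
    return pr.PyRanges(intervals_to_frame(intervals))


def merge_intervals(
    intervals: Sequence[GenomeInterval], gap: int = 0
) -> list[GenomeInterval]:
    """Merge intervals whose gap is <= ``gap`` into disjoint sorted intervals.

    ``gap=0`` merges overlapping and bookended intervals (``mergeBed`` default);
    ``gap=d`` reproduces ``mergeBed -d d`` semantics (a gap of exactly d merges).
    """
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    out: list[GenomeInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= gap:
            if iv.end > out[-1].end:
                out[-1] = GenomeInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomeInterval(iv.chrom, iv.start, iv.end))
    return out


def intersect_intervals(
    a: Sequence[GenomeInterval], b: Sequence[GenomeInterval]
) -> list[GenomeInterval]:
    """Base-level intersection of two interval sets, merged and sorted."""
    if not a or not b:
        return []
    res = _ranges(merge_intervals(a)).intersect(_ranges(merge_intervals(b)))
    df = res.df if hasattr(res, "df") else pd.DataFrame(res)
    if df.empty:
        return []
    return sorted(frame_to_intervals(df), key=lambda i: (i.chrom, i.start))


def subtract_intervals(
    a: Sequence[GenomeInterval], b: Sequence[GenomeInterval]
) -> list[GenomeInterval]:
    """Base-level subtraction a \\ b, merged and sorted."""
    if not a:
        return []
    if not b:
        return merge_intervals(a)
    res = _ranges(merge_intervals(a)).subtract(_ranges(merge_intervals(b)))
    df = res.df if hasattr(res, "df") else pd.DataFrame(res)
    if df.empty:
        return []
    return sorted(frame_to_intervals(df), key=lambda i: (i.chrom, i.start))


def total_length(intervals: Iterable[GenomeInterval]) -> int:
    return sum(len(i) for i in intervals)


class IntervalIndex:
    """Sorted per-chromosome arrays for fast point-in-intervals queries.

    Intervals must be disjoint within a chromosome (merge first if not).
    """

    def __init__(self, intervals: Sequence[GenomeInterval]):
        merged = merge_intervals(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomeInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.asarray([i.start for i in ivs], dtype=np.int64)
            self._ends[chrom] = np.asarray([i.end for i in ivs], dtype=np.int64)

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        return k >= 0 and pos < self._ends[chrom][k]

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.zeros(len(positions), dtype=bool)
        k = np.searchsorted(starts, positions, side="right") - 1
        ok = k >= 0
        hit = np.zeros(len(positions), dtype=bool)
        hit[ok] = positions[ok] < self._ends[chrom][k[ok]]
        return hit
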