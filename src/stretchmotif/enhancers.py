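"""Stretch/typical enhancer classification and DHS compartments.

A stretch enhancer (SE) is a run of contiguous enhancer-state segments at
least 3,000 bp long; a typical enhancer (TE) is such a run of at most 800 bp
(the median enhancer length). Runs of intermediate length are neither and are
excluded from all downstream compartments. Contiguity means bookended
segments (gap 0): any intervening non-enhancer segment, however short,
breaks a run.

Each enhancer class is further partitioned against DNase hypersensitive
sites into DHS and non-DHS compartments; the four compartments tile the
enhancer classes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import (
    GenomeInterval,
    NarrowPeak,
    intersect_intervals,
    subtract_intervals,
    total_length,
)

SE_MIN_LENGTH = 3000
TE_MAX_LENGTH = 800
CLASSES = ("SE", "TE", "OTHER")
COMPARTMENTS = ("SE_DHS", "SE_nonDHS", "TE_DHS", "TE_nonDHS")
DEFAULT_ENHANCER_SUBSTRING = "Enhancer"


@dataclass
class EnhancerSet:
    """Classified enhancer runs for one cell type."""

    cell: str
    enhancers: list[tuple[GenomeInterval, str]]

    def intervals(self, cls: str) -> list[GenomeInterval]:
        return [iv for iv, c in self.enhancers if c == cls]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for _, c in self.enhancers:
            out[c] += 1
        return out


@dataclass
class CompartmentSequences:
    """Intervals and extracted sequences of one compartment of one cell."""

    cell: str
    compartment: str
    intervals: list[GenomeInterval]
    sequences: list[str]

    @property
    def total_nucleotides(self) -> int:
        return total_length(self.intervals)

    def as_mapping(self) -> dict[str, str]:
        """Sequences keyed by their genomic coordinates."""
        return {
            f"{iv.chrom}:{iv.start}-{iv.end}": seq
            for iv, seq in zip(self.intervals, self.sequences)
        }


def classify_run(length: int) -> str:
    if length >= SE_MIN_LENGTH:
        return "SE"
    if length <= TE_MAX_LENGTH:
        return "TE"
    return "OTHER"


def is_enhancer_state(
    state: str, enhancer_state_names: Iterable[str] | None = None
) -> bool:
    if enhancer_state_names is None:
        return DEFAULT_ENHANCER_SUBSTRING.lower() in state.lower()
    return state in set(enhancer_state_names)


def classify_enhancers(
    segmentation: Sequence[tuple[GenomeInterval, Sequence[str]]],
    enhancer_state_names: Iterable[str] | None = None,
    cell: str = "",
) -> EnhancerSet:
    """Merge contiguous enhancer-state segments into runs and classify them.

    ``segmentation`` is a list of (interval, labels) as returned by
    :func:`stretchmotif.io.read_bed`; the first label is the chromatin-state
    name. ``enhancer_state_names`` lists the states counted as enhancer;
    when None, any state whose name contains "Enhancer" (case-insensitive)
    qualifies. Segments are merged only when bookended (gap 0).
    """
    recs = sorted(segmentation, key=lambda r: (r[0].chrom, r[0].start))
    prev: GenomeInterval | None = None
    for iv, _ in recs:
        if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
            raise ValueError(
                f"overlapping segmentation intervals at {iv.chrom}:{iv.start}"
            )
        prev = iv
    runs: list[GenomeInterval] = []
    current: GenomeInterval | None = None
    for iv, labels in recs:
        state = labels[0] if labels else ""
        if is_enhancer_state(state, enhancer_state_names):
            if (
                current is not None
                and current.chrom == iv.chrom
                and current.end == iv.start
            ):
                current = GenomeInterval(current.chrom, current.start, iv.end)
            else:
                if current is not None:
                    runs.append(current)
                current = GenomeInterval(iv.chrom, iv.start, iv.end)
        else:
            # non-enhancer segment: close any open run; a gap in coordinates
            # between consecutive records closes runs implicitly above
            if current is not None:
                runs.append(current)
                current = None
    if current is not None:
        runs.append(current)
    enhancers = [(run, classify_run(len(run))) for run in runs]
    return EnhancerSet(cell=cell, enhancers=enhancers)


def _extract(genome: Mapping[str, str], ivs: Sequence[GenomeInterval]) -> list[str]:
    out = []
    for iv in ivs:
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
        out.append(genome[iv.chrom][iv.start : iv.end])
    return out


def partition_compartments(
    enhancer_set: EnhancerSet,
    dhs_peaks: Sequence[NarrowPeak],
    genome: Mapping[str, str],
) -> dict[str, CompartmentSequences]:
    """Split SE and TE intervals into DHS and non-DHS compartments.

    DHS compartments are base-level intersections of enhancer intervals with
    peak intervals (clipped to the enhancer); non-DHS compartments are the
    complements within the enhancer class. Within each class, the two
    compartments are disjoint and their union is the class.
    """
    peak_ivs = [p.interval for p in dhs_peaks]
    out: dict[str, CompartmentSequences] = {}
    for cls in ("SE", "TE"):
        cls_ivs = enhancer_set.intervals(cls)
        in_dhs = intersect_intervals(cls_ivs, peak_ivs)
        out_dhs = subtract_intervals(cls_ivs, peak_ivs)
        for name, ivs in ((f"{cls}_DHS", in_dhs), (f"{cls}_nonDHS", out_dhs)):
            out[name] = CompartmentSequences(
                cell=enhancer_set.cell,
                compartment=name,
                intervals=ivs,
                sequences=_extract(genome, ivs),
            )
    return out


def _summits_in_class(
    enhancer_set: EnhancerSet, dhs_peaks: Sequence[NarrowPeak], cls: str
) -> dict[str, np.ndarray]:
    by_chrom_ivs: dict[str, list[GenomeInterval]] = {}
    for iv in enhancer_set.intervals(cls):
        by_chrom_ivs.setdefault(iv.chrom, []).append(iv)
    summits: dict[str, list[int]] = {}
    for p in dhs_peaks:
        chrom = p.interval.chrom
        pos = p.summit
        if any(iv.contains(pos) for iv in by_chrom_ivs.get(chrom, [])):
            summits.setdefault(chrom, []).append(pos)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in summits.items()}


def summit_spacing(
    enhancer_set: EnhancerSet, dhs_peaks: Sequence[NarrowPeak], cls: str
) -> list[int]:
    """Distance from each in-class DHS summit to the nearest other one.

    Neighbors are sought on the same chromosome; a chromosome with a single
    in-class summit contributes nothing.
    """
    out: list[int] = []
    for positions in _summits_in_class(enhancer_set, dhs_peaks, cls).values():
        if len(positions) < 2:
            continue
        diffs = np.diff(positions)
        left = np.concatenate([[np.iinfo(np.int64).max], diffs])
        right = np.concatenate([diffs, [np.iinfo(np.int64).max]])
        out.extend(np.minimum(left, right).tolist())
    return out


def dhs_lengths_by_class(
    enhancer_set: EnhancerSet, dhs_peaks: Sequence[NarrowPeak]
) -> dict[str, list[int]]:
    """Peak lengths grouped by the enhancer class containing the peak summit.

    A peak belongs to the class whose interval contains its summit; peaks
    whose summit falls in no SE or TE are excluded.
    """
    by_class: dict[str, list[int]] = {"SE": [], "TE": []}
    lookup: dict[str, list[tuple[GenomeInterval, str]]] = {}
    for iv, cls in enhancer_set.enhancers:
        if cls in ("SE", "TE"):
            lookup.setdefault(iv.chrom, []).append((iv, cls))
    for p in dhs_peaks:
        pos = p.summit
        for iv, cls in lookup.get(p.interval.chrom, []):
            if iv.contains(pos):
                by_class[cls].append(p.interval.length)
                break
    return by_class


def compare_distributions(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two samples -> (statistic, p-value)."""
    res = stats.ranksums(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
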