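"""Summit-centered aggregate profiles, motif-density genome tracks, and
footprint interval post-processing.

Aggregate profiles average a quantity (signal, dinucleotide frequency, or
motif density) in fixed bins relative to DNase-seq peak summits, by default
+/-1,500 bp at 10 bp bins (300 bins). Bin ``k`` covers offsets
``[k*bin - flank, k*bin - flank + bin)`` from the summit; the central bin is
the one containing offset 0.

Motif-density tracks count, for sliding windows along the genome (150 bp at
10 bp steps), a maximal non-overlapping subset of pooled motif sites whose
start lies in the window, and are written as bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeInterval, merge_intervals
from .motifs import PWM, encode_sequence, window_scores

DEFAULT_FLANK = 1500
DEFAULT_BIN = 10


@dataclass
class AggregateProfile:
    """Binned mean signal/frequency/density relative to summits."""

    offsets: np.ndarray  # bin start offsets relative to summit
    values: np.ndarray
    n_sites: int
    bin_size: int

    @property
    def n_bins(self) -> int:
        return len(self.offsets)

    @property
    def centers(self) -> np.ndarray:
        return self.offsets + self.bin_size / 2

    @property
    def central_bin(self) -> int:
        """Index of the bin containing offset 0."""
        return int(np.searchsorted(self.offsets, 0, side="right") - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "value": self.values, "n_sites": self.n_sites}
        )

    def __add__(self, other: "AggregateProfile") -> "AggregateProfile":
        if not np.array_equal(self.offsets, other.offsets):
            raise ValueError("profiles have different binning")
        return AggregateProfile(
            self.offsets, self.values + other.values, self.n_sites, self.bin_size
        )


@dataclass
class DensityTrack:
    """Sliding-window counts of non-overlapping motif sites."""

    chrom: str
    starts: np.ndarray  # window start positions
    counts: np.ndarray
    window: int
    step: int

    def to_bedgraph_rows(self) -> list[tuple[str, int, int, float]]:
        return [
            (self.chrom, int(s), int(s) + self.step, float(c))
            for s, c in zip(self.starts, self.counts)
        ]


class SignalTrack:
    """Dense per-base signal from a bedGraph table; missing positions are 0."""

    def __init__(self, bedgraph: pd.DataFrame, chrom_sizes: Mapping[str, int] | None = None):
        self._arrays: dict[str, np.ndarray] = {}
        sizes: dict[str, int] = dict(chrom_sizes or {})
        for chrom, grp in bedgraph.groupby("chrom"):
            size = max(int(grp["end"].max()), sizes.get(str(chrom), 0))
            arr = np.zeros(size)
            for s, e, v in zip(grp["start"], grp["end"], grp["value"]):
                arr[int(s) : int(e)] = v
            self._arrays[str(chrom)] = arr

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray]) -> "SignalTrack":
        obj = cls.__new__(cls)
        obj._arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}
        return obj

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values in [start, end); zeros outside the chromosome."""
        out = np.zeros(end - start)
        arr = self._arrays.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


def _bin_offsets(flank: int, bin_size: int) -> np.ndarray:
    return np.arange(-flank, flank, bin_size)


def aggregate_signal(
    summits: Sequence[tuple[str, int]],
    signal_track: SignalTrack,
    flank: int = DEFAULT_FLANK,
    bin_size: int = DEFAULT_BIN,
) -> AggregateProfile:
    """Mean per-bin summed signal around summits.

    Each bin's value is the mean over summits of the signal summed within the
    bin; windows truncated by a chromosome edge contribute zeros beyond it.
    """
    if not summits:
        raise ValueError("aggregate_signal requires at least one summit")
    offsets = _bin_offsets(flank, bin_size)
    n_bins = len(offsets)
    acc = np.zeros(n_bins)
    for chrom, pos in summits:
        vals = signal_track.window(chrom, pos - flank, pos - flank + n_bins * bin_size)
        acc += vals.reshape(n_bins, bin_size).sum(axis=1)
    return AggregateProfile(offsets, acc / len(summits), len(summits), bin_size)


def aggregate_dinucleotide(
    summits: Sequence[tuple[str, int]],
    genome: Mapping[str, str],
    dinucleotide: str,
    flank: int = DEFAULT_FLANK,
    bin_size: int = DEFAULT_BIN,
) -> AggregateProfile:
    """Per-bin frequency of a dinucleotide around summits.

    A dinucleotide position is assigned to the bin containing its first base;
    overlapping occurrences all count. The frequency denominator counts
    positions whose two bases both lie inside the chromosome.
    """
    if len(dinucleotide) != 2:
        raise ValueError("dinucleotide must have length 2")
    dinucleotide = dinucleotide.upper()
    offsets = _bin_offsets(flank, bin_size)
    n_bins = len(offsets)
    hits = np.zeros(n_bins)
    totals = np.zeros(n_bins)
    d0, d1 = (encode_sequence(dinucleotide)[i] for i in range(2))
    span = n_bins * bin_size
    enc_cache: dict[str, np.ndarray] = {}
    for chrom, pos in summits:
        if chrom not in enc_cache:
            enc_cache[chrom] = encode_sequence(genome.get(chrom, ""))
        enc = enc_cache[chrom]
        start = pos - flank
        positions = np.arange(start, start + span)
        valid = (positions >= 0) & (positions + 2 <= len(enc))
        match = np.zeros(span, dtype=bool)
        vp = positions[valid]
        if len(vp):
            match[valid] = (enc[vp] == d0) & (enc[vp + 1] == d1)
        bins = np.repeat(np.arange(n_bins), bin_size)
        totals += np.bincount(bins[valid], minlength=n_bins)
        hits += np.bincount(bins[match], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, hits / totals, 0.0)
    return AggregateProfile(offsets, freq, len(summits), bin_size)


@dataclass(frozen=True)
class MotifSite:
    """One thresholded motif occurrence in genome coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    motif: str
    score_bits: float


def call_sites_fraction_threshold(
    pwm: PWM,
    chrom: str,
    sequence: str,
    seq_start: int = 0,
    llr_fraction: float = 0.40,
) -> list[MotifSite]:
    """Call motif sites scoring at least ``llr_fraction`` of the motif's
    maximum attainable log-odds score, on both strands.

    If the fractional threshold is negative it floors at 0 bits. The
    comparison allows a 1e-9-bit tolerance so that at llr_fraction = 1.0 an
    exact consensus match is never lost to summation-order rounding.
    """
    threshold = max(llr_fraction * pwm.max_score, 0.0) - 1e-9
    enc = encode_sequence(sequence)
    sites: list[MotifSite] = []
    for strand in "+-":
        scores = window_scores(pwm, enc, strand)
        for pos in np.nonzero(scores >= threshold)[0]:
            sites.append(
                MotifSite(
                    chrom=chrom,
                    start=seq_start + int(pos),
                    end=seq_start + int(pos) + pwm.width,
                    strand=strand,
                    motif=pwm.name,
                    score_bits=float(scores[pos]),
                )
            )
    return sites


def aggregate_motif_density(
    summits: Sequence[tuple[str, int]],
    motif_names: Sequence[str],
    pwms: Mapping[str, PWM],
    genome: Mapping[str, str],
    llr_fraction: float = 0.40,
    flank: int = DEFAULT_FLANK,
    bin_size: int = DEFAULT_BIN,
) -> AggregateProfile:
    """Summed per-motif site-density histograms around summits.

    For each motif, sites (site = window scoring >= llr_fraction * max score,
    either strand) are binned by their start offset relative to the summit and
    averaged over summits; the per-motif histograms are summed position-wise.
    """
    if not motif_names:
        raise ValueError("aggregate_motif_density requires a non-empty motif set")
    if not summits:
        raise ValueError("aggregate_motif_density requires at least one summit")
    offsets = _bin_offsets(flank, bin_size)
    n_bins = len(offsets)
    total = np.zeros(n_bins)
    for name in motif_names:
        pwm = pwms[name]
        counts = np.zeros(n_bins)
        for chrom, pos in summits:
            seq = genome.get(chrom, "")
            lo = max(pos - flank, 0)
            hi = min(pos + flank + pwm.width - 1, len(seq))
            if hi - lo < pwm.width:
                continue
            for site in call_sites_fraction_threshold(
                pwm, chrom, seq[lo:hi], seq_start=lo, llr_fraction=llr_fraction
            ):
                k = (site.start - (pos - flank)) // bin_size
                if 0 <= k < n_bins:
                    counts[k] += 1
        total += counts / len(summits)
    return AggregateProfile(offsets, total, len(summits), bin_size)


def _greedy_nonoverlapping(sites: Sequence[MotifSite]) -> int:
    """Count a maximal non-overlapping subset, greedy left-to-right by start
    (ties broken toward the higher score)."""
    chosen_end = -1
    count = 0
    for s in sorted(sites, key=lambda s: (s.start, -s.score_bits)):
        if s.start >= chosen_end:
            count += 1
            chosen_end = s.end
    return count


def motif_density_track(
    region: GenomeInterval,
    motif_names: Sequence[str],
    pwms: Mapping[str, PWM],
    genome: Mapping[str, str],
    window: int = 150,
    step: int = 10,
    llr_fraction: float = 0.40,
) -> DensityTrack:
    """Count non-overlapping pooled motif sites in sliding windows.

    A site belongs to the windows containing its start coordinate. Within
    each window a maximal non-overlapping subset is selected greedily
    left-to-right (ties toward the higher-scoring site).
    """
    if region.length < window:
        raise ValueError("region shorter than the window")
    seq = genome[region.chrom][region.start : region.end]
    sites: list[MotifSite] = []
    for name in motif_names:
        sites.extend(
            call_sites_fraction_threshold(
                pwms[name], region.chrom, seq, region.start, llr_fraction
            )
        )
    sites.sort(key=lambda s: (s.start, -s.score_bits))
    starts_arr = np.asarray([s.start for s in sites], dtype=np.int64)
    win_starts = np.arange(region.start, region.end - window + 1, step)
    counts = np.zeros(len(win_starts), dtype=np.int64)
    for i, ws in enumerate(win_starts):
        lo = int(np.searchsorted(starts_arr, ws, side="left"))
        hi = int(np.searchsorted(starts_arr, ws + window, side="left"))
        if hi > lo:
            counts[i] = _greedy_nonoverlapping(sites[lo:hi])
    return DensityTrack(region.chrom, win_starts, counts, window, step)


def postprocess_footprints(
    footprints: Sequence[GenomeInterval],
    extend: int = 5,
    merge_distance: int = 10,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomeInterval]:
    """Extend footprint intervals on both ends and merge nearby ones.

    Mirrors ``mergeBed -d``: intervals separated by a gap of at most
    ``merge_distance`` (inclusive) are merged. Extension clips at 0 and, when
    chromosome sizes are given, at the chromosome end. Output is sorted and
    disjoint; a second pass with the same parameters and ``extend=0`` is a
    no-op.
    """
    grown = []
    sizes = dict(chrom_sizes or {})
    for iv in footprints:
        start = max(iv.start - extend, 0)
        end = iv.end + extend
        if iv.chrom in sizes:
            end = min(end, sizes[iv.chrom])
        grown.append(GenomeInterval(iv.chrom, start, end))
    return merge_intervals(grown, gap=merge_distance)
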