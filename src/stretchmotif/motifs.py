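"""PWM scanning with exact score p-values, dinucleotide shuffling, and
shuffle-normalized motif enrichment.

The scanner scores every window of a sequence on both strands with a
log-odds position weight matrix and calls occurrences whose exact p-value
under an i.i.d. background does not exceed a threshold (default 1e-4).
P-values are computed from the full null distribution of the *discretized*
score (scores are rounded to a fixed granularity, default 1/1000 bit, before
the dynamic-programming convolution over columns); the discretized score is
the scanner's score definition, so hit calls and reported p-values are both
functions of it.

Enrichment of a motif in a sequence set is the ratio of occurrence counts in
the real sequences to occurrence counts in dinucleotide-shuffled copies of
the same sequences, a compositional control that preserves every
dinucleotide count (Altschul-Erickson Eulerian-path shuffle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import MemeMotifRecord

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
# encode A,C,G,T -> 0..3, anything else -> 4 (treated as N)
_ENC_TABLE = bytes(
    {65: 0, 67: 1, 71: 2, 84: 3}.get(c, 4) for c in range(256)
)
_N_PENALTY = np.int64(-(2**40))  # any window touching an N can never be a hit

DEFAULT_GRANULARITY = 1e-3  # bits
DEFAULT_PSEUDOCOUNT = 1e-3
DEFAULT_P_THRESHOLD = 1e-4


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer codes 0-3 (ACGT) / 4 (N or other)."""
    return np.frombuffer(seq.upper().encode().translate(_ENC_TABLE), dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq.upper()))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on one strand of one sequence."""

    motif: str
    sequence_id: str
    start: int
    end: int
    strand: str
    score_bits: float
    p_value: float


class ScoreDistribution:
    """Exact null distribution of the discretized log-odds score.

    Scores (bits) are divided by ``granularity`` and rounded to integers; the
    distribution of the integer score of a random k-mer drawn i.i.d. from the
    background is computed by convolving the four-point column distributions
    across the motif width. Tail probabilities are therefore exact for the
    discretized score.
    """

    def __init__(
        self, log_odds: np.ndarray, background: np.ndarray, granularity: float
    ):
        self.granularity = float(granularity)
        # scores below -64 bits (possible with zero-probability columns) are
        # floored: they can never be hits and keeping them finite bounds the
        # convolution support
        clipped = np.maximum(log_odds, -64.0)
        q = np.rint(clipped / granularity).astype(np.int64)  # w x 4
        self.int_scores = q
        lo = int(q.min(axis=1).sum())
        hi = int(q.max(axis=1).sum())
        pmf = np.zeros(hi - lo + 1)
        # running support starts at the empty-prefix score 0
        offset = 0
        cur = np.array([1.0])
        for i in range(q.shape[0]):
            cmin, cmax = int(q[i].min()), int(q[i].max())
            nxt = np.zeros(len(cur) + (cmax - cmin))
            for b in range(4):
                shift = int(q[i, b]) - cmin
                nxt[shift : shift + len(cur)] += background[b] * cur
            cur = nxt
            offset += cmin
        pmf[offset - lo : offset - lo + len(cur)] = cur
        self.min_int = lo
        self.max_int = hi
        # tail[k] = P(score_int >= lo + k)
        self.tail = np.cumsum(pmf[::-1])[::-1]
        # guard against fp drift: tails are probabilities
        np.clip(self.tail, 0.0, 1.0, out=self.tail)

    def pvalue(self, int_score: np.ndarray | int) -> np.ndarray | float:
        """Upper-tail probability of one or more integer scores."""
        idx = np.clip(np.asarray(int_score) - self.min_int, 0, len(self.tail) - 1)
        out = self.tail[idx]
        scalar = np.isscalar(int_score)
        out = np.where(np.asarray(int_score) < self.min_int, 1.0, out)
        return float(out) if scalar else out

    def threshold_int(self, p_threshold: float) -> int:
        """Smallest integer score whose tail probability is <= p_threshold."""
        ok = np.nonzero(self.tail <= p_threshold)[0]
        if len(ok) == 0:
            return self.max_int + 1  # unattainable
        return self.min_int + int(ok[0])

    @property
    def min_attainable_pvalue(self) -> float:
        return float(self.tail[-1])


@dataclass
class PWM:
    """A position weight matrix with background and pseudocount regularization.

    The probability matrix is regularized as ``(P + eps) / (1 + 4 eps)`` so all
    entries are positive, then scored as ``log2(P' / background)`` per column.
    """

    name: str
    matrix: np.ndarray  # w x 4, columns A C G T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be w x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: background must sum to 1")
        if np.any(self.background <= 0):
            raise ValueError(f"PWM {self.name}: background must be positive")
        self._dists: dict[tuple[str, float], ScoreDistribution] = {}

    @classmethod
    def from_record(
        cls,
        record: MemeMotifRecord,
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        bg = record.background if background is None else np.asarray(background)
        return cls(record.name, record.matrix, bg, pseudocount)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def regularized(self) -> np.ndarray:
        return (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        """w x 4 log2 odds (bits) of the regularized matrix vs background."""
        return np.log2(self.regularized / self.background[None, :])

    @property
    def max_score(self) -> float:
        """Best attainable log-odds score in bits."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def information_content(self) -> float:
        """Total information content in bits relative to the background."""
        p = self.regularized
        return float((p * np.log2(p / self.background[None, :])).sum())

    def reverse_complement_log_odds(self) -> np.ndarray:
        """Log-odds matrix scoring the minus strand on plus-strand coordinates."""
        return self.log_odds[::-1, ::-1]

    def score_kmer(self, kmer: str) -> float:
        """Log-odds score (bits) of one k-mer; NaN if it contains N."""
        enc = encode_sequence(kmer)
        if len(enc) != self.width:
            raise ValueError(f"k-mer length {len(enc)} != motif width {self.width}")
        if np.any(enc >= 4):
            return float("nan")
        return float(self.log_odds[np.arange(self.width), enc].sum())

    def score_distribution(
        self, strand: str = "+", granularity: float = DEFAULT_GRANULARITY
    ) -> ScoreDistribution:
        """Null distribution of the discretized score on one strand.

        The minus-strand distribution differs from the plus-strand one only
        when the background is not complement-symmetric.
        """
        key = (strand, granularity)
        if key not in self._dists:
            lo = (
                self.log_odds if strand == "+" else self.reverse_complement_log_odds()
            )
            self._dists[key] = ScoreDistribution(lo, self.background, granularity)
        return self._dists[key]


def log_odds_score(pwm: PWM, kmer: str) -> float:
    """Module-level convenience wrapper around :meth:`PWM.score_kmer`."""
    return pwm.score_kmer(kmer)


def score_pvalue_table(
    pwm: PWM, granularity: float = DEFAULT_GRANULARITY
) -> dict[float, float]:
    """Map each attainable discretized score (bits) to its upper-tail p-value."""
    dist = pwm.score_distribution("+", granularity)
    # enumerate attainable integer scores by walking the tail support
    scores = np.arange(dist.min_int, dist.max_int + 1)
    return {
        float(s * granularity): float(dist.pvalue(int(s)))
        for s in scores
    }


def window_scores(pwm: PWM, encoded: np.ndarray, strand: str = "+") -> np.ndarray:
    """Real-valued log-odds score of every window on one strand.

    Windows containing N are assigned -inf.
    """
    w = pwm.width
    n_win = len(encoded) - w + 1
    if n_win <= 0:
        return np.zeros(0)
    lo = pwm.log_odds if strand == "+" else pwm.reverse_complement_log_odds()
    padded = np.concatenate([lo, np.full((w, 1), np.nan)], axis=1)
    scores = np.zeros(n_win)
    for i in range(w):
        scores += padded[i, encoded[i : i + n_win]]
    scores[np.isnan(scores)] = -np.inf
    return scores


def _window_int_scores(
    pwm: PWM, encoded: np.ndarray, dist: ScoreDistribution
) -> np.ndarray:
    w = pwm.width
    n_win = len(encoded) - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    q = np.concatenate(
        [dist.int_scores, np.full((w, 1), _N_PENALTY, dtype=np.int64)], axis=1
    )
    scores = np.zeros(n_win, dtype=np.int64)
    for i in range(w):
        scores += q[i, encoded[i : i + n_win]]
    return scores


def scan(
    pwm: PWM,
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Call motif occurrences on both strands of a set of sequences.

    Every window whose discretized-score p-value is <= ``p_threshold`` is
    reported; forward and reverse-complement hits are separate records with
    identical coordinates. Windows containing N are never called.
    """
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    hits: list[MotifHit] = []
    w = pwm.width
    dists = {s: pwm.score_distribution(s, granularity) for s in "+-"}
    thresholds = {s: dists[s].threshold_int(p_threshold) for s in "+-"}
    any_window = False
    for seq_id, seq in items:
        enc = encode_sequence(seq)
        if len(enc) >= w:
            any_window = True
        for strand in "+-":
            dist = dists[strand]
            ints = _window_int_scores(pwm, enc, dist)
            for pos in np.nonzero(ints >= thresholds[strand])[0]:
                s = int(ints[pos])
                hits.append(
                    MotifHit(
                        motif=pwm.name,
                        sequence_id=seq_id,
                        start=int(pos),
                        end=int(pos) + w,
                        strand=strand,
                        score_bits=s * granularity,
                        p_value=float(dist.pvalue(s)),
                    )
                )
    if not any_window:
        import warnings

        warnings.warn(
            f"motif {pwm.name} (width {w}) is longer than every input sequence",
            stacklevel=2,
        )
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


def count_hits(
    pwm: PWM,
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> int:
    return len(scan(pwm, sequences, p_threshold))


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def _shuffle_acgt_segment(seq: str, rng: np.random.Generator) -> str:
    """Eulerian-path shuffle of an N-free segment.

    Preserves the exact dinucleotide count vector and the first and last
    characters. Standard construction: pick, for every vertex except the last
    character, a random terminal edge; accept if the terminal edges form an
    arborescence into the last vertex; then permute each vertex's remaining
    edges and walk the Eulerian path.
    """
    if len(seq) < 2:
        return seq
    succs: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succs.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in succs if v != last]
    for _ in range(10_000):
        terminal = {v: succs[v][rng.integers(len(succs[v]))] for v in vertices}
        # every non-last vertex must reach `last` following terminal edges
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = terminal.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - terminates with probability 1
        raise RuntimeError("dinucleotide shuffle failed to find an arborescence")
    lists: dict[str, list[str]] = {}
    for v, edges in succs.items():
        rest = list(edges)
        if v != last:
            rest.remove(terminal[v])
        perm = rng.permutation(len(rest))
        ordered = [rest[i] for i in perm]
        if v != last:
            ordered.append(terminal[v])
        lists[v] = ordered
    out = [seq[0]]
    idx = {v: 0 for v in lists}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = lists[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_shuffle(sequence: str, seed: int | np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    The first and last characters are fixed. Runs of N split the sequence into
    maximal N-free segments that are shuffled independently; N positions stay
    where they are.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(sequence) < 2:
        return sequence
    seq = sequence.upper()
    out = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            out.append("N" * (j - i))
            i = j
        else:
            j = i
            while j < n and seq[j] != "N":
                j += 1
            out.append(_shuffle_acgt_segment(seq[i:j], rng))
            i = j
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """The 16-entry dinucleotide count vector (N-containing pairs excluded)."""
    counts = {a + b: 0 for a in BASES for b in BASES}
    for a, b in zip(seq, seq[1:]):
        if a in BASES and b in BASES:
            counts[a + b] += 1
    return counts


# ---------------------------------------------------------------------------
# Enrichment and repeat masking
# ---------------------------------------------------------------------------

def motif_enrichment(
    pwm: PWM,
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    seed: int | np.random.Generator,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_shuffles: int = 1,
) -> float:
    """Fold enrichment of a motif in a sequence set vs dinucleotide-shuffled
    controls: ``(hits_real + 1) / (hits_shuffled + 1)``.

    ``hits_shuffled`` is averaged over ``n_shuffles`` independent shuffled
    copies of each sequence. The +1 pseudocounts keep the ratio defined when
    the shuffled control has no hits.
    """
    items = list(sequences.items() if isinstance(sequences, Mapping) else sequences)
    if not items:
        raise ValueError("motif_enrichment requires a non-empty sequence set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits_real = len(scan(pwm, items, p_threshold))
    shuffled_counts = []
    for _ in range(n_shuffles):
        shuffled = [
            (sid, dinucleotide_shuffle(s, rng)) for sid, s in items
        ]
        shuffled_counts.append(len(scan(pwm, shuffled, p_threshold)))
    hits_shuffled = float(np.mean(shuffled_counts))
    return (hits_real + 1.0) / (hits_shuffled + 1.0)


SIMPLE_REPEATS = ("AAAAAAAA", "TTTTTTTT", "ACACACAC", "GTGTGTGT")


def mask_simple_repeats(sequence: str) -> str:
    """Replace A8/AC-repeat 8-mers (and reverse complements) with N.

    Overlapping occurrences are fully masked: every position covered by any
    occurrence of any of the four patterns becomes N.
    """
    seq = sequence.upper()
    mask = np.zeros(len(seq), dtype=bool)
    for pat in SIMPLE_REPEATS:
        start = seq.find(pat)
        while start != -1:
            mask[start : start + len(pat)] = True
            start = seq.find(pat, start + 1)
    if not mask.any():
        return sequence
    chars = list(sequence)
    for i in np.nonzero(mask)[0]:
        chars[i] = "N"
    return "".join(chars)
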