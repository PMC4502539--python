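"""Brute-force scanner oracle used by the unit and acceptance suites.

The oracle enumerates every k-mer, scores it column-by-column with the same
per-column rounding rule the score distribution documents (round each column
log-odds to 1/granularity of a bit, then sum the integers), and derives
p-values by summing the background probability of every k-mer whose integer
score is at least as large. Hit calling then checks each N-free window's
k-mer against the p-value table. Sharing the documented discretization rule
keeps the comparison exact instead of flapping at the p-threshold boundary.
"""

import numpy as np


def kmer_table(log_odds, background, granularity=1e-3):
    """(int_scores, pvalues) per k-mer index for one strand's matrix."""
    w = log_odds.shape[0]
    powers = 4 ** np.arange(w - 1, -1, -1)
    digits = (np.arange(4 ** w)[:, None] // powers) % 4
    q = np.rint(np.clip(log_odds, -64.0, None) / granularity).astype(np.int64)
    ints = q[np.arange(w), digits].sum(axis=1)
    probs = np.asarray(background)[digits].prod(axis=1)
    order = np.argsort(ints)[::-1]
    tail = np.cumsum(probs[order])
    sorted_desc = ints[order]
    # p(kmer) = total probability of k-mers with integer score >= its own
    pos = np.searchsorted(-sorted_desc, -ints, side="right") - 1
    pvals = tail[pos]
    return ints, np.clip(pvals, 0.0, 1.0)


def brute_force_hits(pwm, sequences, p_threshold, granularity=1e-3):
    """Set of (sequence_id, start, strand) hits plus their p-values."""
    from stretchmotif.motifs import encode_sequence

    w = pwm.width
    powers = 4 ** np.arange(w - 1, -1, -1)
    hits = {}
    for strand in "+-":
        lo = pwm.log_odds if strand == "+" else pwm.reverse_complement_log_odds()
        _, pvals = kmer_table(lo, pwm.background, granularity)
        for sid, seq in sequences.items():
            enc = encode_sequence(seq)
            for pos in range(len(seq) - w + 1):
                window = enc[pos:pos + w]
                if (window == 4).any():
                    continue
                k = int((window * powers).sum())
                if pvals[k] <= p_threshold:
                    hits[(sid, pos, strand)] = float(pvals[k])
    return hits
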