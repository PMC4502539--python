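import math

import numpy as np
import pytest

from conftest import make_pwm
from stretchmotif.motifs import (
    PWM,
    dinucleotide_counts,
    dinucleotide_shuffle,
    mask_simple_repeats,
    motif_enrichment,
    reverse_complement,
    scan,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScoring:
    def test_consensus_score_no_pseudocount(self):
        pwm = make_pwm("ACGT", pseudocount=0.0)
        # off-consensus entries are exactly 0, so log2 legitimately hits -inf
        with np.errstate(divide="ignore"):
            assert math.isclose(pwm.score_kmer("ACGT"), 8.0)

    def test_mismatch_score_with_regularization(self):
        # independent hand computation of the (P + eps)/(1 + 4 eps) rule
        eps = 1e-3
        pwm = make_pwm("ACGT", pseudocount=eps)
        hit = math.log2(((1.0 + eps) / (1.0 + 4 * eps)) / 0.25)
        miss = math.log2((eps / (1.0 + 4 * eps)) / 0.25)
        assert math.isclose(pwm.score_kmer("ACGA"), 3 * hit + miss, rel_tol=1e-12)

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("u", np.full((5, 4), 0.25), pseudocount=0.0)
        for kmer in ("AAAAA", "ACGTA", "TTTTT"):
            assert math.isclose(pwm.score_kmer(kmer), 0.0)

    def test_n_in_kmer_undefined(self):
        # undefined-score signal: callers skip the window
        assert math.isnan(make_pwm("ACGT").score_kmer("ACGN"))
        with pytest.raises(ValueError):
            make_pwm("ACGT").score_kmer("ACGTA")


class TestScoreDistribution:
    def test_width4_min_pvalue(self):
        # brute force over all 256 4-mers: unique consensus -> (1/4)^4
        dist = make_pwm("ACGT").score_distribution("+")
        assert math.isclose(dist.min_attainable_pvalue, 0.00390625)

    def test_width8_min_pvalue(self):
        dist = make_pwm("ACGTACGT").score_distribution("+")
        assert math.isclose(dist.min_attainable_pvalue, 4.0 ** -8)

    def test_uniform_pwm_single_score(self):
        pwm = PWM("u", np.full((3, 4), 0.25), pseudocount=0.0)
        dist = pwm.score_distribution("+")
        assert math.isclose(dist.pvalue(0), 1.0)

    def test_tail_monotone_and_one_at_minimum(self, rng):
        mat = rng.dirichlet(np.ones(4), size=6)
        pwm = PWM("r", mat)
        dist = pwm.score_distribution("+")
        scores = np.arange(dist.min_int, dist.max_int + 1)
        tails = np.asarray([dist.pvalue(int(s)) for s in scores])
        assert math.isclose(tails[0], 1.0)
        assert np.all(np.diff(tails) <= 1e-15)


class TestScan:
    def test_width4_impossible_at_1e4(self, rng):
        pwm = make_pwm("ACGT")
        seqs = {"s": random_seq(rng, 500)}
        assert scan(pwm, seqs, 1e-4) == []

    def test_planted_width8_recovered(self, rng):
        consensus = "ACGTACCA"
        pwm = make_pwm(consensus)
        seq = random_seq(rng, 200)
        seq = seq[:100] + consensus + seq[108:]
        hits = scan(pwm, {"s": seq}, 1e-4)
        assert any(h.start == 100 and h.strand == "+" for h in hits)

    def test_palindrome_hits_both_strands(self):
        consensus = "ACGCGCGT"
        assert reverse_complement(consensus) == consensus
        pwm = make_pwm(consensus)
        seq = "T" * 50 + consensus + "T" * 50
        hits = scan(pwm, {"s": seq}, 1e-4)
        at = [(h.start, h.strand) for h in hits]
        assert (50, "+") in at and (50, "-") in at

    def test_hits_never_overlap_n(self, rng):
        consensus = "ACGTACCA"
        pwm = make_pwm(consensus)
        # consensus with an N in the middle, plus a clean copy
        seq = "T" * 20 + "ACGTNCCA" + "T" * 20 + consensus + "T" * 20
        hits = scan(pwm, {"s": seq}, 1e-4)
        assert {h.start for h in hits} == {48}

    def test_motif_longer_than_sequences_warns(self):
        pwm = make_pwm("ACGTACGTACGT")
        with pytest.warns(UserWarning):
            assert scan(pwm, {"s": "ACGT"}, 1e-4) == []

    def test_pvalues_in_unit_interval(self, rng):
        pwm = make_pwm("ACGTAGGA", prob=0.9)
        hits = scan(pwm, {"s": random_seq(rng, 2000)}, 1e-2)
        assert hits, "expected some hits at the loose threshold"
        for h in hits:
            assert 0.0 < h.p_value <= 1e-2
            assert h.end - h.start == pwm.width


class TestBruteForceOracle:
    """Miniature of the acceptance oracle: exact hit-set equivalence."""

    def test_small_equivalence(self, rng):
        from oracle_utils import brute_force_hits

        for trial in range(5):
            w = int(rng.integers(3, 5))
            mat = rng.dirichlet(np.full(4, 0.3), size=w)
            bg = rng.dirichlet(np.full(4, 5.0))
            pwm = PWM(f"m{trial}", mat, bg)
            seqs = {f"s{i}": random_seq(rng, 80) for i in range(5)}
            expected = brute_force_hits(pwm, seqs, 1e-2)
            got = {(h.sequence_id, h.start, h.strand): h.p_value
                   for h in scan(pwm, seqs, 1e-2)}
            assert set(got) == set(expected)
            for key, p in got.items():
                assert math.isclose(p, expected[key], rel_tol=1e-9)


class TestShuffle:
    def test_unique_arrangement_fixed(self):
        assert dinucleotide_shuffle("AAAA", 0) == "AAAA"

    def test_counts_preserved(self, rng):
        for _ in range(20):
            s = random_seq(rng, int(rng.integers(10, 300)))
            t = dinucleotide_shuffle(s, rng)
            assert dinucleotide_counts(t) == dinucleotide_counts(s)
            assert (t[0], t[-1], len(t)) == (s[0], s[-1], len(s))

    def test_seed_determinism(self):
        s = "ACGTACGTTTGCAACGT"
        assert dinucleotide_shuffle(s, 7) == dinucleotide_shuffle(s, 7)

    def test_double_shuffle_preserves_counts(self, rng):
        s = random_seq(rng, 200)
        t = dinucleotide_shuffle(dinucleotide_shuffle(s, rng), rng)
        assert dinucleotide_counts(t) == dinucleotide_counts(s)

    def test_n_positions_fixed(self, rng):
        s = random_seq(rng, 50) + "NNN" + random_seq(rng, 50)
        t = dinucleotide_shuffle(s, rng)
        assert t[50:53] == "NNN"
        assert dinucleotide_counts(t) == dinucleotide_counts(s)

    def test_short_input_unchanged(self):
        assert dinucleotide_shuffle("A", 0) == "A"
        assert dinucleotide_shuffle("", 0) == ""


class TestEnrichment:
    def test_zero_hits_both_sets(self, rng):
        pwm = make_pwm("ACGT")  # cannot reach p<=1e-4
        seqs = {"s": random_seq(rng, 300)}
        assert motif_enrichment(pwm, seqs, seed=0) == 1.0

    def test_planted_enrichment_large(self, rng):
        consensus = "ACGTAGCA"
        pwm = make_pwm(consensus)
        parts = []
        for i in range(40):
            s = random_seq(rng, 500)
            # one consensus planted per 500 bp
            pos = int(rng.integers(0, 492))
            parts.append((f"s{i}", s[:pos] + consensus + s[pos + 8:]))
        assert motif_enrichment(pwm, parts, seed=0) > 2.0

    def test_random_sequence_enrichment_bounded(self, rng):
        pwm = make_pwm("ACGTAGCA", prob=0.85)
        seqs = {"s": random_seq(rng, 30_000)}
        # loose threshold so the shuffled control has >=20 hits
        from stretchmotif.motifs import scan as _scan

        fe = motif_enrichment(pwm, seqs, seed=0, p_threshold=1e-3)
        n_shuf = len(_scan(pwm, {"s": dinucleotide_shuffle(seqs["s"],
                                                           np.random.default_rng(0))},
                           1e-3))
        assert n_shuf >= 20
        assert 0.5 <= fe <= 2.0

    def test_planted_exceeds_unplanted_19_of_20(self):
        consensus = "ACGTAGCA"
        pwm = make_pwm(consensus)
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            planted, unplanted = [], []
            for i in range(20):
                s = random_seq(r, 300)
                pos = int(r.integers(0, 292))
                planted.append((f"p{i}", s[:pos] + consensus + s[pos + 8:]))
                unplanted.append((f"u{i}", random_seq(r, 300)))
            fe_p = motif_enrichment(pwm, planted, seed=seed)
            fe_u = motif_enrichment(pwm, unplanted, seed=seed)
            wins += fe_p > fe_u
        assert wins >= 19


class TestMasking:
    def test_single_occurrence(self):
        assert mask_simple_repeats("GGAAAAAAAAGG") == "GGNNNNNNNNGG"

    def test_overlapping_masked(self):
        assert mask_simple_repeats("AAAAAAAAA") == "NNNNNNNNN"

    def test_below_length_unchanged(self):
        assert mask_simple_repeats("ACACACA") == "ACACACA"

    def test_reverse_complements_masked(self):
        assert mask_simple_repeats("TTTTTTTT") == "NNNNNNNN"
        assert mask_simple_repeats("GTGTGTGT") == "NNNNNNNN"
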