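import numpy as np
import pytest

from conftest import make_pwm
from stretchmotif.intervals import GenomeInterval
from stretchmotif.profiles import (
    SignalTrack,
    aggregate_dinucleotide,
    aggregate_motif_density,
    aggregate_signal,
    motif_density_track,
    postprocess_footprints,
)

CONSENSUS = "ACGCAGGA"


def plant(genome, pos, s=CONSENSUS, chrom="chr1"):
    g = genome[chrom]
    genome[chrom] = g[:pos] + s + g[pos + len(s):]


class TestAggregateSignal:
    def test_constant_track(self):
        track = SignalTrack.from_arrays({"chr1": np.full(10_000, 2.5)})
        prof = aggregate_signal([("chr1", 5000)], track)
        assert prof.n_bins == 300
        assert np.allclose(prof.values, 25.0)

    def test_delta_at_summit(self):
        arr = np.zeros(10_000)
        arr[5000] = 7.0
        prof = aggregate_signal([("chr1", 5000)], SignalTrack.from_arrays({"chr1": arr}))
        assert prof.values[prof.central_bin] == 7.0
        assert np.count_nonzero(prof.values) == 1

    def test_linearity(self):
        r = np.random.default_rng(0)
        a1, a2 = r.uniform(0, 5, 8000), r.uniform(0, 5, 8000)
        summits = [("chr1", 3000), ("chr1", 4500)]
        p1 = aggregate_signal(summits, SignalTrack.from_arrays({"chr1": a1}))
        p2 = aggregate_signal(summits, SignalTrack.from_arrays({"chr1": a2}))
        p12 = aggregate_signal(
            summits, SignalTrack.from_arrays({"chr1": 2 * a1 + 3 * a2}))
        assert np.allclose(p12.values, 2 * p1.values + 3 * p2.values)

    def test_edge_truncation_counts_zero(self):
        track = SignalTrack.from_arrays({"chr1": np.full(2000, 1.0)})
        prof = aggregate_signal([("chr1", 100)], track)
        # bins before the chromosome start contribute 0
        assert prof.values[0] == 0.0
        assert prof.values[prof.central_bin] == 10.0

    def test_no_summits_rejected(self):
        with pytest.raises(ValueError):
            aggregate_signal([], SignalTrack.from_arrays({"chr1": np.zeros(10)}))

    def test_offsets_convention(self):
        track = SignalTrack.from_arrays({"chr1": np.zeros(5000)})
        prof = aggregate_signal([("chr1", 2000)], track)
        assert prof.offsets[0] == -1500
        assert prof.offsets[-1] == 1490
        assert prof.offsets[prof.central_bin] == 0


class TestAggregateDinucleotide:
    def test_all_c_genome(self):
        genome = {"chr1": "C" * 10_000}
        prof = aggregate_dinucleotide([("chr1", 5000)], genome, "CC")
        assert np.allclose(prof.values, 1.0)

    def test_alternating_cg(self):
        genome = {"chr1": "CG" * 5000}
        prof = aggregate_dinucleotide([("chr1", 5000)], genome, "CG")
        assert np.allclose(prof.values, 0.5)

    def test_random_genome_near_expected(self):
        r = np.random.default_rng(3)
        genome = {"chr1": "".join(r.choice(list("ACGT"), size=200_000))}
        summits = [("chr1", int(p)) for p in r.integers(2000, 198_000, size=200)]
        prof = aggregate_dinucleotide(summits, genome, "CG")
        # each bin pools ~200*10 positions: binomial 3-s.e. bound around 1/16
        se = np.sqrt((1 / 16) * (15 / 16) / 2000)
        assert np.all(np.abs(prof.values - 1 / 16) < 3.5 * se)


class TestAggregateMotifDensity:
    def test_spike_at_center(self):
        genome = {"chr1": "T" * 40_000}
        summits = []
        for k in range(10):
            pos = 4000 * k + 2000
            plant(genome, pos)
            summits.append(("chr1", pos))
        pwm = make_pwm(CONSENSUS, name="m")
        prof = aggregate_motif_density(summits, ["m"], {"m": pwm}, genome)
        assert int(np.argmax(prof.values)) == prof.central_bin

    def test_two_motifs_symmetric_peaks(self):
        other = "GGATATCC"
        genome = {"chr1": "T" * 40_000}
        summits = []
        for k in range(10):
            pos = 4000 * k + 2000
            plant(genome, pos - 200)
            plant(genome, pos + 200, s=other)
            summits.append(("chr1", pos))
        pwms = {"m1": make_pwm(CONSENSUS, name="m1"),
                "m2": make_pwm(other, name="m2")}
        prof = aggregate_motif_density(summits, ["m1", "m2"], pwms, genome)
        c = prof.central_bin
        peaks = np.argsort(prof.values)[-2:]
        assert {int(p) for p in peaks} == {c - 20, c + 20}

    def test_full_threshold_matches_string_search(self):
        r = np.random.default_rng(9)
        genome = {"chr1": "".join(r.choice(list("ACGT"), size=30_000))}
        for pos in (5000, 9000, 9100, 14_000):
            plant(genome, pos)
        summits = [("chr1", p) for p in (5050, 9050, 14_050)]
        pwm = make_pwm(CONSENSUS, name="m")
        prof = aggregate_motif_density(
            summits, ["m"], {"m": pwm}, genome, llr_fraction=1.0)
        total_sites = round(float(prof.values.sum()) * len(summits))
        # oracle: exact string occurrences (both strands) within +/-1500
        from stretchmotif.motifs import reverse_complement

        expected = 0
        seq = genome["chr1"]
        for _, s in summits:
            window = seq[s - 1500:s + 1500]
            for target in (CONSENSUS, reverse_complement(CONSENSUS)):
                start = 0
                while True:
                    i = window.find(target, start)
                    if i < 0:
                        break
                    expected += 1
                    start = i + 1
        assert total_sites == expected


class TestDensityTrack:
    def _region(self):
        return GenomeInterval("chr1", 1000, 2000)

    def test_three_disjoint_sites(self):
        genome = {"chr1": "T" * 4000}
        for pos in (1200, 1250, 1300):
            plant(genome, pos)
        pwm = make_pwm(CONSENSUS, name="m")
        track = motif_density_track(self._region(), ["m"], {"m": pwm}, genome)
        at = {int(s): int(c) for s, c in zip(track.starts, track.counts)}
        assert at[1200] == 3

    def test_overlapping_sites_count_one(self):
        # two motifs whose sites overlap on the same planted bases
        genome = {"chr1": "T" * 4000}
        plant(genome, 1500, s="ACGCAGGACT")
        pwms = {"m1": make_pwm("ACGCAGGA", name="m1"),
                "m2": make_pwm("GCAGGACT", name="m2")}
        track = motif_density_track(self._region(), ["m1", "m2"], pwms, genome)
        at = {int(s): int(c) for s, c in zip(track.starts, track.counts)}
        assert at[1500] == 1

    def test_site_straddling_window_edge(self):
        genome = {"chr1": "T" * 4000}
        plant(genome, 1145)  # start inside [1000,1150), end outside
        pwm = make_pwm(CONSENSUS, name="m")
        track = motif_density_track(self._region(), ["m"], {"m": pwm}, genome)
        at = {int(s): int(c) for s, c in zip(track.starts, track.counts)}
        assert at[1000] == 1

    def test_motif_order_invariance(self):
        r = np.random.default_rng(4)
        genome = {"chr1": "".join(r.choice(list("ACGT"), size=4000))}
        pwms = {"m1": make_pwm(CONSENSUS, prob=0.9, name="m1"),
                "m2": make_pwm("GGATATCC", prob=0.9, name="m2")}
        t1 = motif_density_track(self._region(), ["m1", "m2"], pwms, genome)
        t2 = motif_density_track(self._region(), ["m2", "m1"], pwms, genome)
        assert np.array_equal(t1.counts, t2.counts)

    def test_region_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            motif_density_track(
                GenomeInterval("chr1", 0, 100), [], {}, {"chr1": "T" * 200})


class TestFootprints:
    def iv(self, s, e):
        return GenomeInterval("chr1", s, e)

    def test_worked_toy(self):
        out = postprocess_footprints(
            [self.iv(100, 110), self.iv(125, 135)], extend=5, merge_distance=10)
        assert out == [self.iv(95, 140)]

    def test_clip_at_zero(self):
        assert postprocess_footprints([self.iv(3, 10)], extend=5,
                                      merge_distance=10) == [self.iv(0, 15)]

    def test_clip_at_chrom_end(self):
        out = postprocess_footprints(
            [self.iv(90, 98)], extend=5, merge_distance=10,
            chrom_sizes={"chr1": 100})
        assert out == [self.iv(85, 100)]

    def test_gap_exactly_d_merges(self):
        out = postprocess_footprints(
            [self.iv(0, 10), self.iv(20, 30)], extend=0, merge_distance=10)
        assert out == [self.iv(0, 30)]

    def test_idempotent(self):
        out = postprocess_footprints(
            [self.iv(100, 110), self.iv(125, 135)], extend=5, merge_distance=10)
        again = postprocess_footprints(out, extend=0, merge_distance=10)
        assert again == out
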