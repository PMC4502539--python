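import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_pwm
from stretchmotif.expression import (
    assign_cell_motifs,
    build_enrichment_table,
    central_enrichment,
    cluster_motifs,
    cross_region_correlation,
    expression_enrichment_correlation,
    prune_for_heatmap,
    shuffled_cell_null,
)

CELLS = [f"cell{i + 1:02d}" for i in range(9)]


def enrichment_table(values_by_motif, compartment="SE_DHS"):
    rows = []
    for motif, vals in values_by_motif.items():
        for cell, v in zip(CELLS, vals):
            rows.append((motif, cell, compartment, float(v)))
    return build_enrichment_table(rows)


def expression_frame(values_by_tf):
    return pd.DataFrame(values_by_tf, index=CELLS).T


class TestCorrelation:
    def test_monotone_rho_one(self):
        enr = enrichment_table({"m1": range(1, 10)})
        expr = expression_frame({"TF1": [2 * v for v in range(1, 10)]})
        rho = expression_enrichment_correlation(enr, expr, {"m1": "TF1"}, "SE_DHS")
        assert math.isclose(rho["m1"], 1.0)

    def test_reversed_rho_minus_one(self):
        enr = enrichment_table({"m1": range(1, 10)})
        expr = expression_frame({"TF1": list(range(9, 0, -1))})
        rho = expression_enrichment_correlation(enr, expr, {"m1": "TF1"}, "SE_DHS")
        assert math.isclose(rho["m1"], -1.0)

    def test_constant_expression_missing(self):
        enr = enrichment_table({"m1": range(1, 10)})
        expr = expression_frame({"TF1": [5.0] * 9})
        rho = expression_enrichment_correlation(enr, expr, {"m1": "TF1"}, "SE_DHS")
        assert math.isnan(rho["m1"])

    def test_unmapped_motif_missing(self):
        enr = enrichment_table({"m1": range(1, 10)})
        expr = expression_frame({"TF1": range(9)})
        rho = expression_enrichment_correlation(enr, expr, {}, "SE_DHS")
        assert math.isnan(rho["m1"])


class TestShuffledCellNull:
    def _tables(self, coupled, seed):
        r = np.random.default_rng(seed)
        enr, expr, mapping = {}, {}, {}
        for k in range(15):
            e = r.uniform(1, 5, 9)
            x = 2 * e + r.normal(0, 0.3, 9) if coupled else r.uniform(0, 10, 9)
            enr[f"m{k}"] = e
            expr[f"TF{k}"] = x
            mapping[f"m{k}"] = f"TF{k}"
        return enrichment_table(enr), expression_frame(expr), mapping

    def test_coupled_detected(self):
        enr, expr, mapping = self._tables(True, 0)
        _, _, p = shuffled_cell_null(enr, expr, mapping, "SE_DHS", seed=0)
        assert p < 0.01

    def test_decoupled_calibrated(self):
        ok = 0
        for seed in range(20):
            enr, expr, mapping = self._tables(False, 100 + seed)
            _, _, p = shuffled_cell_null(enr, expr, mapping, "SE_DHS", seed=seed)
            ok += p > 0.05
        assert ok >= 18


class TestCrossRegion:
    def test_self_correlation_is_one(self):
        r = np.random.default_rng(0)
        vals = {f"m{k}": r.uniform(1, 5, 9) for k in range(6)}
        enr = pd.concat(
            [enrichment_table(vals, "SE_DHS"), enrichment_table(vals, "SE_nonDHS")],
            ignore_index=True)
        rho, _, _ = cross_region_correlation(enr, "SE_DHS", "SE_nonDHS", seed=0)
        assert np.allclose(rho.to_numpy(dtype=float), 1.0)

    def test_permuted_cells_near_zero(self):
        r = np.random.default_rng(1)
        vals = {f"m{k}": r.uniform(1, 5, 9) for k in range(20)}
        permuted = {m: np.asarray(v)[r.permutation(9)] for m, v in vals.items()}
        enr = pd.concat(
            [enrichment_table(vals, "SE_DHS"),
             enrichment_table(permuted, "SE_nonDHS")],
            ignore_index=True)
        rho, _, p = cross_region_correlation(enr, "SE_DHS", "SE_nonDHS", seed=1)
        assert abs(float(rho.mean())) < 0.35
        assert p > 0.05


class TestCentralEnrichment:
    CONSENSUS = "ACGCAGGA"

    def _seqs(self, n, positions, length=100, rng=None):
        rng = rng or np.random.default_rng(0)
        out = []
        for i in range(n):
            s = list("T" * length)
            pos = positions[i % len(positions)]
            s[pos:pos + 8] = self.CONSENSUS
            out.append("".join(s))
        return out

    def test_all_central(self):
        pwm = make_pwm(self.CONSENSUS)
        n = 30
        center = (100 - 8) // 2  # start index of the central window
        res = central_enrichment(pwm, self._seqs(n, [center]))
        assert res.n_total == n
        assert res.n_central == n
        assert res.best_half_width == 0
        # independent binomial arithmetic: all n best sites in the 1-start
        # window has probability (1/93)^n; Bonferroni can add at most ln(93)
        assert res.log_adjusted_p <= n * math.log(1.0 / 93) + math.log(93)
        assert res.log_adjusted_p < -50

    def test_monotone_in_n_total(self):
        pwm = make_pwm(self.CONSENSUS)
        center = (100 - 8) // 2
        logps = [central_enrichment(pwm, self._seqs(n, [center])).log_adjusted_p
                 for n in (5, 15, 30, 60)]
        assert all(b < a for a, b in zip(logps, logps[1:]))

    def test_monotone_in_central_fraction(self):
        pwm = make_pwm(self.CONSENSUS)
        center = (100 - 8) // 2
        n = 40
        logps = []
        for n_central in (10, 20, 30, 40):
            rng = np.random.default_rng(42)
            seqs = self._seqs(n_central, [center])
            # remaining best sites parked far off-center at fixed spots
            seqs += self._seqs(n - n_central, [2, 88, 5, 85], rng=rng)
            logps.append(central_enrichment(pwm, seqs).log_adjusted_p)
        assert all(b < a for a, b in zip(logps, logps[1:]))

    def test_uniform_placement_calibrated(self):
        pwm = make_pwm(self.CONSENSUS)
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            positions = rng.integers(0, 93, size=40)
            seqs = [self._seqs(1, [int(p)])[0] for p in positions]
            res = central_enrichment(pwm, seqs)
            ok += res.log_adjusted_p > -5.0
        assert ok >= 18

    def test_empty_input(self):
        res = central_enrichment(make_pwm(self.CONSENSUS), [])
        assert res.n_total == 0 and res.log_adjusted_p == 0.0

    def test_below_floor_means_no_sites(self):
        res = central_enrichment(make_pwm(self.CONSENSUS), ["T" * 100] * 10)
        assert res.n_total == 0 and res.log_adjusted_p == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            central_enrichment(make_pwm(self.CONSENSUS), ["T" * 100, "T" * 99])


class TestPrune:
    def _inputs(self, log2_vals, rpkm_max, rho):
        fe = {"m1": [2.0 ** v for v in log2_vals] + [1.0] * (9 - len(log2_vals))}
        enr = enrichment_table(fe)
        expr = expression_frame({"TF1": [rpkm_max] + [0.1] * 8})
        return enr, expr, {"m1": "TF1"}, pd.Series({"m1": rho})

    def test_paper_thresholds_pass(self):
        enr, expr, mapping, rho = self._inputs([1.6, 0.7], 3.0, 0.5)
        assert prune_for_heatmap(enr, expr, mapping, rho) == ["m1"]

    def test_range_fails(self):
        # max 1.6 fine but the fillers at log2=0 widen the range; use a flat row
        fe = {"m1": [2.0 ** 1.6] * 4 + [2.0 ** 1.0] * 5}
        enr = enrichment_table(fe)
        expr = expression_frame({"TF1": [3.0] * 9})
        rho = pd.Series({"m1": 0.5})
        assert prune_for_heatmap(enr, expr, {"m1": "TF1"}, rho) == []

    def test_rpkm_boundary_strict(self):
        enr, expr, mapping, rho = self._inputs([1.6, 0.7], 2.0, 0.5)
        assert prune_for_heatmap(enr, expr, mapping, rho) == []

    def test_rho_zero_fails(self):
        enr, expr, mapping, rho = self._inputs([1.6, 0.7], 3.0, 0.0)
        assert prune_for_heatmap(enr, expr, mapping, rho) == []

    def test_unmapped_motif_warns(self):
        enr, expr, _, rho = self._inputs([1.6, 0.7], 3.0, 0.5)
        with pytest.warns(UserWarning):
            assert prune_for_heatmap(enr, expr, {}, rho) == []


class TestClustering:
    def test_identical_rows_merge_first(self):
        df = pd.DataFrame(
            {"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [9.0, 9.0]}).T
        clust = cluster_motifs(df)
        assert set(clust.merges[0]) == {frozenset({"a"}), frozenset({"b"})}

    def test_near_duplicates_merge_before_distant(self):
        df = pd.DataFrame(
            {"x": [0.0, 0.0], "y": [0.1, 0.0], "far": [5.0, 5.0]}).T
        clust = cluster_motifs(df)
        assert set(clust.merges[0]) == {frozenset({"x"}), frozenset({"y"})}

    def test_two_family_cut(self):
        rng = np.random.default_rng(0)
        rows = {}
        for k in range(4):
            rows[f"fam1_{k}"] = rng.normal(0.0, 0.1, 6)
        for k in range(4):
            rows[f"fam2_{k}"] = rng.normal(4.0, 0.1, 6)
        clust = cluster_motifs(pd.DataFrame(rows).T)
        labels = clust.cut(2)
        fam1 = {labels[m] for m in rows if m.startswith("fam1")}
        fam2 = {labels[m] for m in rows if m.startswith("fam2")}
        assert len(fam1) == 1 and len(fam2) == 1 and fam1 != fam2

    def test_single_motif(self):
        df = pd.DataFrame({"only": [1.0, 2.0]}).T
        assert cluster_motifs(df).order == ["only"]


class TestAssign:
    def _assign(self, rpkm, logp, rho_val, mapping=None, central=None):
        enr = enrichment_table({"m1": range(1, 10)})
        expr = expression_frame({"TF1": [rpkm] * 9})
        from stretchmotif.expression import CentralEnrichmentResult

        central = central or {
            "m1": CentralEnrichmentResult("m1", 10, 10, 0, logp)}
        return assign_cell_motifs(
            enr, expr, mapping or {"m1": "TF1"}, pd.Series({"m1": rho_val}),
            central, CELLS[0])

    def test_paper_thresholds_assigned(self):
        assert self._assign(3.0, -60.0, 0.5).motifs == ["m1"]

    def test_expression_filter(self):
        assert self._assign(1.9, -200.0, 0.9).motifs == []

    def test_central_filter_strict_boundary(self):
        assert self._assign(3.0, -50.0, 0.5).motifs == []

    def test_dedup_lowest_logp(self):
        from stretchmotif.expression import CentralEnrichmentResult

        enr = enrichment_table({"m1": range(1, 10), "m2": range(1, 10)})
        expr = expression_frame({"TF1": [5.0] * 9})
        central = {"m1": CentralEnrichmentResult("m1", 10, 10, 0, -70.0),
                   "m2": CentralEnrichmentResult("m2", 10, 10, 0, -55.0)}
        cms = assign_cell_motifs(
            enr, expr, {"m1": "TF1", "m2": "TF1"},
            pd.Series({"m1": 0.5, "m2": 0.5}), central, CELLS[0])
        assert cms.motifs == ["m1"]

    def test_filters_commute(self):
        # the conjunctive cascade equals the intersection of the three
        # single-filter outcomes, so application order cannot matter
        from stretchmotif.expression import CentralEnrichmentResult

        rng = np.random.default_rng(5)
        enr = enrichment_table({f"m{k}": rng.uniform(1, 4, 9) for k in range(12)})
        expr = expression_frame(
            {f"TF{k}": rng.uniform(0, 5, 9) for k in range(12)})
        mapping = {f"m{k}": f"TF{k}" for k in range(12)}
        rho = pd.Series({f"m{k}": rng.uniform(-1, 1) for k in range(12)})
        central = {f"m{k}": CentralEnrichmentResult(f"m{k}", 5, 10, 3,
                                                    rng.uniform(-120, 0))
                   for k in range(12)}
        cms = assign_cell_motifs(enr, expr, mapping, rho, central, CELLS[0])
        expected = {m for m in mapping
                    if expr.loc[mapping[m], CELLS[0]] > 2.0
                    and central[m].log_adjusted_p < -50.0
                    and rho[m] > 0.0}
        assert set(cms.motifs) == expected


class TestEnrichmentTable:
    def test_log2_column(self):
        df = enrichment_table({"m1": [4.0] * 9})
        assert np.allclose(df["log2_enrichment"], 2.0)

    def test_negative_fe_rejected(self):
        with pytest.raises(ValueError):
            build_enrichment_table([("m1", "cell01", "SE_DHS", -0.5)])
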