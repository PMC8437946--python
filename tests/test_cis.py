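import numpy as np
import pandas as pd
import pytest

from epilayers.cis import (
    distal_cis_screen,
    epiconvergence_report,
    promoter_cis_screen,
)
from epilayers.core import Parameters
from epilayers.simulate import (
    simulate_cis_matrices,
    simulate_distal_geometry,
    simulate_pattern_cohort,
)
from epilayers.epipoly import epipolymorphism_table


class TestPromoterScreen:
    def test_fdr_is_k_over_m(self, params):
        e, m, planted = simulate_cis_matrices(200, 40, 0.8, 120, seed=0)
        res = promoter_cis_screen(e, m, params)
        curve = res.fdr_curve
        assert np.allclose(curve["fdr"], curve["k"] / np.maximum(curve["m"], 1))
        # when every diagonal rank <= k, FDR(k) = k / n_genes
        full = curve.loc[curve["m"] == len(res.table)]
        assert (full["fdr"] >= full["k"] / len(res.table) - 1e-12).all()

    def test_planted_pairs_rank_first(self, params):
        e, m, planted = simulate_cis_matrices(300, 20, 0.8, 200, seed=1)
        res = promoter_cis_screen(e, m, params)
        t = res.table.set_index("gene")
        assert (t.loc[planted, "rank"] <= 3).all()
        assert (t.loc[planted, "r_cis"] < -0.5).all()

    def test_positive_direction_mirrors(self, params):
        e, m, planted = simulate_cis_matrices(200, 20, 0.8, 120, seed=2)
        e.loc[planted] = 16 - e.loc[planted]  # flip the coupling sign
        res_neg = promoter_cis_screen(e, m, params, direction="negative")
        res_pos = promoter_cis_screen(e, m, params, direction="positive")
        tn = res_neg.table.set_index("gene")
        tp = res_pos.table.set_index("gene")
        assert (tp.loc[planted, "rank"] <= 3).all()
        assert (tn.loc[planted, "rank"] > 3).all()

    def test_excluded_genes_removed(self, params):
        e, m, planted = simulate_cis_matrices(100, 10, 0.8, 120, seed=3)
        res = promoter_cis_screen(e, m, params, exclude_genes=planted[:5])
        assert not set(planted[:5]) & set(res.table["gene"])

    def test_mismatched_inputs_rejected(self, params):
        e, m, _ = simulate_cis_matrices(50, 0, 0.5, 120, seed=4)
        with pytest.raises(ValueError, match="square-matched"):
            promoter_cis_screen(e.iloc[:-1], m, params)

    def test_all_missing_diagonal_rejected(self):
        e, m, _ = simulate_cis_matrices(50, 0, 0.5, 30, seed=5)
        with pytest.raises(ValueError, match="own-promoter"):
            promoter_cis_screen(e, m, Parameters())  # 30 < min support 50

    def test_null_calibration(self, params):
        # 20 independent-matrix replicates: essentially no discoveries
        total_calls = 0
        for s in range(20):
            e, m, _ = simulate_cis_matrices(500, 0, 0.0, 200, seed=100 + s)
            res = promoter_cis_screen(e, m, params)
            total_calls += len(res.genes_at_fdr(0.05))
        # every call is false under the null; empirical FDR within 2x nominal
        assert total_calls / max(20 * 500 * 0.05, 1) <= 2.0
        assert total_calls <= 10

    def test_power_with_planted_pairs(self, params):
        e, m, planted = simulate_cis_matrices(2000, 50, 0.6, 500, seed=7)
        res = promoter_cis_screen(e, m, params)
        calls = set(res.genes_at_fdr(0.05))
        sens = len(calls & set(planted)) / len(planted)
        assert sens >= 0.8
        t = res.table.set_index("gene")
        assert (t.loc[sorted(calls & set(planted)), "rank"] <= 52).all()


class TestDistalScreen:
    def test_pairing_window_rules(self, params):
        # one locus coupled to a gene 400 kb away, one to another chromosome
        e, gc, m, lc = simulate_distal_geometry(30, 30, 200, seed=0)
        lc.loc["L00000"] = ["chr1", 10_000, 10_200]
        gc.loc["G00000"] = ["chr1", 410_000]
        lc.loc["L00001"] = ["chr2", 10_000, 10_200]
        gc.loc["G00001"] = ["chr3", 10_000]
        for j in (0, 1):
            z = (m.iloc[j] - m.iloc[j].mean()) / m.iloc[j].std()
            e.iloc[j] = 8 - 0.95 * z
        res = distal_cis_screen(e, gc, m, lc, params, n_shuffles=2, seed=0)
        t = res.table.set_index("locus")
        assert t.loc["L00000", "best_gene"] == "G00000" and t.loc["L00000", "paired"]
        assert t.loc["L00001", "best_gene"] == "G00001" and not t.loc["L00001", "paired"]

    def test_fdr_is_shuffled_over_real_ratio(self, params):
        e, gc, m, lc = simulate_distal_geometry(
            400, 300, 250, seed=1, n_coupled=60, rho=0.8)
        res = distal_cis_screen(e, gc, m, lc, params, n_shuffles=4, seed=1)
        assert res.n_paired >= 60
        assert res.fdr == pytest.approx(
            np.mean(res.shuffled_paired) / res.n_paired)
        assert res.fdr < 0.5
        rep = res.distance_report
        assert rep["frac_within_50kb"].iloc[0] + rep["frac_50_500kb"].iloc[0] == pytest.approx(1.0)

    def test_global_null_fdr_near_one(self, params):
        # gene-dense toy genome so chance pairings are frequent enough for
        # the ratio estimator to stabilize
        fdrs = []
        for s in range(5):
            e, gc, m, lc = simulate_distal_geometry(
                800, 500, 150, seed=50 + s, chrom_length=10_000_000)
            res = distal_cis_screen(e, gc, m, lc, params, n_shuffles=3, seed=s)
            fdrs.append(min(res.fdr, 2.0))
        assert np.mean(fdrs) >= 0.9

    def test_zero_shuffles_rejected(self, params):
        e, gc, m, lc = simulate_distal_geometry(20, 20, 120, seed=2)
        with pytest.raises(ValueError, match="n_shuffles"):
            distal_cis_screen(e, gc, m, lc, params, n_shuffles=0)


class TestEpiconvergence:
    def _epipoly(self, seed, n_bg=80, n_cc=40):
        counts, labels, means = simulate_pattern_cohort(n_bg, n_cc, 60, seed)
        table = epipolymorphism_table(counts, depth=30, seed=seed)
        epi = table["epipolymorphism"]
        return (epi[labels == "concentrated"], means[labels == "concentrated"],
                epi[labels == "background"], means[labels == "background"])

    def test_identical_distributions_not_significant(self):
        _, _, bg_epi, bg_meth = self._epipoly(0)
        report = epiconvergence_report(bg_epi, bg_meth, bg_epi, bg_meth)
        assert (report["p"] > 0.4).all()

    def test_concentrated_epialleles_detected(self):
        cc_epi, cc_meth, bg_epi, bg_meth = self._epipoly(1)
        report = epiconvergence_report(cc_epi, cc_meth, bg_epi, bg_meth)
        low = report[report["stratum_hi"] <= 0.3]
        assert (low["p"] < 0.01).any()
        assert (low["median_cis"] < low["median_background"]).all()

    def test_null_calibration_over_seeds(self):
        # background split at random against itself: few significant strata
        hits, total = 0, 0
        rng = np.random.default_rng(3)
        _, _, bg_epi, bg_meth = self._epipoly(2, n_bg=160, n_cc=0)
        for _ in range(10):
            mask = rng.random(len(bg_epi)) < 0.5
            report = epiconvergence_report(
                bg_epi[mask], bg_meth[mask], bg_epi[~mask], bg_meth[~mask])
            hits += int((report["p_adj"] < 0.05).any())
            total += 1
        assert hits / total <= 0.2

    def test_empty_stratum_skipped(self):
        cc_epi, cc_meth, bg_epi, bg_meth = self._epipoly(4)
        report = epiconvergence_report(
            cc_epi, cc_meth * 0 + 0.05, bg_epi, bg_meth * 0 + 0.05,
            strata=(0.0, 0.1, 0.9, 1.0))
        assert (report["stratum_hi"] <= 0.1).all()
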