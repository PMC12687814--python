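"""Scans and hierarchical correction: windows, xQTL/qQTL/vQTL/iQTL, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from quantqtl.qtl_mapping import (
    InteractionFit,
    build_cis_windows,
    classify_iqtl_direction,
    fit_null_models,
    hierarchical_correct,
    map_iqtl,
    map_qqtl,
    map_vqtl,
    map_xqtl,
    rank_inverse_normal,
)
from quantqtl.quantile_core import QuantileGrid, rank_score_scan
from quantqtl.synthio import gen_genotypes


def _single_variant(G, ids=None):
    from quantqtl.io_formats import DosageMatrix, VariantRecord

    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    variants = [
        VariantRecord((ids or [f"v{j}" for j in range(m)])[j], "1",
                      100 + j, "A", "G",
                      maf=min(G[:, j].mean() / 2, 1 - G[:, j].mean() / 2))
        for j in range(m)
    ]
    return DosageMatrix([f"S{i}" for i in range(n)], variants, G)


class TestCisWindows:
    def test_default_span_centered_on_tss(self):
        w = build_cis_windows([("G1", "1", 10_000_000, 10_010_000)])[0]
        assert (w.start, w.end) == (9_000_000, 11_000_000)

    def test_long_tad_wins(self):
        tadb = pd.DataFrame({"chrom": ["1"], "start": [9_500_000],
                             "end": [12_500_000]})
        w = build_cis_windows([("G1", "1", 10_000_000, 10_010_000)], tadb)[0]
        assert (w.start, w.end) == (9_500_000, 12_500_000)

    def test_short_tad_loses_to_span(self):
        tadb = pd.DataFrame({"chrom": ["1"], "start": [9_800_000],
                             "end": [10_800_000]})
        w = build_cis_windows([("G1", "1", 10_000_000, 10_010_000)], tadb)[0]
        assert (w.start, w.end) == (9_000_000, 11_000_000)

    def test_missing_chromosome_falls_back(self, caplog):
        tadb = pd.DataFrame({"chrom": ["2"], "start": [0], "end": [5_000_000]})
        with caplog.at_level("INFO"):
            w = build_cis_windows([("G1", "1", 10_000_000, 10_010_000)], tadb)[0]
        assert (w.start, w.end) == (9_000_000, 11_000_000)


class TestXqtl:
    def test_exact_linear_relationship(self):
        G = np.array([0.0, 0, 1, 1, 2, 2, 0, 1, 2, 1])
        res = map_xqtl("g", 2.0 * G, _single_variant(G), None)[0]
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.p_nominal <= np.finfo(float).tiny * 10

    def test_six_point_textbook_t(self):
        # hand OLS on a 6-point fixture, intercept only
        G = np.array([0.0, 0, 1, 1, 2, 2])
        Y = np.array([1.0, 2, 2, 3, 5, 4])
        res = map_xqtl("g", Y, _single_variant(G), None)[0]
        gx = G - G.mean()
        beta = gx @ (Y - Y.mean()) / (gx @ gx)
        resid = (Y - Y.mean()) - beta * gx
        se = np.sqrt(resid @ resid / 4 / (gx @ gx))
        t = beta / se
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_nominal == pytest.approx(2 * stats.t.sf(abs(t), 4),
                                              abs=1e-12)

    def test_null_calibration(self, rng):
        n = 300
        Y = rng.normal(size=n)
        G = rng.binomial(2, 0.3, size=(n, 2000)).astype(float)
        res = map_xqtl("g", Y, _single_variant(G), None)
        frac = np.mean([r.p_nominal < 0.05 for r in res])
        assert 0.035 < frac < 0.065


class TestQqtlVqtl:
    def test_scale_model_caught_by_qqtl_missed_by_xqtl(self, rng):
        n = 2000
        hits_q, miss_x = 0, 0
        for _ in range(5):
            G = rng.binomial(2, 0.3, n).astype(float)
            Y = (1 + 0.6 * G) * rng.normal(size=n)
            dm = _single_variant(G)
            qres, _ = map_qqtl("g", Y, dm, None)
            xres = map_xqtl("g", Y, dm, None)
            hits_q += qres[0].p_nominal < 1e-4
            miss_x += xres[0].p_nominal > 0.01
        assert hits_q >= 4
        assert miss_x >= 3

    def test_location_model_detected_by_both(self, rng):
        n = 1500
        G = rng.binomial(2, 0.3, n).astype(float)
        Y = 0.5 * G + rng.normal(size=n)
        dm = _single_variant(G)
        qres, scan = map_qqtl("g", Y, dm, None)
        xres = map_xqtl("g", Y, dm, None)
        assert qres[0].p_nominal < 1e-6 and xres[0].p_nominal < 1e-6

    def test_vqtl_shares_scores_with_qqtl(self, rng):
        n = 400
        C = rng.normal(size=(n, 3))
        Y = rng.normal(size=n)
        G = rng.binomial(2, 0.25, size=(n, 5)).astype(float)
        dm = _single_variant(G)
        fits = fit_null_models(Y, C)
        _, scan = map_qqtl("g", Y, dm, C, null_fits=fits)
        vres = map_vqtl("g", Y, dm, C, scan=scan, null_fits=fits)
        scan2 = rank_score_scan(dm.dosages, fits, C)
        np.testing.assert_array_equal(scan.score, scan2.score)
        assert len(vres) == 5

    def test_vqtl_antisymmetric_in_genotype(self, rng):
        n = 500
        Y = (1 + 0.4 * rng.binomial(2, 0.3, n)) * rng.normal(size=n)
        G = rng.binomial(2, 0.3, n).astype(float)
        v1 = map_vqtl("g", Y, _single_variant(G), None)[0]
        v2 = map_vqtl("g", Y, _single_variant(-G + 2), None)[0]
        assert v1.V == pytest.approx(-v2.V, abs=1e-9)

    def test_vqtl_location_shift_is_null(self, rng):
        # a pure mean shift must not trigger the variance contrast
        n = 800
        ps = []
        for _ in range(40):
            G = rng.binomial(2, 0.3, n).astype(float)
            Y = 0.8 * G + rng.normal(size=n)
            ps.append(map_vqtl("g", Y, _single_variant(G), None)[0].p)
        assert np.mean(np.array(ps) < 0.05) < 0.15

    def test_vqtl_power_on_scale_model(self, rng):
        n = 2000
        hits = 0
        for _ in range(5):
            G = rng.binomial(2, 0.3, n).astype(float)
            Y = (1 + 0.6 * G) * rng.normal(size=n)
            hits += map_vqtl("g", Y, _single_variant(G), None)[0].p < 1e-4
        assert hits >= 4


class TestIqtl:
    def test_direction_rules(self):
        f = InteractionFit("g", "v", 0, 0.3, 0, 0.2, 0.001, 0.5, 0.01)
        assert classify_iqtl_direction(f) == "amplifying"
        f.betaI = -0.2
        assert classify_iqtl_direction(f) == "counteracting"
        f.pG = 0.2
        assert classify_iqtl_direction(f) == "uncertain"

    def test_low_maf_excluded(self, rng):
        n = 400
        G = np.zeros((n, 2))
        G[:, 0] = rng.binomial(2, 0.03, n)
        G[:, 1] = rng.binomial(2, 0.3, n)
        dm = _single_variant(G)
        F = rng.binomial(2, 0.2, n).astype(float)
        res = map_iqtl("g", rng.normal(size=n), dm, F, None)
        assert [r.variant_id for r in res] == ["v1"]

    def test_interaction_power_and_calibration(self, rng):
        n, hits, null_ps = 400, 0, []
        for _ in range(20):
            G = rng.binomial(2, 0.25, n).astype(float)
            F = rng.binomial(2, 0.3, n).astype(float)
            eps = rng.normal(size=n)
            Y = 0.3 * G + 0.8 * G * F + eps
            dm = _single_variant(G)
            hits += map_iqtl("g", Y, dm, F, None)[0].pI < 0.05
            Y0 = 0.3 * G + eps
            null_ps.append(map_iqtl("g", Y0, dm, F, None)[0].pI)
        assert hits >= 15
        assert np.mean(np.array(null_ps) < 0.05) < 0.3

    def test_constant_factor_rejected(self, rng):
        G = rng.binomial(2, 0.3, 50).astype(float)
        with pytest.raises(ValueError, match="constant"):
            map_iqtl("g", rng.normal(size=50), _single_variant(G),
                     np.ones(50), None)

    def test_rank_inverse_normal_is_monotone_and_gaussian(self, rng):
        y = rng.exponential(size=500)
        t = rank_inverse_normal(y)
        assert np.all(np.diff(t[np.argsort(y)]) >= 0)
        assert abs(t.mean()) < 0.01
        assert stats.kstest(t, "norm").pvalue > 0.01


class TestHierarchicalCorrection:
    def test_three_gene_worked_example(self):
        pairs = {
            "A": [("v1", 0.001), ("v2", 0.5)],
            "B": [("v1", 0.03)],
            "C": [("v1", 0.2), ("v2", 0.9), ("v3", 0.9), ("v4", 0.9)],
        }
        call = hierarchical_correct(pairs, fdr=0.05)
        assert call.gene_q == pytest.approx(
            {"A": 0.006, "B": 0.045, "C": 0.8}, abs=1e-12
        )
        assert call.significant_genes == ["A", "B"]
        assert call.t_star == pytest.approx(0.03)
        assert call.significant_pairs == [("A", "v1"), ("B", "v1")]

    def test_single_gene_single_variant(self):
        call = hierarchical_correct({"A": [("v1", 0.01)]})
        assert call.gene_q["A"] == pytest.approx(0.01)
        assert call.significant_pairs == [("A", "v1")]

    def test_no_significant_genes(self):
        call = hierarchical_correct({"A": [("v1", 0.9)], "B": [("v1", 0.8)]})
        assert call.significant_pairs == [] and call.t_star is None

    def test_stage2_never_admits_nonsignificant_gene(self, rng):
        pairs = {
            f"G{i}": [(f"v{j}", float(p)) for j, p in
                      enumerate(rng.uniform(size=5))]
            for i in range(30)
        }
        pairs["HIT"] = [("v0", 1e-8)]
        call = hierarchical_correct(pairs)
        sig_genes = set(call.significant_genes)
        assert all(g in sig_genes for g, _ in call.significant_pairs)

    def test_bonferroni_uses_testable_count(self):
        call = hierarchical_correct({"A": [("v1", 0.004), ("v2", 0.5),
                                           ("v3", 0.7)]})
        row = call.pair_table.set_index("variant_id")
        assert row.loc["v1", "p_bonf_within_gene"] == pytest.approx(0.012)
        assert row.loc["v2", "p_bonf_within_gene"] == pytest.approx(1.0)


class TestFlatBh:
    def test_flat_bh_matches_hand_computation(self):
        from quantqtl.qtl_mapping import flat_bh_correct

        pairs = {"A": [("v1", 0.001), ("v2", 0.02)], "B": [("v1", 0.9)]}
        call = flat_bh_correct(pairs, fdr=0.05)
        got = dict(zip(
            call.pair_table["variant_id"] + "@" + call.pair_table["gene_id"],
            call.pair_table["q_value"],
        ))
        assert got["v1@A"] == pytest.approx(0.003)
        assert got["v2@A"] == pytest.approx(0.03)
        assert got["v1@B"] == pytest.approx(0.9)
        assert set(call.significant_pairs) == {("A", "v1"), ("A", "v2")}
        assert call.t_star is None


class TestGeneCategories:
    def test_gene_level_from_significant_pairs(self):
        from quantqtl.qtl_classify import categorize_genes

        q = hierarchical_correct({"A": [("v1", 1e-5)], "B": [("v1", 1e-5)],
                                  "C": [("v1", 0.9)]})
        x = hierarchical_correct({"A": [("v1", 1e-5)], "B": [("v1", 0.9)],
                                  "C": [("v1", 1e-5)]})
        cats = categorize_genes(q, x)
        assert cats == {"A": "shared", "B": "qqtl_only", "C": "xqtl_only"}
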