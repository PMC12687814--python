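"""Quantile TWAS: pruning, weight training, regions, LD-aware association."""

import numpy as np
import pytest
from scipy import stats

from quantqtl.io_formats import LdMatrix
from quantqtl.qtwas import (
    WeightMatrix,
    estimate_weights,
    gene_assoc,
    integrate_weights,
    make_dynamic_regions,
    make_fixed_regions,
    region_assoc,
    select_and_prune,
)
from quantqtl.quantile_core import QuantileGrid


def _wm(weights, gene="G1"):
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    p, T = W.shape
    taus = np.round(np.arange(1, T + 1) / (T + 1), 6)
    return WeightMatrix(gene, [f"v{j}" for j in range(p)], taus, W)


class TestSelectAndPrune:
    def test_high_ld_pair_pruned(self):
        r = np.sqrt(0.95)
        ld = LdMatrix(["a", "b"], np.array([[1, r], [r, 1]]))
        assert select_and_prune([("a", 1e-9), ("b", 1e-6)], ld) == ["a"]

    def test_absent_variant_dropped(self, caplog):
        ld = LdMatrix(["a"], np.eye(1))
        with caplog.at_level("INFO"):
            kept = select_and_prune([("a", 1e-9), ("zzz", 1e-6)], ld)
        assert kept == ["a"]

    def test_low_ld_all_retained(self):
        sigma = np.full((3, 3), 0.3)
        np.fill_diagonal(sigma, 1.0)
        ld = LdMatrix(["a", "b", "c"], sigma)
        kept = select_and_prune([("a", 1e-9), ("b", 1e-8), ("c", 1e-7)], ld)
        assert sorted(kept) == ["a", "b", "c"]


class TestEstimateWeights:
    def test_location_model_recovery(self, rng):
        # single causal variant with constant effect: weights flat in tau
        n = 1500
        G = rng.binomial(2, 0.3, n).astype(float)
        Y = 0.5 * G + rng.normal(size=n)
        from quantqtl.synthio import gen_genotypes

        dm = gen_genotypes(n, 1, 0.3, rng)
        dm.dosages[:, 0] = G
        grid = QuantileGrid(np.round(np.arange(1, 10) * 0.1, 2))
        W = estimate_weights("g", Y, dm, None, grid=grid, standardize=False)
        assert np.all(np.abs(W.weights[0] - 0.5) < 0.15)

    def test_null_weights_near_zero(self, rng):
        # per-tau slope estimates are correlated across tau, so a single
        # draw's tau-average has SE ~ 0.04 at n=2000; average over draws
        n, draws = 2000, 6
        from quantqtl.synthio import gen_genotypes

        grid = QuantileGrid(np.round(np.arange(1, 10) * 0.1, 2))
        means = []
        for _ in range(draws):
            dm = gen_genotypes(n, 1, 0.3, rng)
            Y = rng.normal(size=n)
            W = estimate_weights("g", Y, dm, None, grid=grid,
                                 standardize=False)
            means.append(W.weights[0].mean())
        assert abs(np.mean(means)) < 0.05
        assert np.max(np.abs(means)) < 0.15

    def test_collinear_variant_dropped_deterministically(self, rng, caplog):
        from quantqtl.io_formats import DosageMatrix, VariantRecord

        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        dm = DosageMatrix(
            [f"S{i}" for i in range(n)],
            [VariantRecord("v0", "1", 1, "A", "G"),
             VariantRecord("v1", "1", 2, "A", "G")],
            np.column_stack([g, g]),  # identical columns
        )
        with caplog.at_level("INFO"):
            W = estimate_weights("g", rng.normal(size=n), dm, None,
                                 grid=QuantileGrid([0.5]), standardize=False)
        assert W.variant_ids == ["v0"]


class TestRegions:
    def test_fixed_regions_three_thirds(self):
        rs = make_fixed_regions()
        assert [len(r) for r in rs.regions] == [33, 33, 33]
        assert np.concatenate(rs.regions).tolist() == list(range(99))

    def test_dynamic_constant_weights_single_region(self):
        W = _wm(np.full((2, 99), 0.4))
        rs = make_dynamic_regions(W)
        assert rs.K == 1

    def test_dynamic_sign_flip_boundary_near_half(self):
        # scale-model weight pattern: antisymmetric sign flip at tau = 0.5
        taus = np.round(np.arange(1, 100) * 0.01, 2)
        w = 0.5 * stats.norm.ppf(taus)
        W = WeightMatrix("g", ["v0"], taus, w[None, :])
        rs = make_dynamic_regions(W)
        assert 2 <= rs.K <= 10
        boundaries = [taus[r[0]] for r in rs.regions[1:]]
        assert any(0.45 <= b <= 0.55 for b in boundaries)

    def test_k_cap_respected(self, rng):
        W = _wm(rng.normal(size=(3, 99)))
        rs = make_dynamic_regions(W, k_max=4)
        assert rs.K <= 4
        assert all(len(r) >= 3 for r in rs.regions)

    def test_integrate_weights_partition_conservation(self, rng):
        W = _wm(rng.normal(size=(2, 12)))
        rs = make_fixed_regions(12)
        omegas = integrate_weights(W, rs)
        np.testing.assert_allclose(
            sum(omegas), W.weights.sum(axis=1), atol=1e-12
        )

    def test_integrate_weights_hand_toy(self):
        W = _wm([[1.0, 2, 3, 4], [10, 20, 30, 40]])
        rs = make_fixed_regions(4)  # regions [0], [1], [2,3]
        omegas = integrate_weights(W, rs)
        np.testing.assert_allclose(omegas[0], [1, 10])
        np.testing.assert_allclose(omegas[1], [2, 20])
        np.testing.assert_allclose(omegas[2], [7, 70])


class TestRegionAssoc:
    def test_single_variant_identity(self):
        Z, p = region_assoc([1.0], [3.0], np.eye(1))
        assert Z == pytest.approx(3.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        w = rng.normal(size=4)
        z = rng.normal(size=4)
        sigma = np.full((4, 4), 0.3)
        np.fill_diagonal(sigma, 1.0)
        Z1, _ = region_assoc(w, z, sigma)
        Z2, _ = region_assoc(7.3 * w, z, sigma)
        assert Z1 == pytest.approx(Z2, abs=1e-10)

    def test_two_variant_hand_value(self):
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        Z, p = region_assoc([1.0, 1.0], [2.0, 2.0], sigma)
        assert Z == pytest.approx(4 / np.sqrt(3), abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(4 / np.sqrt(3)), abs=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            region_assoc([1.0, 2.0], [1.0], np.eye(1))

    def test_null_calibration(self, rng):
        # z ~ MVN(0, Sigma) with arbitrary weights: tail-calibrated
        p_dim = 12
        A = rng.normal(size=(p_dim, 3 * p_dim))
        sigma = np.corrcoef(A)
        L = np.linalg.cholesky(sigma + 1e-10 * np.eye(p_dim))
        w = rng.normal(size=p_dim)
        hits = 0
        n_draws = 2000
        for _ in range(n_draws):
            z = L @ rng.normal(size=p_dim)
            _, p = region_assoc(w, z, sigma)
            hits += p < 0.05
        assert 0.035 <= hits / n_draws <= 0.065


class TestGeneAssoc:
    def test_single_region_passthrough(self):
        res = gene_assoc("g", [(2.0, 0.03)])
        assert res.combined_p == pytest.approx(0.03, abs=1e-12)

    def test_equal_region_ps_fixed_point(self):
        res = gene_assoc("g", [(1.0, 0.01), (-1.0, 0.01), (2.0, 0.01)])
        assert res.combined_p == pytest.approx(0.01, abs=1e-10)

    def test_bonferroni_family(self):
        res = gene_assoc("g", [(4.0, 1e-6)], n_tests_in_family=100)
        assert res.significant
        res2 = gene_assoc("g", [(2.0, 0.01)], n_tests_in_family=100)
        assert not res2.significant

    def test_no_regions_raises(self):
        with pytest.raises(ValueError):
            gene_assoc("g", [])


class TestAlleleFlipEquivariance:
    def test_flipping_alleles_and_z_preserves_absolute_Z(self, rng):
        # flip in the GWAS table -> harmonized z flips -> |Z_k| unchanged
        import pandas as pd

        from quantqtl.io_formats import GwasSummary, VariantRecord, harmonize_gwas

        variants = [VariantRecord(f"v{j}", "1", 100 + j, "A", "G")
                    for j in range(4)]
        z = rng.normal(size=4)
        base = pd.DataFrame({
            "id": [v.id for v in variants], "chrom": "1",
            "pos": [v.pos for v in variants],
            "a1": "G", "a2": "A", "z": z,
        })
        flipped = base.assign(a1="A", a2="G", z=-z)
        m1 = harmonize_gwas(GwasSummary(base), variants)
        m2 = harmonize_gwas(GwasSummary(flipped), variants)
        sigma = np.full((4, 4), 0.2)
        np.fill_diagonal(sigma, 1.0)
        w = rng.normal(size=4)
        Z1, _ = region_assoc(w, m1["z"].to_numpy(), sigma)
        Z2, _ = region_assoc(w, m2["z"].to_numpy(), sigma)
        assert abs(Z1) == pytest.approx(abs(Z2), abs=1e-12)
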