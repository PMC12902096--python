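"""Metagene aggregation, soft threshold, TOM, modules, eigengenes, traits."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from salinomics import network as nw
from salinomics import synthetic as syn
from salinomics.core_io import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneOrthogroupMap,
    SampleTraits,
    ValidationError,
)


def _toy_expression():
    genes_a = pd.DataFrame(
        {"a1": [1.0, 2.0, 3.0], "a2": [4.0, 5.0, 6.0]},
        index=["gA1", "gA2", "gA3"],
    )
    genes_b = pd.DataFrame(
        {"b1": [7.0, 8.0], "b2": [9.0, 10.0]}, index=["gB1", "gB2"]
    )
    gmap = GeneOrthogroupMap(pd.DataFrame([
        dict(gene_id="gA1", species_id="A", orthogroup_id="OG1"),
        dict(gene_id="gA2", species_id="A", orthogroup_id="OG1"),
        dict(gene_id="gA3", species_id="A", orthogroup_id="OG2"),
        dict(gene_id="gB1", species_id="B", orthogroup_id="OG1"),
        dict(gene_id="gB2", species_id="B", orthogroup_id="OG2"),
    ]))
    return (
        [ExpressionMatrix(genes_a, "A"), ExpressionMatrix(genes_b, "B")],
        gmap,
    )


class TestAggregation:
    def test_sums_member_genes_and_intersects_orthogroups(self):
        exprs, gmap = _toy_expression()
        mm = nw.aggregate_metagenes(exprs, gmap)
        assert sorted(mm.orthogroup_ids) == ["OG1", "OG2"]
        assert mm.sample_ids == ["a1", "a2", "b1", "b2"]
        # OG1 in species A is gA1 + gA2
        assert mm.values.loc["OG1", "a1"] == 1.0 + 2.0
        assert mm.values.loc["OG1", "b2"] == 9.0
        # provenance records member-gene counts per species
        assert mm.provenance.loc["OG1", "A"] == 2
        assert mm.provenance.loc["OG1", "B"] == 1

    def test_orthogroup_missing_in_one_species_is_dropped(self):
        exprs, gmap = _toy_expression()
        # remove OG2's only gene in species B
        gm2 = GeneOrthogroupMap(gmap.table[gmap.table["gene_id"] != "gB2"])
        exprs[1] = ExpressionMatrix(exprs[1].values.drop(index="gB2"), "B")
        mm = nw.aggregate_metagenes(exprs, gm2)
        assert mm.orthogroup_ids == ["OG1"]

    def test_duplicate_sample_ids_rejected(self):
        exprs, gmap = _toy_expression()
        clash = ExpressionMatrix(
            exprs[1].values.rename(columns={"b1": "a1"}), "B"
        )
        with pytest.raises(ValidationError, match="duplicate sample"):
            nw.aggregate_metagenes([exprs[0], clash], gmap)

    def test_synthetic_aggregation_recovers_metagenes_exactly(self):
        exprs, gmap, _, _ = syn.simulate_expression(
            n_metagenes=130, noise_sd=0.0, seed=5
        )
        mm = nw.aggregate_metagenes(exprs, gmap)
        # gene splitting uses fixed weights summing to 1, so per-sample sums
        # differ across orthogroups only by the planted latent structure
        assert mm.values.shape == (130, 24)
        assert np.isfinite(mm.values.to_numpy()).all()


class TestAdjacency:
    def test_unsigned_adjacency_is_abs_cor_power(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 15))
        adj = nw.adjacency_matrix(x, power=7)
        cor = np.corrcoef(x)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(adj[off], np.abs(cor[off]) ** 7, atol=1e-12)
        np.testing.assert_allclose(np.diag(adj), 1.0)

    def test_signed_variant_kills_negative_correlation(self):
        x = np.vstack([np.arange(10.0), -np.arange(10.0)])
        adj = nw.adjacency_matrix(x, power=2, signed=True)
        assert adj[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestTOM:
    @staticmethod
    def _triple_loop(adj):
        a = adj.copy()
        np.fill_diagonal(a, 0.0)
        n = a.shape[0]
        k = a.sum(axis=1)
        tom = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j]
                        for u in range(n) if u != i and u != j)
                tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
        return tom

    def test_matches_triple_loop_oracle_on_random_networks(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=(10, 8))
            adj = nw.adjacency_matrix(x, power=6)
            got = nw.tom_similarity(adj)
            want = self._triple_loop(adj)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_hand_example_two_shared_neighbors(self):
        # nodes 0 and 1 fully connected to node 2 and each other
        adj = np.ones((3, 3))
        tom = nw.tom_similarity(adj)
        # l_{01} = a02*a21 = 1, k = 2, so (1 + 1) / (2 + 1 - 1) = 1
        assert tom[0, 1] == pytest.approx(1.0)

    def test_bounded_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(15, 10))
        tom = nw.tom_similarity(nw.adjacency_matrix(x, power=3))
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestSoftThreshold:
    def test_smallest_passing_power_is_chosen(self):
        exprs, gmap, _, _ = syn.simulate_expression(seed=0)
        mm = nw.drop_constant_rows(nw.aggregate_metagenes(exprs, gmap))
        power, table = nw.pick_soft_threshold(mm, list(range(1, 13)), r2_min=0.2)
        passing = table.loc[table["fit_index"] > 0.2, "power"]
        if len(passing):
            assert power == passing.min()
        assert set(table["power"]) == set(range(1, 13))

    def test_failure_is_flagged_not_fatal(self):
        exprs, gmap, _, _ = syn.simulate_expression(seed=0)
        mm = nw.drop_constant_rows(nw.aggregate_metagenes(exprs, gmap))
        power, table = nw.pick_soft_threshold(mm, [1, 2], r2_min=0.999)
        assert not table["passed"].any()
        assert power in (1, 2)

    def test_scale_free_fit_is_signed(self):
        # a power-law-like degree distribution scores close to +1
        k = np.repeat([1.0, 2.0, 4.0, 8.0, 16.0], [16, 8, 4, 2, 1])
        assert nw.scale_free_fit(k, n_bins=5) > 0.95
        # the sign flips when frequency rises with connectivity
        k_up = np.repeat([1.0, 2.0, 4.0, 8.0, 16.0], [1, 2, 4, 8, 16])
        assert nw.scale_free_fit(k_up, n_bins=5) < 0


class TestModules:
    def test_block_diagonal_network_recovers_blocks(self):
        rng = np.random.default_rng(3)
        f1, f2 = rng.normal(size=(2, 20))
        block = lambda f, n: f[None, :] * 0.95 + rng.normal(0, 0.1, (n, 20))  # noqa: E731
        x = np.vstack([block(f1, 40), block(f2, 40)])
        tom = nw.tom_similarity(nw.adjacency_matrix(x, power=6))
        labels = nw.detect_modules(tom, [f"g{i}" for i in range(80)],
                                   min_size=30, cut_height=0.99)
        truth = ["A"] * 40 + ["B"] * 40
        assert adjusted_rand_score(truth, list(labels)) == pytest.approx(1.0)
        # deterministic naming: larger-or-earlier block is M1
        assert set(labels) == {"M1", "M2"}

    def test_pure_noise_is_all_grey(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 20))
        tom = nw.tom_similarity(nw.adjacency_matrix(x, power=6))
        labels = nw.detect_modules(tom, [f"g{i}" for i in range(60)],
                                   min_size=30, cut_height=0.2)
        assert (labels == nw.GREY).all()

    def test_min_size_bound(self):
        with pytest.raises(ValidationError):
            nw.detect_modules(np.eye(3), ["a", "b", "c"], min_size=1)


class TestEigengene:
    def test_orientation_and_unit_scale(self):
        rng = np.random.default_rng(5)
        f = np.linspace(-1, 1, 12)
        x = f[None, :] * rng.uniform(0.5, 1.5, (35, 1)) + rng.normal(
            0, 0.05, (35, 12)
        )
        mm = nw.MetageneMatrix(
            pd.DataFrame(x, index=[f"g{i}" for i in range(35)],
                         columns=[f"s{i}" for i in range(12)]),
            pd.DataFrame(index=[f"g{i}" for i in range(35)]),
        )
        labels = pd.Series("M1", index=mm.orthogroup_ids)
        eg = nw.module_eigengene(mm, labels)
        profile = eg.loc["M1"].to_numpy()
        # sign matches the mean member profile
        mean_profile = ((x - x.mean(1, keepdims=True))
                        / x.std(1, keepdims=True)).mean(0)
        assert np.corrcoef(profile, mean_profile)[0, 1] > 0.99

    def test_explains_most_variance_of_tight_module(self):
        rng = np.random.default_rng(6)
        f = rng.normal(size=16)
        x = f[None, :] + rng.normal(0, 0.05, (40, 16))
        mm = nw.MetageneMatrix(
            pd.DataFrame(x, index=[f"g{i}" for i in range(40)],
                         columns=[f"s{i}" for i in range(16)]),
            pd.DataFrame(index=[f"g{i}" for i in range(40)]),
        )
        labels = pd.Series("M1", index=mm.orthogroup_ids)
        eg = nw.module_eigengene(mm, labels).loc["M1"].to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        # projection onto the eigengene captures > 90% of z-scored variance
        egn = eg / np.linalg.norm(eg)
        explained = ((z @ egn) ** 2).sum() / (z**2).sum()
        assert explained > 0.9

    def test_all_grey_rejected(self):
        mm = nw.MetageneMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["g0"], columns=["s0", "s1"]),
            pd.DataFrame(index=["g0"]),
        )
        with pytest.raises(ValidationError):
            nw.module_eigengene(mm, pd.Series(nw.GREY, index=["g0"]))


class TestModuleTrait:
    def _mm_with_trait(self):
        sids = [f"s{i}" for i in range(12)]
        trait = np.linspace(0, 11, 12)
        traits = SampleTraits(pd.DataFrame({
            "severity": trait, "duration": np.zeros(12) + 3,
            "damage": np.tile([0, 1], 6), "mem25_specific": np.zeros(12),
        }, index=sids))
        eg = pd.DataFrame([trait - trait.mean()], index=["M1"], columns=sids)
        return eg, traits

    def test_inclusive_significance_boundaries(self):
        eg, traits = self._mm_with_trait()
        mt = nw.module_trait(eg, traits, r_min=1.0, p_max=1.0)
        row = mt[(mt["module"] == "M1") & (mt["trait"] == "severity")].iloc[0]
        # perfect correlation: |r| = 1 >= r_min exactly, still significant
        assert row["r"] == pytest.approx(1.0)
        assert bool(row["significant"])

    def test_constant_trait_is_nan_and_not_significant(self):
        eg, traits = self._mm_with_trait()
        mt = nw.module_trait(eg, traits, r_min=0.1, p_max=1.0)
        row = mt[(mt["module"] == "M1") & (mt["trait"] == "duration")].iloc[0]
        assert np.isnan(row["r"])
        assert not bool(row["significant"])

    def test_pearson_p_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 30))
        r, p = nw.pearson_with_p(x, y)
        want = stats.pearsonr(x, y)
        assert r == pytest.approx(want.statistic, abs=1e-12)
        assert p == pytest.approx(want.pvalue, rel=1e-9)
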