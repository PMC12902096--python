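"""Metabolite DA, transcript-metabolite network, triage rules, summary stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from salinomics import integrate as it
from salinomics.core_io import (
    MetaboliteMatrix,
    OrthogroupCounts,
    ValidationError,
)


def _mets(values, reps=3, conditions=("control", "salt")):
    cols = ([f"{conditions[0]}_r{i}" for i in range(reps)]
            + [f"{conditions[1]}_r{i}" for i in range(reps)])
    cond = pd.Series([conditions[0]] * reps + [conditions[1]] * reps,
                     index=cols)
    return MetaboliteMatrix(
        pd.DataFrame(values, columns=cols,
                     index=[f"m{i}" for i in range(len(values))]),
        cond,
    )


class TestMetaboliteDA:
    def test_log2fc_direction_and_welch_p(self):
        mm = _mets([[10, 10, 10, 40, 40, 40.5]])
        (res,) = it.metabolite_da(mm, "control", "salt")
        assert res.log2fc == pytest.approx(np.log2(40.16666667 / 10), rel=1e-6)
        a = np.log2([10, 10, 10.0])
        b = np.log2([40, 40, 40.5])
        want = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert res.p == pytest.approx(want, rel=1e-9)

    def test_inclusive_boundaries(self):
        # exactly 2-fold change with zero within-group noise: |lfc| == 1
        mm = _mets([[10, 10, 10, 20, 20, 20.0]])
        (res,) = it.metabolite_da(mm, "control", "salt",
                                  log2fc_min=1.0, p_max=0.05)
        assert res.log2fc == pytest.approx(1.0)
        assert res.significant  # >= is inclusive

    def test_fold_change_alone_is_not_enough(self):
        # large fold change but huge within-group spread: p fails
        mm = _mets([[1, 100, 1, 8, 800, 8.0]])
        (res,) = it.metabolite_da(mm, "control", "salt")
        assert abs(res.log2fc) >= 1
        assert not res.significant

    def test_requires_two_replicates(self):
        cols = ["a", "b"]
        mm = MetaboliteMatrix(
            pd.DataFrame([[1.0, 2.0]], columns=cols, index=["m0"]),
            pd.Series(["control", "salt"], index=cols),
        )
        with pytest.raises(ValidationError):
            it.metabolite_da(mm, "control", "salt")


class TestNetwork:
    def _random_profiles(self, seed, n_cond=8):
        rng = np.random.default_rng(seed)
        g = [it.FoldChangeProfile(f"g{i}", "orthogroup",
                                  rng.normal(size=n_cond)) for i in range(10)]
        m = [it.FoldChangeProfile(f"m{i}", "metabolite",
                                  rng.normal(size=n_cond)) for i in range(8)]
        # plant one strong positive and one strong negative pair
        m[0] = it.FoldChangeProfile(
            "m0", "metabolite", g[0].log2fc * 2 + rng.normal(0, 1e-3, n_cond))
        m[1] = it.FoldChangeProfile(
            "m1", "metabolite", -g[1].log2fc * 2 + rng.normal(0, 1e-3, n_cond))
        return g, m

    def test_matches_brute_force_filter(self):
        for seed in range(5):
            g, m = self._random_profiles(seed)
            edges = it.transcript_metabolite_network(g, m, 0.90, 0.001)
            want = set()
            for gp in g:
                for mp in m:
                    r, p = stats.pearsonr(gp.log2fc, mp.log2fc)
                    if r > 0.90 and p < 0.001:
                        want.add((gp.entity_id, mp.entity_id))
            assert {(e.orthogroup_id, e.metabolite_id) for e in edges} == want

    def test_negative_correlation_is_excluded(self):
        g, m = self._random_profiles(0)
        edges = it.transcript_metabolite_network(g, m, 0.90, 0.001)
        pairs = {(e.orthogroup_id, e.metabolite_id) for e in edges}
        assert ("g0", "m0") in pairs  # positive planted pair
        assert ("g1", "m1") not in pairs  # anti-correlated pair: one-sided rule

    def test_sorted_by_descending_correlation(self):
        g, m = self._random_profiles(1)
        edges = it.transcript_metabolite_network(g, m, 0.0, 1.0)
        pccs = [e.pcc for e in edges]
        assert pccs == sorted(pccs, reverse=True)

    def test_short_profiles_rejected(self):
        g = [it.FoldChangeProfile("g0", "orthogroup", np.array([1.0, 2.0]))]
        m = [it.FoldChangeProfile("m0", "metabolite", np.array([1.0, 2.0]))]
        with pytest.raises(ValidationError):
            it.transcript_metabolite_network(g, m)

    def test_constant_profile_is_skipped(self):
        g = [it.FoldChangeProfile("g0", "orthogroup", np.zeros(5))]
        m = [it.FoldChangeProfile("m0", "metabolite", np.arange(5.0))]
        assert it.transcript_metabolite_network(g, m) == []


class TestTriage:
    def _setup(self):
        expr = pd.DataFrame(
            {
                "focal_mean": [1.0, 5.0, 5.0, 1.0],
                "fresh_mean": [4.0, 1.0, 1.0, 4.0],
                "focal_high": [2.0, 1.0, 2.0, 2.0],
                "focal_low": [1.0, 3.0, 1.0, 1.0],
            },
            index=["OG0", "OG1", "OG2", "OG3"],
        )
        module_of = pd.Series(
            {"OG0": "M1", "OG1": "M2", "OG2": "M1", "OG3": "grey"}
        )
        ann = {
            "M1": it.ModuleAnnotation("M1", True, False, False),
            "M2": it.ModuleAnnotation("M2", False, True, True),
        }
        counts = OrthogroupCounts(pd.DataFrame(
            {
                "MEM25": [1, 1, 2, 1],
                "fw1": [3, 1, 1, 5],
                "fw2": [2, 1, 1, 5],
            },
            index=["OG0", "OG1", "OG2", "OG3"],
        ).astype(np.int64))
        return expr, module_of, ann, counts

    def test_rules_match_hand_evaluation(self):
        expr, module_of, ann, counts = self._setup()
        cands = it.triage_candidates(
            expr, module_of, ann, counts, "MEM25", ["fw1", "fw2"]
        )
        got = {(c.orthogroup_id, c.strategy) for c in cands}
        # OG0: fresh > focal in fresh-associated non-specific module (rule 1)
        #      and copy-expanded in both freshwater species (rule 3)
        # OG1: focal_high < focal_low in salt-associated specific module (rule 2)
        # OG2: fresh_mean < focal_mean, copies not expanded -> nothing
        # OG3: grey module -> skipped despite qualifying numbers
        assert got == {("OG0", 1), ("OG0", 3), ("OG1", 2)}

    def test_mean_comparator_differs_from_majority(self):
        expr, module_of, ann, counts = self._setup()
        # OG2: copies fw=(1,1) vs focal 2: neither comparator fires; make
        # one freshwater species hugely expanded so only the mean fires
        counts2 = OrthogroupCounts(
            counts.counts.assign(fw1=[3, 1, 9, 5]).astype(np.int64)
        )
        majority = it.triage_candidates(
            expr, module_of, ann, counts2, "MEM25", ["fw1", "fw2"],
            expansion_comparator="majority",
        )
        mean = it.triage_candidates(
            expr, module_of, ann, counts2, "MEM25", ["fw1", "fw2"],
            expansion_comparator="mean",
        )
        og2_major = {(c.orthogroup_id, c.strategy) for c in majority
                     if c.orthogroup_id == "OG2"}
        og2_mean = {(c.orthogroup_id, c.strategy) for c in mean
                    if c.orthogroup_id == "OG2"}
        assert og2_major == set()
        assert og2_mean == {("OG2", 3)}

    def test_missing_annotation_rejected(self):
        expr, module_of, ann, counts = self._setup()
        del ann["M2"]
        with pytest.raises(ValidationError, match="M2"):
            it.triage_candidates(expr, module_of, ann, counts,
                                 "MEM25", ["fw1", "fw2"])

    def test_missing_columns_rejected(self):
        expr, module_of, ann, counts = self._setup()
        with pytest.raises(ValidationError, match="fresh_mean"):
            it.triage_candidates(expr.drop(columns="fresh_mean"), module_of,
                                 ann, counts, "MEM25", ["fw1"])

    def test_strategy1_monotone_in_fresh_expression(self):
        expr, module_of, ann, counts = self._setup()
        # raising fresh_mean can only add rule-1 candidates, never remove
        base = {(c.orthogroup_id, c.strategy) for c in it.triage_candidates(
            expr, module_of, ann, counts, "MEM25", ["fw1", "fw2"]
        ) if c.strategy == 1}
        boosted = expr.assign(fresh_mean=expr["fresh_mean"] + 10)
        more = {(c.orthogroup_id, c.strategy) for c in it.triage_candidates(
            boosted, module_of, ann, counts, "MEM25", ["fw1", "fw2"]
        ) if c.strategy == 1}
        assert base <= more


class TestSummaryStats:
    def test_wald_t_p_and_ci(self):
        s = it.wald_stats(beta=2.0, se=0.5, df=10)
        assert s.t == pytest.approx(4.0)
        assert s.p == pytest.approx(2 * stats.t.sf(4.0, df=10), rel=1e-12)
        crit = stats.t.ppf(0.975, df=10)
        assert s.ci95[0] == pytest.approx(2.0 - crit * 0.5)
        assert s.ci95[1] == pytest.approx(2.0 + crit * 0.5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            it.wald_stats(1.0, 0.0, 10)
        with pytest.raises(ValidationError):
            it.wald_stats(1.0, 1.0, 0)

    def test_bh_hand_example(self):
        adj = it.multiple_testing(np.array([0.01, 0.02, 0.03]), method="bh")
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03], atol=1e-12)

    def test_bonferroni_and_override(self):
        adj = it.multiple_testing(np.array([0.01, 0.4]), method="bonferroni")
        np.testing.assert_allclose(adj, [0.02, 0.8])
        adj = it.multiple_testing(np.array([0.01]), method="bonferroni",
                                  m_override=100)
        np.testing.assert_allclose(adj, [1.0])
        assert it.bonferroni_threshold(0.05, 10) == pytest.approx(0.005)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_bh_properties(self, ps):
        p = np.asarray(ps)
        adj = it.multiple_testing(p, method="bh")
        assert ((adj >= p - 1e-12) & (adj <= 1 + 1e-12)).all()
        # BH preserves the significance ordering
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
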