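import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasig import (bh_fdr, cohort_effects, dersimonian_laird, fisher_combine,
                     hedges_g, meta_analyze, select_significant)
from metasig.meta import PooledGene

from conftest import make_cohort
from oracles import (oracle_bh, oracle_dersimonian_laird, oracle_fisher,
                     oracle_hedges_g)


class TestHedgesG:
    def test_hand_computed_example(self):
        # means 3 vs 1, pooled SD 1, J = 0.8 -> g = 1.6, v = 6/9 + 1.6^2/12
        g, v, p = hedges_g([2, 3, 4], [0, 1, 2])
        assert g == pytest.approx(1.6, abs=1e-12)
        assert v == pytest.approx(0.88, abs=1e-12)
        assert 0 < p < 1

    def test_identical_groups_give_zero_effect(self):
        g, v, p = hedges_g([2, 3, 4], [2, 3, 4])
        assert g == 0.0
        assert p == pytest.approx(1.0)

    def test_group_swap_negates_g_preserves_v(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 2, 9)
        g1, v1, p1 = hedges_g(a, b)
        g2, v2, p2 = hedges_g(b, a)
        assert g2 == pytest.approx(-g1, abs=1e-12)
        assert v2 == pytest.approx(v1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_rejects_small_groups_and_zero_variance(self):
        with pytest.raises(ValueError, match=">= 2"):
            hedges_g([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="pooled variance"):
            hedges_g([1.0, 1.0], [1.0, 1.0])

    @given(st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_independent_formula(self, data):
        floats = st.floats(-50, 50)
        case = data.draw(st.lists(floats, min_size=2, max_size=12))
        control = data.draw(st.lists(floats, min_size=2, max_size=12))
        if np.var(case + control) == 0 or (np.var(case, ddof=1) == 0 and np.var(control, ddof=1) == 0):
            return
        g, v, p = hedges_g(case, control)
        og, ov, op = oracle_hedges_g(case, control)
        assert g == pytest.approx(og, abs=1e-9)
        assert v == pytest.approx(ov, abs=1e-9)
        assert p == pytest.approx(op, abs=1e-9)


class TestDersimonianLaird:
    def test_hand_computed_example(self):
        pooled, se, tau2, q = dersimonian_laird([0.5, 1.5], [0.1, 0.1])
        assert pooled == pytest.approx(1.0, abs=1e-12)
        assert se == pytest.approx(0.5, abs=1e-12)
        assert tau2 == pytest.approx(0.4, abs=1e-12)
        assert q == pytest.approx(5.0, abs=1e-12)

    def test_single_study_passthrough(self):
        assert dersimonian_laird([0.7], [0.2]) == pytest.approx(
            (0.7, np.sqrt(0.2), 0.0, 0.0))

    def test_zero_heterogeneity_with_identical_effects(self):
        pooled, se, tau2, q = dersimonian_laird([0.9] * 4, [0.3] * 4)
        assert pooled == pytest.approx(0.9)
        assert tau2 == 0.0
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_tau2_zero_reduces_to_fixed_effect(self):
        # effects so close that Q < k-1 forces tau^2 to clip at zero
        g = [1.0, 1.001, 0.999]
        v = [0.5, 0.4, 0.6]
        pooled, se, tau2, _ = dersimonian_laird(g, v)
        assert tau2 == 0.0
        w = 1 / np.asarray(v)
        assert pooled == pytest.approx(float(w @ g / w.sum()), abs=1e-12)
        assert se == pytest.approx(float(1 / np.sqrt(w.sum())), abs=1e-12)

    def test_rejects_empty_and_nonpositive_variance(self):
        with pytest.raises(ValueError):
            dersimonian_laird([], [])
        with pytest.raises(ValueError):
            dersimonian_laird([1.0], [0.0])


class TestFisherCombine:
    def test_frozen_example(self):
        stat, p = fisher_combine([0.05, 0.05])
        assert stat == pytest.approx(11.982929, abs=1e-5)
        assert p == pytest.approx(0.017479, abs=1e-5)

    def test_boundary_all_ones(self):
        stat, p = fisher_combine([1.0, 1.0])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_single_p_recovered_by_chi2_identity(self):
        stat, p = fisher_combine([0.3])
        assert p == pytest.approx(0.3, abs=1e-12)

    def test_monotone_in_each_component(self):
        _, p_base = fisher_combine([0.2, 0.4, 0.6])
        _, p_smaller = fisher_combine([0.2, 0.1, 0.6])
        assert p_smaller <= p_base

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            fisher_combine([])


class TestBHFDR:
    def test_hand_stepped_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04], abs=1e-12)

    def test_single_and_equal_p_are_fixed_points(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_q_at_least_p_and_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        q_sm = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(p) == pytest.approx(q_sm, abs=1e-12)


class TestCohortEffects:
    def test_one_effect_per_variable_gene(self, small_cohorts):
        effects = cohort_effects(small_cohorts[0])
        assert len(effects) == 3
        assert {e.gene for e in effects} == {"SEP", "NOISE1", "NOISE2"}

    def test_constant_gene_excluded(self):
        cohort = make_cohort("D", ["FLAT", "VAR"],
                             [[1, 1, 1], [0.5, 1.2, 0.3]],
                             [[1, 1, 1], [2.0, 1.5, 2.5]])
        effects = cohort_effects(cohort)
        assert [e.gene for e in effects] == ["VAR"]

    def test_sample_permutation_invariance(self, small_cohorts):
        cohort = small_cohorts[0]
        rng = np.random.default_rng(2)
        perm = rng.permutation(cohort.samples)
        shuffled = type(cohort)(cohort.dataset_id, cohort.values[perm],
                                cohort.labels.loc[perm])
        for a, b in zip(cohort_effects(cohort), cohort_effects(shuffled)):
            assert a.g == pytest.approx(b.g, abs=1e-12)

    def test_agrees_with_scalar_hedges_g(self, small_cohorts):
        cohort = small_cohorts[0]
        for eff in cohort_effects(cohort):
            row = cohort.values.loc[eff.gene]
            g, v, p = hedges_g(row[cohort.labels == "case"],
                               row[cohort.labels == "control"])
            assert (eff.g, eff.v, eff.p) == pytest.approx((g, v, p), abs=1e-12)


class TestMetaAnalyze:
    def test_pooling_matches_scalar_route(self, small_cohorts):
        pooled = {pg.gene: pg for pg in meta_analyze(small_cohorts)}
        per_cohort = [
            {e.gene: e for e in cohort_effects(c)}
            for c in sorted(small_cohorts, key=lambda c: c.dataset_id)
        ]
        for gene, pg in pooled.items():
            g = [eff[gene].g for eff in per_cohort]
            v = [eff[gene].v for eff in per_cohort]
            mu, se, tau2, q = dersimonian_laird(g, v)
            assert pg.pooled_g == pytest.approx(mu, abs=1e-10)
            assert pg.se == pytest.approx(se, abs=1e-10)
            assert pg.tau2 == pytest.approx(tau2, abs=1e-10)
            assert pg.Q == pytest.approx(q, abs=1e-10)
            stat, fp = fisher_combine([eff[gene].p for eff in per_cohort])
            assert pg.fisher_stat == pytest.approx(stat, abs=1e-10)
            assert pg.fisher_p == pytest.approx(fp, abs=1e-10)
            assert pg.k == 2

    def test_constant_gene_in_one_cohort_pooled_with_smaller_k(self):
        a = make_cohort("A", ["X", "Y"], [[1, 1, 1], [0.1, 0.5, 0.9]],
                        [[1, 1, 1], [1.5, 2.0, 2.5]])
        b = make_cohort("B", ["X", "Y"], [[0.3, 0.6, 0.9], [0.2, 0.4, 0.6]],
                        [[1.2, 1.4, 1.6], [1.8, 2.0, 2.2]])
        by_gene = {pg.gene: pg for pg in meta_analyze([a, b])}
        assert by_gene["X"].k == 1
        assert by_gene["Y"].k == 2

    def test_cohort_order_invariance(self, small_cohorts):
        fwd = meta_analyze(small_cohorts)
        rev = meta_analyze(small_cohorts[::-1])
        for x, y in zip(fwd, rev):
            assert x == y

    def test_q_never_below_fisher_p(self, planted_cohorts):
        for pg in meta_analyze(planted_cohorts[:3]):
            assert pg.q >= pg.fisher_p - 1e-15

    def test_direction_follows_pooled_sign(self, planted_cohorts):
        for pg in meta_analyze(planted_cohorts[:2]):
            assert pg.direction == ("up" if pg.pooled_g > 0 else "down")


class TestSelectSignificant:
    def _pg(self, gene, pooled_g, q):
        return PooledGene(gene, 2, pooled_g, 0.1, 0.0, 0.0, pooled_g / 0.1,
                          0.0, 10.0, q, q, "up" if pooled_g > 0 else "down")

    def test_threshold_logic(self):
        pooled = [self._pg("A", 2.5, 0.001), self._pg("B", 2.5, 0.02),
                  self._pg("C", -3.0, 0.001), self._pg("D", 1.5, 0.0001)]
        up, down = select_significant(pooled, es_min=2.0, fdr_max=0.01)
        assert [pg.gene for pg in up] == ["A"]
        assert [pg.gene for pg in down] == ["C"]

    def test_sorted_by_effect_then_symbol(self):
        pooled = [self._pg(g, es, 0.001)
                  for g, es in [("B", 2.5), ("A", 2.5), ("C", 4.0)]]
        up, _ = select_significant(pooled, es_min=2.0, fdr_max=0.01)
        assert [pg.gene for pg in up] == ["C", "A", "B"]

    def test_rejects_bad_thresholds(self):
        with pytest.raises(ValueError):
            select_significant([], es_min=0.0)
        with pytest.raises(ValueError):
            select_significant([], fdr_max=0.0)
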