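"""Correlation, enrichment, pathway similarity, recovery benchmarks."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fclmr.matching import (
    correlate_lnc_mrna,
    discovery_rate,
    expressed_universe,
    hypergeometric_enrichment,
    ortholog_recovery_rate,
    pathway_similarity,
    select_fclmr,
    top_correlated_genes,
)
from fclmr.synteny import SyntenicPair
from fclmr.types import ExpressionMatrix, OrthologMap, PathwayDB, PipelineConfig
from conftest import make_expr


class TestCorrelateLncMrna:
    def test_self_correlation_is_one(self):
        expr = make_expr({"L": [1, 5, 2, 8, 3], "G": [2, 2, 2, 2, 2]})
        corr = correlate_lnc_mrna(expr, "L", ["L"], "spearman")
        assert corr["L"] == pytest.approx(1.0)

    def test_reversed_profile_is_minus_one(self):
        expr = make_expr({"L": [1, 2, 3, 4], "G": [9, 7, 5, 3]})
        for method in ("spearman", "pearson"):
            assert correlate_lnc_mrna(expr, "L", ["G"], method)["G"] == pytest.approx(-1.0)
        ranks_only = make_expr({"L": [1, 2, 3, 4], "G": [9, 7, 5, 1]})
        assert correlate_lnc_mrna(ranks_only, "L", ["G"], "spearman")["G"] == pytest.approx(-1.0)

    def test_spearman_matches_scipy_on_five_samples(self):
        rng = np.random.default_rng(0)
        expr = make_expr({"L": list(rng.random(5)), "G1": list(rng.random(5)),
                          "G2": list(rng.random(5))})
        corr = correlate_lnc_mrna(expr, "L", ["G1", "G2"], "spearman")
        for g in ("G1", "G2"):
            expected = stats.spearmanr(expr.values.loc["L"], expr.values.loc[g]).statistic
            assert corr[g] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_flagged_undefined(self):
        expr = make_expr({"L": [1, 2, 3], "G": [5, 5, 5]})
        assert np.isnan(correlate_lnc_mrna(expr, "L", ["G"])["G"])

    def test_fewer_than_three_samples_is_error(self):
        expr = make_expr({"L": [1, 2], "G": [3, 4]})
        with pytest.raises(ValueError, match=">= 3 samples"):
            correlate_lnc_mrna(expr, "L", ["G"])


class TestTopCorrelated:
    def test_absolute_value_ranking(self):
        import pandas as pd
        corr = pd.Series({"A": 0.9, "B": -0.95, "C": 0.1})
        assert top_correlated_genes(corr, 2) == ["B", "A"]

    def test_top_n_larger_than_gene_count_returns_all(self):
        import pandas as pd
        corr = pd.Series({"A": 0.9, "B": -0.95})
        assert top_correlated_genes(corr, 10) == ["B", "A"]

    def test_tie_broken_by_gene_id(self):
        import pandas as pd
        corr = pd.Series({"E": 0.5, "D": -0.5, "F": 0.2})
        assert top_correlated_genes(corr, 2) == ["D", "E"]

    def test_all_undefined_is_error(self):
        import pandas as pd
        with pytest.raises(ValueError, match="undefined"):
            top_correlated_genes(pd.Series({"A": np.nan}), 1)


def enumeration_p(N, K, n, k_obs):
    """P(overlap >= k_obs) by exhaustive enumeration of all query draws."""
    universe = range(N)
    pathway = set(range(K))
    hits = sum(1 for q in combinations(universe, n) if len(pathway & set(q)) >= k_obs)
    return hits / comb(N, n)


class TestHypergeometricEnrichment:
    def test_worked_full_overlap_case(self):
        """Universe 10, pathway 5, query of the same 5 genes: p = 1/C(10,5)."""
        universe = {f"g{i}" for i in range(10)}
        db = PathwayDB({"P": ("P", frozenset({f"g{i}" for i in range(5)}))})
        (res,) = hypergeometric_enrichment({f"g{i}" for i in range(5)}, db, universe)
        assert res.p_value == pytest.approx(1 / 252, rel=1e-9)
        assert (res.overlap_k, res.query_n, res.pathway_K, res.universe_N) == (5, 5, 5, 10)

    def test_zero_overlap_p_at_most_one(self):
        universe = {f"g{i}" for i in range(10)}
        db = PathwayDB({"P": ("P", frozenset({"g0", "g1"}))})
        (res,) = hypergeometric_enrichment({"g8", "g9"}, db, universe)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)
        assert res.overlap_k == 0

    @given(
        N=st.integers(4, 14),
        data=st.data(),
    )
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_matches_enumeration_oracle(self, N, data):
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        universe = {f"g{i}" for i in range(N)}
        db = PathwayDB({"P": ("P", frozenset({f"g{i}" for i in range(K)}))})
        query = set(data.draw(st.permutations(sorted(universe)))[:n])
        (res,) = hypergeometric_enrichment(query, db, universe)
        k_obs = len(query & db.members("P"))
        assert res.p_value == pytest.approx(enumeration_p(N, K, n, k_obs), rel=1e-9)

    def test_query_outside_universe_is_error(self):
        db = PathwayDB({"P": ("P", frozenset({"a"}))})
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"zz"}, db, {"a", "b"})
        with pytest.raises(ValueError, match="empty universe"):
            hypergeometric_enrichment(set(), db, set())

    def test_bh_adjustment_matches_stepup_by_hand(self):
        """Raw (0.01, 0.02, 0.03) with m=3 -> adjusted (0.03, 0.03, 0.03)."""
        universe = {f"g{i}" for i in range(40)}
        # build three pathways engineered to give increasing raw p
        db = PathwayDB()
        query = {f"g{i}" for i in range(8)}
        db.add("P1", "x", {f"g{i}" for i in range(6)})
        db.add("P2", "x", {f"g{i}" for i in range(4, 12)})
        db.add("P3", "x", {f"g{i}" for i in range(30, 40)})
        results = {r.pathway_id: r for r in hypergeometric_enrichment(query, db, universe)}
        raw = np.array([results[p].p_value for p in ("P1", "P2", "P3")])
        adj = np.array([results[p].adjusted_p for p in ("P1", "P2", "P3")])
        # independent step-up computation
        order = np.argsort(raw)
        stepup = np.empty(3)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            i = 3 - 1 - rank_from_end  # zero-based rank in ascending order
            running = min(running, raw[idx] * 3 / (i + 1))
            stepup[idx] = running
        np.testing.assert_allclose(adj, stepup, rtol=1e-9)
        assert (adj >= raw - 1e-15).all()
        # literal worked triple
        hand = np.array([0.01, 0.02, 0.03])
        expected = np.array([0.03, 0.03, 0.03])
        from statsmodels.stats.multitest import multipletests
        np.testing.assert_allclose(multipletests(hand, method="fdr_bh")[1], expected)


class TestPathwaySimilarity:
    def build(self, sig_h, sig_m, config):
        def enrich(sig):
            return [
                type("E", (), {"pathway_id": p, "adjusted_p": 0.01})() for p in sig
            ]
        return pathway_similarity(enrich(sig_h), enrich(sig_m), config)

    def test_identical_sets_pass_with_jaccard_one(self, config):
        sim = self.build({"P1", "P2"}, {"P1", "P2"}, config)
        assert sim.jaccard == 1.0 and sim.passes

    def test_disjoint_sets_fail_with_jaccard_zero(self, config):
        sim = self.build({"P1"}, {"P2"}, config)
        assert sim.jaccard == 0.0 and not sim.passes

    def test_set_arithmetic(self, config):
        sim = self.build({"P1", "P2", "P3"}, {"P2", "P3", "P4"}, config)
        assert sim.shared_pathways == {"P2", "P3"}
        assert sim.jaccard == pytest.approx(0.5)

    def test_symmetric_in_arguments(self, config):
        a = self.build({"P1", "P2"}, {"P2", "P3", "P4"}, config)
        b = self.build({"P2", "P3", "P4"}, {"P1", "P2"}, config)
        assert a.shared_pathways == b.shared_pathways and a.jaccard == b.jaccard

    def test_empty_sets_give_jaccard_zero_not_error(self, config):
        sim = self.build(set(), set(), config)
        assert sim.jaccard == 0.0 and not sim.passes


class TestSelectFclmr:
    def make_pair(self, i):
        return SyntenicPair(f"h{i}", f"m{i}", (("A", "a"), ("B", "b")), True)

    def test_all_pass_and_none_pass(self, config):
        pairs = [(self.make_pair(i), ["fast"]) for i in range(3)]
        sim_pass = pathway_similarity(
            [type("E", (), {"pathway_id": "P", "adjusted_p": 0.001})()],
            [type("E", (), {"pathway_id": "P", "adjusted_p": 0.001})()],
            config,
        )
        sims = {(f"h{i}", f"m{i}"): sim_pass for i in range(3)}
        assert len(select_fclmr(pairs, sims, config)) == 3
        sim_fail = pathway_similarity([], [], config)
        sims = {(f"h{i}", f"m{i}"): sim_fail for i in range(3)}
        assert select_fclmr(pairs, sims, config) == []

    def test_missing_similarity_is_error(self, config):
        with pytest.raises(ValueError, match="no similarity"):
            select_fclmr([(self.make_pair(0), ["fast"])], {}, config)


class TestOrthologRecovery:
    def test_identical_profiles_rank_first(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 8))
        expr_h = make_expr({f"H{i}": list(x[i]) for i in range(6)})
        expr_m = make_expr({f"M{i}": list(x[i]) for i in range(6)}, compartment="mouse")
        omap = OrthologMap([(f"H{i}", f"M{i}") for i in range(6)])
        assert ortholog_recovery_rate(expr_h, expr_m, omap, k=1) == 1.0

    def test_k_equal_to_gene_count_recovers_everything(self):
        rng = np.random.default_rng(2)
        expr_h = make_expr({f"H{i}": list(rng.random(5)) for i in range(4)})
        expr_m = make_expr({f"M{i}": list(rng.random(5)) for i in range(4)}, compartment="mouse")
        omap = OrthologMap([(f"H{i}", f"M{i}") for i in range(4)])
        assert ortholog_recovery_rate(expr_h, expr_m, omap, k=4) == 1.0

    def test_null_rate_matches_random_expectation(self):
        """With mouse profiles re-drawn independently, recovery at k=1
        averages ~1/N across repeated draws."""
        rng = np.random.default_rng(3)
        N, reps = 20, 60
        rates = []
        x = rng.random((N, 10))
        expr_h = make_expr({f"H{i}": list(x[i]) for i in range(N)})
        omap = OrthologMap([(f"H{i}", f"M{i}") for i in range(N)])
        for _ in range(reps):
            y = rng.random((N, 10))
            expr_m = make_expr({f"M{i}": list(y[i]) for i in range(N)}, compartment="mouse")
            rates.append(ortholog_recovery_rate(expr_h, expr_m, omap, k=1))
        # mean ~ 1/20 = 0.05; sd of the mean ~ sqrt(.05*.95/(N*reps)) ~ 0.0063
        assert np.mean(rates) == pytest.approx(1 / N, abs=0.03)

    def test_no_shared_orthologs_is_error(self):
        expr_h = make_expr({"H0": [1, 2, 3, 4]})
        expr_m = make_expr({"M0": [1, 2, 3, 4]}, compartment="mouse")
        with pytest.raises(ValueError, match="no orthologous genes"):
            ortholog_recovery_rate(expr_h, expr_m, OrthologMap([("HX", "MX")]), k=1)


class TestDiscoveryRate:
    @pytest.mark.parametrize(
        "selected,candidates,expected", [(59, 2419, 2.4), (0, 100, 0.0), (1, 3, 33.3)]
    )
    def test_worked_values(self, selected, candidates, expected):
        assert discovery_rate(selected, candidates) == expected

    def test_zero_candidates_is_error(self):
        with pytest.raises(ValueError):
            discovery_rate(0, 0)


def test_expressed_universe_fraction_rule():
    expr = make_expr({"A": [0, 0, 1, 1], "B": [0, 0, 0, 2], "C": [1, 1, 1, 1]})
    assert expressed_universe(expr, ["A", "B", "C"], fraction=0.5) == {"A", "C"}
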