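"""Differential regulation and the cross-species consistency filter."""

import numpy as np
import pytest

from fclmr.coregulation import (
    build_regulation_profile,
    DEResult,
    differential_expression,
    match_coregulated,
)
from fclmr.synteny import SyntenicPair
from fclmr.types import PipelineConfig
from conftest import make_expr


def de_one(values_a, values_b, pseudocount=1.0):
    expr = make_expr({"G": list(values_a) + list(values_b)},
                     ["a"] * len(values_a) + ["b"] * len(values_b))
    (res,) = differential_expression(
        expr, expr.samples_for("a"), expr.samples_for("b"), pseudocount
    )
    return res


class TestDifferentialExpression:
    def test_constant_gene_identical_groups_is_null(self):
        res = de_one([5, 5, 5], [5, 5, 5])
        assert res.log2fc == 0.0 and res.p_value == 1.0

    def test_log2fc_hand_arithmetic_with_pseudocount(self):
        # means 4 and 8, pseudocount 1 -> log2(9/5)
        res = de_one([3, 4, 5], [7, 8, 9])
        assert res.log2fc == pytest.approx(np.log2(9 / 5), abs=1e-12)
        assert (res.mean_a, res.mean_b) == (4.0, 8.0)

    def test_group_smaller_than_two_is_error(self):
        expr = make_expr({"G": [1, 2, 3]}, ["a", "b", "b"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(expr, ["a_r1"], ["b_r1", "b_r2"])

    def test_unknown_sample_id_is_error(self):
        expr = make_expr({"G": [1, 2, 3, 4]}, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="unknown sample"):
            differential_expression(expr, ["a_r1", "nope"], ["b_r1", "b_r2"])

    def test_overlapping_groups_are_an_error(self):
        expr = make_expr({"G": [1, 2, 3, 4]}, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="disjoint"):
            differential_expression(expr, ["a_r1", "a_r2"], ["a_r2", "b_r1"])

    @pytest.mark.parametrize("n_per_group,tol", [(3, 0.2), (8, 0.03)])
    def test_p_agrees_with_permutation_oracle(self, n_per_group, tol):
        """Welch p vs a label-permutation oracle (10,000 shuffles).

        At n=3 the permutation distribution has only C(6,3)=20 distinct
        splits, so agreement is necessarily coarse; at n=8 the two should
        agree closely for roughly normal log-scale data.
        """
        rng = np.random.default_rng(42)
        n_genes = 12
        a = 2 ** rng.normal(5.0, 0.5, size=(n_genes, n_per_group))
        b = 2 ** rng.normal(5.0 + np.linspace(0, 1.5, n_genes)[:, None], 0.5,
                            size=(n_genes, n_per_group))
        expr = make_expr(
            {f"G{i}": list(a[i]) + list(b[i]) for i in range(n_genes)},
            ["a"] * n_per_group + ["b"] * n_per_group,
        )
        results = differential_expression(expr, expr.samples_for("a"), expr.samples_for("b"))

        logx = np.log2(np.concatenate([a, b], axis=1) + 1.0)
        n = n_per_group

        def welch_t(x):
            ga, gb = x[:, :n], x[:, n:]
            va, vb = ga.var(axis=1, ddof=1), gb.var(axis=1, ddof=1)
            return (gb.mean(axis=1) - ga.mean(axis=1)) / np.sqrt(va / n + vb / n)

        t_obs = np.abs(welch_t(logx))
        n_perm = 10_000
        count = np.zeros(n_genes)
        for _ in range(n_perm):
            perm = rng.permutation(2 * n)
            count += np.abs(welch_t(logx[:, perm])) >= t_obs - 1e-12
        p_perm = count / n_perm
        for res, pp in zip(results, p_perm):
            assert res.p_value == pytest.approx(pp, abs=tol)

    def test_type_i_error_near_nominal_on_null(self):
        """Null 5v5 log-normal simulation: ~5% of 2,000 genes at p<0.05."""
        rng = np.random.default_rng(7)
        x = 2 ** rng.normal(5.0, 0.4, size=(2000, 10))
        expr = make_expr({f"G{i}": list(x[i]) for i in range(2000)}, ["a"] * 5 + ["b"] * 5)
        res = differential_expression(expr, expr.samples_for("a"), expr.samples_for("b"))
        frac = np.mean([r.p_value < 0.05 for r in res])
        assert frac == pytest.approx(0.05, abs=0.015)


class TestRegulationProfile:
    def make_profiles(self, entries, config):
        de = {
            cond: [DEResult("L", fc, p, 1.0, 1.0)]
            for cond, (fc, p) in entries.items()
        }
        (prof,) = build_regulation_profile(["L"], de, config)
        return prof

    def test_threshold_semantics_are_strict(self, config):
        prof = self.make_profiles(
            {"fast": (0.5, 0.01), "refeed": (0.6, 0.04), "fxr": (-0.6, 0.2)}, config
        )
        # |log2FC| exactly 0.5 does not pass the strict > rule
        assert not prof.calls["fast"].significant
        assert prof.calls["refeed"].significant and prof.calls["refeed"].direction == "up"
        assert not prof.calls["fxr"].significant and prof.calls["fxr"].direction == "none"

    def test_p_boundary_is_strict_too(self, config):
        prof = self.make_profiles({"fast": (0.8, 0.05)}, config)
        assert not prof.calls["fast"].significant

    def test_missing_condition_is_error(self, config):
        de = {"fast": [DEResult("L", 1.0, 0.01, 1, 1)], "fxr": []}
        with pytest.raises(ValueError, match="fxr"):
            build_regulation_profile(["L"], de, config)

    def test_empty_condition_set_is_error(self, config):
        with pytest.raises(ValueError, match="empty condition set"):
            build_regulation_profile(["L"], {}, config)


def pair(h="hL", m="mL"):
    return SyntenicPair(h, m, (("A", "a"), ("B", "b")), True)


def profiles_from(spec, config):
    """spec: {lnc: {cond: (fc, p)}} -> profiles list."""
    lncs = sorted(spec)
    conds = sorted({c for v in spec.values() for c in v})
    de = {
        cond: [DEResult(l, *spec[l][cond], 1.0, 1.0) for l in lncs]
        for cond in conds
    }
    return build_regulation_profile(lncs, de, config)


class TestMatchCoregulated:
    def test_same_direction_retained_with_condition(self, config):
        ph = profiles_from({"hL": {"fast": (1.0, 0.01), "fxr": (0.1, 0.9)}}, config)
        pm = profiles_from({"mL": {"fast": (0.8, 0.02), "fxr": (0.2, 0.8)}}, config)
        retained = match_coregulated([pair()], ph, pm, config)
        assert [(p.lnc_h, conds) for p, conds in retained] == [("hL", ["fast"])]

    def test_opposite_direction_veto_drops_pair(self, config):
        ph = profiles_from({"hL": {"fast": (1.0, 0.01), "fxr": (1.0, 0.01)}}, config)
        pm = profiles_from({"mL": {"fast": (0.8, 0.02), "fxr": (-0.9, 0.01)}}, config)
        assert match_coregulated([pair()], ph, pm, config) == []
        # with the veto off, the matching fast condition is enough
        no_veto = config.with_(opposite_veto=False)
        assert len(match_coregulated([pair()], ph, pm, no_veto)) == 1

    def test_published_direction_examples(self, config):
        """Both-up under fasting and both-down under FXR activation both
        count as similarly regulated."""
        ph = profiles_from(
            {"hLMR2": {"fast": (1.2, 0.001), "fxr": (0.0, 0.9)},
             "hLMR4": {"fast": (0.1, 0.7), "fxr": (-1.1, 0.004)}}, config)
        pm = profiles_from(
            {"mLMR2": {"fast": (0.9, 0.01), "fxr": (0.1, 0.6)},
             "mLMR4": {"fast": (0.0, 0.9), "fxr": (-0.8, 0.02)}}, config)
        pairs = [pair("hLMR2", "mLMR2"), pair("hLMR4", "mLMR4")]
        retained = match_coregulated(pairs, ph, pm, config)
        assert {(p.lnc_h, tuple(c)) for p, c in retained} == {
            ("hLMR2", ("fast",)),
            ("hLMR4", ("fxr",)),
        }

    def test_missing_profile_is_error(self, config):
        ph = profiles_from({"hL": {"fast": (1.0, 0.01)}}, config)
        with pytest.raises(ValueError, match="profile"):
            match_coregulated([pair()], ph, [], config)

    def test_threshold_monotonicity(self):
        """Raising the fold-change bar or lowering alpha never retains more."""
        rng = np.random.default_rng(3)
        spec_h, spec_m, pairs = {}, {}, []
        for i in range(40):
            h, m = f"h{i}", f"m{i}"
            pairs.append(pair(h, m))
            spec_h[h] = {c: (rng.normal(0, 1), rng.random()) for c in ("fast", "fxr")}
            spec_m[m] = {c: (rng.normal(0, 1), rng.random()) for c in ("fast", "fxr")}
        counts = []
        for lfc, alpha in [(0.3, 0.2), (0.5, 0.1), (0.8, 0.05), (1.2, 0.01)]:
            cfg = PipelineConfig(lfc_threshold=lfc, p_threshold=alpha)
            retained = match_coregulated(
                pairs, profiles_from(spec_h, cfg), profiles_from(spec_m, cfg), cfg
            )
            counts.append(len(retained))
        assert counts == sorted(counts, reverse=True)

    def test_removing_a_condition_never_adds_pairs(self):
        """Fewer shared conditions can only shrink the retained set (the
        veto is off: with it, dropping a vetoing condition could rescue a
        pair by construction)."""
        rng = np.random.default_rng(9)
        cfg = PipelineConfig(opposite_veto=False)
        conds = ("fast", "refeed", "fxr")
        spec_h, spec_m, pairs = {}, {}, []
        for i in range(60):
            h, m = f"h{i}", f"m{i}"
            pairs.append(pair(h, m))
            spec_h[h] = {c: (rng.normal(0, 1), rng.random()) for c in conds}
            spec_m[m] = {c: (rng.normal(0, 1), rng.random()) for c in conds}
        full = {
            (p.lnc_h, p.lnc_m)
            for p, _ in match_coregulated(
                pairs, profiles_from(spec_h, cfg), profiles_from(spec_m, cfg), cfg
            )
        }
        for drop in conds:
            sub_h = {l: {c: v for c, v in d.items() if c != drop} for l, d in spec_h.items()}
            sub_m = {l: {c: v for c, v in d.items() if c != drop} for l, d in spec_m.items()}
            sub = {
                (p.lnc_h, p.lnc_m)
                for p, _ in match_coregulated(
                    pairs, profiles_from(sub_h, cfg), profiles_from(sub_m, cfg), cfg
                )
            }
            assert sub <= full
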