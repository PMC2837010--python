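"""Differential calls, permutation FDR, temperature filter, set algebra."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_expression
from srcprog.config import PipelineConfig
from srcprog.containers import DifferentialResult, GeneSet
from srcprog.differential import (
    anova_transformation_test,
    build_gene_sets,
    estimate_permutation_fdr,
    filter_temperature_confounded,
    pairwise_differential,
    pairwise_rule,
    platform_concordance,
)

CFG = PipelineConfig(n_permutations=100, seed=1)


def expr_3v3(rows: np.ndarray) -> "make_expression":
    return make_expression(rows, ["a"] * 3 + ["b"] * 3)


class TestPairwise:
    def test_identical_constant_groups_fail(self):
        em = expr_3v3(np.full((2, 6), 8.0))
        res = pairwise_differential(em, ["s0", "s1", "s2"], ["s3", "s4", "s5"], CFG)
        assert (res.table["fold_change"] == 1.0).all()
        assert not res.table["passes"].any()
        assert (res.table["p_value"] == 1.0).all()

    def test_planted_fourfold_called_up(self, rng):
        base = 2.0 ** (8 + rng.normal(0, 0.05, size=(1, 6)))
        base[0, 3:] *= 4.0
        res = pairwise_differential(expr_3v3(base), ["s0", "s1", "s2"], ["s3", "s4", "s5"], CFG)
        assert res.table["passes"].iloc[0]
        assert res.table["direction"].iloc[0] == "up"

    def test_significant_but_subthreshold_fold_change_fails(self, rng):
        base = 2.0 ** (8 + rng.normal(0, 0.01, size=(1, 6)))
        base[0, 3:] *= 1.5
        res = pairwise_differential(expr_3v3(base), ["s0", "s1", "s2"], ["s3", "s4", "s5"], CFG)
        assert res.table["p_value"].iloc[0] < 0.05
        assert not res.table["passes"].iloc[0]

    def test_group_swap_flips_direction_only(self, rng):
        base = 2.0 ** rng.normal(8, 1, size=(50, 6))
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        r1 = pairwise_differential(expr_3v3(base), a, b, CFG)
        r2 = pairwise_differential(expr_3v3(base), b, a, CFG)
        np.testing.assert_allclose(r1.table["p_value"], r2.table["p_value"], rtol=1e-9)
        assert (r1.table["passes"] == r2.table["passes"]).all()
        moved = r1.table["direction"] != "none"
        flip = {"up": "down", "down": "up"}
        assert (r2.table.loc[moved, "direction"] == r1.table.loc[moved, "direction"].map(flip)).all()

    def test_small_group_rejected(self):
        em = expr_3v3(np.ones((1, 6)))
        with pytest.raises(ValueError):
            pairwise_differential(em, ["s0"], ["s1", "s2"], CFG)


def expr_3groups(rows: np.ndarray) -> "make_expression":
    return make_expression(rows, ["c1"] * 3 + ["c2"] * 3 + ["t"] * 3)


GROUPS_9 = (["s0", "s1", "s2"], ["s3", "s4", "s5"])
TEST_9 = ["s6", "s7", "s8"]


class TestAnova:
    def test_test_specific_fourfold_passes_up(self, rng):
        rows = 2.0 ** (8 + rng.normal(0, 0.05, size=(1, 9)))
        rows[0, 6:] *= 4.0
        res = anova_transformation_test(expr_3groups(rows), GROUPS_9, TEST_9, CFG)
        assert res.table["passes"].iloc[0]
        assert res.table["direction"].iloc[0] == "up"

    def test_constant_feature_fails(self):
        res = anova_transformation_test(expr_3groups(np.full((1, 9), 6.0)), GROUPS_9, TEST_9, CFG)
        assert not res.table["passes"].iloc[0]

    def test_control_only_contrast_gets_direction_none(self, rng):
        # controls differ four-fold; test group sits at their geometric mean
        rows = 2.0 ** (8 + rng.normal(0, 0.02, size=(1, 9)))
        rows[0, 0:3] *= 0.5
        rows[0, 3:6] *= 2.0
        res = anova_transformation_test(expr_3groups(rows), GROUPS_9, TEST_9, CFG)
        assert res.table["direction"].iloc[0] == "none"
        assert not res.table["passes"].iloc[0]
        assert res.table["fold_change"].iloc[0] == pytest.approx(4.0, rel=0.1)

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            anova_transformation_test(expr_3groups(np.ones((1, 9))), (GROUPS_9[0],), TEST_9, CFG)


class TestPermutationFdr:
    def test_zero_observed_is_zero_with_warning(self, rng, caplog):
        em = expr_3v3(2.0 ** rng.normal(8, 0.01, size=(30, 6)))
        with caplog.at_level("WARNING"):
            est = estimate_permutation_fdr(em, [["s0", "s1", "s2"], ["s3", "s4", "s5"]], pairwise_rule, CFG)
        assert est.fdr_estimate == 0.0 and est.observed_count == 0
        assert "no observed calls" in caplog.text

    def test_small_designs_enumerated_exactly(self, rng, caplog):
        em = make_expression(2.0 ** rng.normal(8, 1, size=(20, 4)), ["a", "a", "b", "b"])
        groups = [["s0", "s1"], ["s2", "s3"]]
        with caplog.at_level("WARNING"):
            e1 = estimate_permutation_fdr(em, groups, pairwise_rule, CFG)
        assert "enumerating exactly" in caplog.text
        e2 = estimate_permutation_fdr(em, groups, pairwise_rule, CFG)
        assert e1 == e2  # enumeration is deterministic

    def test_feature_order_invariance_and_seed_reproducibility(self, rng):
        vals = 2.0 ** rng.normal(8, 1, size=(100, 6))
        groups = [["s0", "s1", "s2"], ["s3", "s4", "s5"]]
        em = expr_3v3(vals)
        shuffled = expr_3v3(vals[::-1])
        e1 = estimate_permutation_fdr(em, groups, pairwise_rule, CFG)
        e2 = estimate_permutation_fdr(shuffled, groups, pairwise_rule, CFG)
        e3 = estimate_permutation_fdr(em, groups, pairwise_rule, CFG)
        assert e1.mean_null_count == e2.mean_null_count
        assert e1 == e3


def _result(rows: dict[str, tuple[float, bool]]) -> DifferentialResult:
    table = pd.DataFrame(
        {
            "fold_change": [2.0 ** abs(l) for l, _ in rows.values()],
            "log2_ratio": [l for l, _ in rows.values()],
            "p_value": 0.01,
            "direction": ["up" if l >= 0 else "down" for l, _ in rows.values()],
            "passes": [p for _, p in rows.values()],
        },
        index=list(rows),
    )
    return DifferentialResult(table, "ttest")


class TestTemperatureFilter:
    def setup_method(self):
        self.ts = GeneSet("ts", {"g1": "up", "g2": "up", "g3": "down", "g4": "up"})
        # g1: temp 2.0 vs wt 1.0 -> removed; g3: temp 0.5 vs wt 2.0 -> retained
        # g4 temp-regulated but absent from wt comparison -> removed (FC-1 rule)
        self.temp = _result({"g1": (2.0, True), "g3": (0.5, True), "g4": (1.2, True)})
        self.wt = _result({"g1": (1.0, True), "g2": (1.5, True), "g3": (2.0, True)})

    def test_rules(self):
        kept, removed = filter_temperature_confounded(self.ts, self.temp, self.wt)
        assert removed.ids == {"g1", "g4"}
        assert kept.ids == {"g2", "g3"}
        ev = removed.evidence.set_index("gene_id")
        assert ev.loc["g1", "temperature_abs_log2fc"] == pytest.approx(2.0)
        assert ev.loc["g4", "wt_abs_log2fc"] == 0.0


class TestSetAlgebra:
    def test_disjoint_inputs_give_empty_derived_sets(self):
        a = GeneSet("TR", {"g1": "up"})
        b = GeneSet("CEF", {"g2": "up"})
        c = GeneSet("CNR", {"g3": "down"})
        fam = build_gene_sets(a, b, c)
        assert len(fam["common_all3"]) == len(fam["ts_only"]) == len(fam["CSR"]) == 0

    def test_direction_conflict_resolved_from_tr(self, caplog):
        a = GeneSet("TR", {"g1": "up"})
        b = GeneSet("CEF", {"g1": "down"})
        c = GeneSet("CNR", {"g1": "down"})
        with caplog.at_level("WARNING"):
            fam = build_gene_sets(a, b, c)
        assert fam["common_all3"].members["g1"] == "up"
        assert "conflict" in caplog.text

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_csr_is_disjoint_union(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(40)]
        def rand_set(name):
            ids = rng.choice(universe, size=rng.integers(5, 30), replace=False)
            return GeneSet(name, {g: "up" for g in ids})
        fam = build_gene_sets(rand_set("TR"), rand_set("CEF"), rand_set("CNR"))
        assert fam["common_all3"].ids.isdisjoint(fam["ts_only"].ids)
        assert fam["CSR"].ids == fam["common_all3"].ids | fam["ts_only"].ids
        assert len(fam["CSR"]) == len(fam["common_all3"]) + len(fam["ts_only"])


class TestPlatformConcordance:
    def test_perfect_agreement(self):
        c = platform_concordance([(x, x) for x in (-2.0, -0.5, 1.0, 3.0)])
        assert (c.spearman_rho, c.ols_slope) == (1.0, pytest.approx(1.0))

    def test_half_slope_keeps_perfect_rank_correlation(self):
        c = platform_concordance([(x, 0.5 * x) for x in (-2.0, -0.5, 1.0, 3.0)])
        assert c.spearman_rho == 1.0
        assert c.ols_slope == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            platform_concordance([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])
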