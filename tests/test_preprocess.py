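"""Normalization and probe-set summarization oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from conftest import make_plm
from srcprog.config import SimulationConfig
from srcprog.containers import DifferentialResult, ProbeAnnotation
from srcprog.preprocess import (
    choose_baseline_array,
    collapse_to_genes,
    compute_mbei,
    normalize_experiment,
    normalize_to_baseline,
    scale_to_common_median,
    select_invariant_probes,
)
from srcprog.simulate import simulate_microarray_experiment


class TestMedianScaling:
    def test_scales_every_array_to_target(self, rng):
        plm = make_plm({"ps1": rng.uniform(50, 400, size=(11, 2))})
        plm.intensities["a0"] *= 100 / plm.intensities["a0"].median()
        plm.intensities["a1"] *= 200 / plm.intensities["a1"].median()
        (out,) = scale_to_common_median([plm], target_median=150)
        assert out.intensities.median(axis=0).to_numpy() == pytest.approx([150.0, 150.0])
        # "auto" = mean of medians
        (out_auto,) = scale_to_common_median([plm])
        assert out_auto.intensities.median(axis=0).to_numpy() == pytest.approx([150.0, 150.0])

    def test_array_at_target_unchanged_and_ratios_preserved(self, rng):
        vals = rng.uniform(10, 1000, size=(21, 2))
        plm = make_plm({"ps1": vals})
        target = float(np.median(vals[:, 0]))
        (out,) = scale_to_common_median([plm], target_median=target)
        np.testing.assert_allclose(out.intensities["a0"], vals[:, 0])
        before = vals[3, 1] / vals[17, 1]
        after = out.intensities["a1"].iloc[3] / out.intensities["a1"].iloc[17]
        assert after == pytest.approx(before, rel=1e-12)

    def test_zero_median_array_rejected(self):
        plm = make_plm({"ps1": np.zeros((5, 1))})
        with pytest.raises(ValueError, match="median"):
            scale_to_common_median([plm])


class TestInvariantSet:
    def test_identical_and_globally_scaled_arrays_keep_all_probes(self, rng):
        b = rng.uniform(10, 5000, size=500)
        assert select_invariant_probes(b, b).size == 500
        assert select_invariant_probes(2.0 * b, b).size == 500

    def test_rank_shifted_probes_are_excluded(self, rng):
        n = 2000
        b = np.sort(rng.uniform(10, 5000, size=n))
        t = b.copy()
        perturbed = rng.choice(n, size=n // 10, replace=False)
        t[perturbed] *= rng.uniform(5, 20, size=perturbed.size)  # large upward rank shifts
        inv = select_invariant_probes(t, b)
        excluded = np.setdiff1d(perturbed, inv)
        assert excluded.size >= 0.95 * perturbed.size

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            select_invariant_probes(np.ones(20), np.ones(21))


class TestNormalizationCurve:
    def test_identity_map(self, rng):
        b = rng.uniform(10, 5000, size=800)
        out = normalize_to_baseline(b, b, np.arange(800))
        np.testing.assert_allclose(out, b, rtol=1e-9)

    def test_inverts_global_doubling_within_1pct(self, rng):
        b = rng.uniform(10, 5000, size=2000)
        t = 2.0 * b
        out = normalize_to_baseline(t, b, np.arange(2000))
        inside = (t > np.quantile(t, 0.05)) & (t < np.quantile(t, 0.95))
        np.testing.assert_allclose(out[inside], b[inside], rtol=0.01)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_output_monotone_in_target(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.lognormal(5, 1, size=300)
        t = rng.lognormal(5, 1, size=300)
        inv = select_invariant_probes(t, b, rank_threshold=0.05)
        out = normalize_to_baseline(t, b, inv)
        order = np.argsort(t, kind="stable")
        assert (np.diff(out[order]) >= -1e-9).all()

    def test_small_invariant_set_falls_back_to_median_ratio(self, rng, caplog):
        b = rng.uniform(10, 100, size=50)
        t = 3.0 * b
        with caplog.at_level("WARNING"):
            out = normalize_to_baseline(t, b, np.arange(5))
        assert "falling back" in caplog.text
        assert np.median(out) == pytest.approx(np.median(b))

    def test_idempotent_within_0p1pct(self, rng):
        b = rng.lognormal(6, 1, size=3000)
        t = 1.7 * b ** 1.05
        inv = select_invariant_probes(t, b)
        once = normalize_to_baseline(t, b, inv)
        inv2 = select_invariant_probes(once, b)
        twice = normalize_to_baseline(once, b, inv2)
        inside = (once > np.quantile(once, 0.02)) & (once < np.quantile(once, 0.98))
        assert np.max(np.abs(twice[inside] - once[inside]) / once[inside]) < 1e-3


class TestMbei:
    def test_exact_on_noise_free_rank_one(self, rng):
        phi = rng.uniform(0.3, 2.0, size=8)
        phi /= phi.mean()  # identifiability: arithmetic mean 1
        theta = rng.uniform(50, 800, size=5)
        plm = make_plm({"ps1": np.outer(phi, theta)})
        expr = compute_mbei(plm)
        np.testing.assert_allclose(expr.values.loc["ps1"].to_numpy(), theta, rtol=1e-8)

    def test_recovers_theta_within_5pct_under_1pct_noise(self, rng):
        phi = rng.uniform(0.3, 2.0, size=11)
        phi /= phi.mean()
        theta = rng.uniform(100, 1000, size=6)
        signal = np.outer(phi, theta)
        noisy = signal + rng.normal(0, 0.01 * signal)
        plm = make_plm({"ps1": noisy})
        expr = compute_mbei(plm)
        np.testing.assert_allclose(expr.values.loc["ps1"].to_numpy(), theta, rtol=0.05)

    def test_single_probe_set_passthrough(self, rng):
        row = rng.uniform(10, 100, size=4)
        plm = make_plm({"ps1": row[None, :], "ps2": rng.uniform(10, 100, size=(5, 4))})
        expr = compute_mbei(plm)
        np.testing.assert_allclose(expr.values.loc["ps1"].to_numpy(), row)

    def test_scale_equivariance(self, rng):
        probes = rng.lognormal(5, 1, size=(7, 5))
        e1 = compute_mbei(make_plm({"ps1": probes}))
        e2 = compute_mbei(make_plm({"ps1": 3.0 * probes}))
        np.testing.assert_allclose(e2.values.to_numpy(), 3.0 * e1.values.to_numpy(), rtol=1e-8)

    def test_outlier_probe_is_masked(self, rng):
        phi = rng.uniform(0.5, 1.5, size=10)
        phi /= phi.mean()
        theta = rng.uniform(100, 500, size=6)
        x = np.outer(phi, theta)
        x[0, 0] *= 40.0  # one wild intensity
        expr = compute_mbei(make_plm({"ps1": x}))
        np.testing.assert_allclose(expr.values.loc["ps1"].to_numpy(), theta, rtol=0.05)


def _ann(mapping: dict[str, str]) -> ProbeAnnotation:
    table = pd.DataFrame(
        {"gene_id": list(mapping.values()), "gene_symbol": list(mapping.values())},
        index=pd.Index(list(mapping), name="probeset_id"),
    )
    return ProbeAnnotation(table)


def _diff(rows: dict[str, float]) -> DifferentialResult:
    table = pd.DataFrame(
        {
            "fold_change": 2.0,
            "log2_ratio": 1.0,
            "p_value": pd.Series(rows),
            "direction": "up",
            "passes": True,
        }
    )
    return DifferentialResult(table, "ttest")


class TestCollapse:
    def test_lowest_p_probe_set_retained(self):
        res = _diff({"psA": 0.004, "psB": 0.020})
        out = collapse_to_genes(res, _ann({"psA": "g1", "psB": "g1"}))
        assert list(out.table.index) == ["g1"]
        assert out.table.loc["g1", "probeset_id"] == "psA"

    def test_unique_genes_size_preserved(self):
        res = _diff({"psA": 0.01, "psB": 0.02, "psC": 0.03})
        out = collapse_to_genes(res, _ann({"psA": "g1", "psB": "g2", "psC": "g3"}))
        assert len(out.table) == 3

    def test_p_tie_breaks_lexicographically(self):
        res = _diff({"psZ": 0.01, "psA": 0.01})
        out = collapse_to_genes(res, _ann({"psZ": "g1", "psA": "g1"}))
        assert out.table.loc["g1", "probeset_id"] == "psA"

    def test_unannotated_feature_raises_with_ids(self):
        res = _diff({"psA": 0.01, "psQ": 0.02})
        with pytest.raises(KeyError, match="psQ"):
            collapse_to_genes(res, _ann({"psA": "g1"}))

    def test_expression_collapse_uses_retained_map(self, rng):
        from conftest import make_expression

        em = make_expression(rng.uniform(1, 10, size=(2, 3)), ["a", "a", "b"], feature_prefix="ps")
        retained = pd.Series({"g1": "ps1"})
        out = collapse_to_genes(em, _ann({"ps0": "g1", "ps1": "g1"}), retained=retained)
        assert list(out.values.index) == ["g1"]
        np.testing.assert_allclose(out.values.loc["g1"], em.values.loc["ps1"])


class TestEndToEndPreprocessing:
    def test_realized_fold_changes_track_truth(self):
        """Scaling + invariant-set normalization + MBEI preserves planted log2 FCs."""
        cfg = SimulationConfig(n_probesets=600, n_planted_up=40, n_planted_down=40,
                               n_temperature_genes=0, seed=21)
        plm, truth = simulate_microarray_experiment(cfg)
        (scaled,) = scale_to_common_median([plm])
        expr = compute_mbei(normalize_experiment(scaled))
        log = expr.log2()
        gene_of = pd.Series(truth.probeset_to_gene)
        test = expr.samples_for(truth.extras["test_condition"])
        ctrl = [s for s in expr.values.columns if s not in test]
        d = (log[test].mean(axis=1) - log[ctrl].mean(axis=1)).groupby(
            gene_of.loc[log.index].to_numpy()
        ).mean()
        planted = {**{g: np.log2(f) for g, f in truth.planted_up.items()},
                   **{g: -np.log2(f) for g, f in truth.planted_down.items()}}
        realized = [d[g] for g in planted]
        rho = spearmanr(realized, list(planted.values())).statistic
        assert rho >= 0.95

    def test_baseline_is_median_of_medians(self, rng):
        plm = make_plm({"ps1": rng.uniform(10, 100, size=(9, 5))})
        medians = plm.intensities.median(axis=0)
        assert medians[choose_baseline_array(plm)] == sorted(medians)[2]
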