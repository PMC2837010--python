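"""Synthetic data generators with planted, recorded ground truth.

Two generators stand in for the study's raw data: a probe-level oligo-array
simulator (perfect-match intensities with multiplicative probe affinities,
log-normal noise, planted fold changes, temperature confounds and redundant
probe sets) and a tumor-cohort simulator (log2 expression with a planted
high-signature subgroup and exponential proportional-hazards survival with
independent censoring). Both are deterministic functions of (config, seed) and
return a GroundTruth record sufficient to score every downstream caller.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import CohortConfig, SimulationConfig
from .containers import ConfigurationError, GroundTruth, ProbeLevelMatrix, TumorCohort

__all__ = [
    "simulate_microarray_experiment",
    "simulate_tumor_cohort",
    "simulate_discovery_scenario",
]


def _generate_probe_level(
    theta_log2: pd.DataFrame,  # gene x condition log2 expression
    probeset_to_gene: dict[str, str],
    conditions: tuple[tuple[str, str], ...],
    replicates: int,
    probes_per_set: int,
    affinity_log2_sd: float,
    noise_sd: float,
    rng: np.random.Generator,
    name: str = "",
) -> ProbeLevelMatrix:
    """Core generator: PM(i, j) = phi(i) * theta(gene, condition(j)) * 2**eps.

    Probe affinities phi are log-normal with unit geometric mean within each
    probe set, so probe-set log-scale summaries are unbiased.
    """
    probesets = list(probeset_to_gene)
    n_sets = len(probesets)
    genes = [probeset_to_gene[ps] for ps in probesets]

    # affinities: centered per set on the log2 scale -> unit geometric mean
    log_phi = rng.normal(0.0, affinity_log2_sd, size=(n_sets, probes_per_set))
    log_phi -= log_phi.mean(axis=1, keepdims=True)

    array_ids, cond_of_array, temp_of_array, rep_of_array = [], [], [], []
    for cond, temp in conditions:
        for r in range(1, replicates + 1):
            array_ids.append(f"{cond}@{temp}_r{r}")
            cond_of_array.append(cond)
            temp_of_array.append(temp)
            rep_of_array.append(r)
    n_arrays = len(array_ids)

    theta = theta_log2.loc[genes, [c for c, _ in conditions]].to_numpy()  # (n_sets, n_cond)
    theta_per_array = np.repeat(theta, replicates, axis=1)  # (n_sets, n_arrays)

    log_pm = log_phi[:, :, None] + theta_per_array[:, None, :]
    if noise_sd > 0:
        log_pm = log_pm + rng.normal(0.0, noise_sd, size=log_pm.shape)
    pm = np.exp2(log_pm).reshape(n_sets * probes_per_set, n_arrays)

    index = pd.MultiIndex.from_arrays(
        [np.repeat(probesets, probes_per_set), np.tile(np.arange(probes_per_set), n_sets)],
        names=["probeset_id", "probe_index"],
    )
    intensities = pd.DataFrame(pm, index=index, columns=array_ids)
    samples = pd.DataFrame(
        {"condition": cond_of_array, "temperature": temp_of_array, "replicate": rep_of_array},
        index=pd.Index(array_ids, name="array_id"),
    )
    return ProbeLevelMatrix(intensities, samples, name=name)


def _gene_universe(cfg: SimulationConfig, rng: np.random.Generator):
    """Gene ids and a probe-set map where redundant genes carry two probe sets."""
    n_genes = cfg.n_genes
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_dup = cfg.n_probesets - n_genes
    dup_genes = list(rng.choice(genes, size=n_dup, replace=False)) if n_dup else []
    probeset_to_gene = {f"PS_{g}_a": g for g in genes}
    probeset_to_gene.update({f"PS_{g}_b": g for g in dup_genes})
    return genes, probeset_to_gene


def simulate_microarray_experiment(config: SimulationConfig) -> tuple[ProbeLevelMatrix, GroundTruth]:
    """Simulate one multi-condition probe-level infection experiment.

    Planted up/down genes carry their fold change in the designated test
    condition (default: the last condition); temperature genes carry a fold
    change wherever the array temperature differs from the first condition's.
    """
    if config.n_planted_up + config.n_planted_down + config.n_temperature_genes > config.n_genes:
        raise ConfigurationError("planted + temperature gene counts exceed the gene universe")
    rng = np.random.default_rng(config.seed)
    genes, probeset_to_gene = _gene_universe(config, rng)

    perm = rng.permutation(len(genes))
    k1 = config.n_planted_up
    k2 = k1 + config.n_planted_down
    k3 = k2 + config.n_temperature_genes
    up_genes = [genes[i] for i in perm[:k1]]
    down_genes = [genes[i] for i in perm[k1:k2]]
    temp_genes = [genes[i] for i in perm[k2:k3]]

    lo, hi = config.fold_change_range
    fc_up = dict(zip(up_genes, rng.uniform(lo, hi, size=len(up_genes))))
    fc_down = dict(zip(down_genes, rng.uniform(lo, hi, size=len(down_genes))))
    tlo, thi = config.temperature_fold_range
    temp_fc = rng.uniform(tlo, thi, size=len(temp_genes))
    temp_sign = rng.choice([-1.0, 1.0], size=len(temp_genes))
    fc_temp = {g: float(f) ** float(s) for g, f, s in zip(temp_genes, temp_fc, temp_sign)}

    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=len(genes))
    cond_labels = [c for c, _ in config.conditions]
    theta = pd.DataFrame(
        np.tile(base[:, None], (1, len(cond_labels))), index=genes, columns=cond_labels
    )
    test = config.resolved_test_condition
    for g, f in fc_up.items():
        theta.loc[g, test] += np.log2(f)
    for g, f in fc_down.items():
        theta.loc[g, test] -= np.log2(f)
    base_temp = config.conditions[0][1]
    warm_conditions = [c for c, t in config.conditions if t != base_temp]
    for g, f in fc_temp.items():
        theta.loc[g, warm_conditions] += np.log2(f)

    plm = _generate_probe_level(
        theta,
        probeset_to_gene,
        config.conditions,
        config.replicates_per_condition,
        config.probes_per_set,
        config.affinity_log2_sd,
        config.noise_sd,
        rng,
        name=f"sim_seed{config.seed}",
    )
    truth = GroundTruth(
        planted_up={g: float(f) for g, f in fc_up.items()},
        planted_down={g: float(f) for g, f in fc_down.items()},
        temperature_genes={g: float(f) for g, f in fc_temp.items()},
        probeset_to_gene=probeset_to_gene,
        extras={"test_condition": test, "baseline_temperature": base_temp},
    )
    return plm, truth


def _censoring_rate_for(c: float, hazards: np.ndarray) -> float:
    """P(censored) for exponential event/censoring with given rates."""
    return float(np.mean(c / (c + hazards)))


def solve_censoring_rate(target: float, hazards: np.ndarray) -> float:
    """Exponential censoring rate that yields the requested censoring proportion."""
    if target <= 0:
        return 0.0
    hi = float(hazards.max())
    upper = hi
    while _censoring_rate_for(upper, hazards) < target:
        upper *= 2.0
        if upper > 1e12 * hi:  # pragma: no cover - unreachable for target < 1
            break
    return float(brentq(lambda c: _censoring_rate_for(c, hazards) - target, 1e-12 * hi, upper))


def simulate_tumor_cohort(config: CohortConfig) -> tuple[TumorCohort, GroundTruth]:
    """Simulate a survival-annotated tumor cohort with a planted aggressive subgroup.

    Signature genes are named ``SIG####`` (shared across cohorts built with the
    same gene counts, so independent cohorts share the planted program);
    background genes are ``BG####``.
    """
    rng = np.random.default_rng(config.seed)
    sig_genes = [f"SIG{i:04d}" for i in range(config.n_signature_genes)]
    bg_genes = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    genes = sig_genes + bg_genes
    tumors = [f"T{i:04d}" for i in range(config.n_tumors)]

    n_aggr = max(1, int(round(config.aggressive_fraction * config.n_tumors)))
    aggressive = np.zeros(config.n_tumors, dtype=bool)
    aggressive[rng.choice(config.n_tumors, size=n_aggr, replace=False)] = True

    mu = rng.normal(7.0, 1.0, size=len(genes))
    expr = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), config.n_tumors))
    expr[: len(sig_genes), aggressive] += config.expression_shift
    expression = pd.DataFrame(expr, index=genes, columns=tumors)

    hazards = np.where(aggressive, config.baseline_hazard * config.hazard_ratio, config.baseline_hazard)
    event_times = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        c = solve_censoring_rate(config.censoring_rate, hazards)
        censor_times = rng.exponential(1.0 / c, size=config.n_tumors)
    else:
        censor_times = np.full(config.n_tumors, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    survival = pd.DataFrame(
        {"time": observed, "event": event}, index=pd.Index(tumors, name="tumor_id")
    )

    cohort = TumorCohort(
        expression,
        survival,
        time_unit=config.time_unit,
        endpoint=config.endpoint,
        name=f"cohort_seed{config.seed}",
    )
    truth = GroundTruth(
        planted_up={g: 2.0**config.expression_shift for g in sig_genes},
        aggressive_tumors=[t for t, a in zip(tumors, aggressive) if a],
        true_hazard_ratio=float(config.hazard_ratio),
        extras={"signature_genes": sig_genes},
    )
    return cohort, truth


def simulate_discovery_scenario(
    seed: int = 0,
    n_probesets: int = 2000,
    probes_per_set: int = 11,
    replicates: int = 3,
    n_common_up: int = 40,
    n_common_down: int = 44,
    n_ts_only_up: int = 40,
    n_ts_only_down: int = 51,
    n_tr_only: int = 100,
    n_temperature_genes: int = 20,
    fold_change_range: tuple[float, float] = (2.0, 8.0),
    temperature_fold_range: tuple[float, float] = (1.5, 3.0),
    noise_sd: float = 0.25,
    redundancy_fraction: float = 0.1,
    affinity_log2_sd: float = 0.7,
) -> tuple[dict[str, ProbeLevelMatrix], GroundTruth]:
    """Simulate the full three-experiment discovery design plus temperature control.

    Returns four probe-level experiments sharing one gene universe:

    - ``exp1``: control / transformation-deficient / transforming conditions at
      the non-permissive temperature (ANOVA regime);
    - ``cef_ts`` and ``cnr_ts``: temperature-sensitive mutant at permissive vs
      non-permissive temperature (pairwise regime);
    - ``temp_control``: no-oncogene virus at both temperatures.

    Planted classes: a *common program* regulated in all three systems, a
    *ts-only* program regulated in both temperature-sensitive experiments but
    not the first, a *TR-only* class seen only in the first experiment, and
    temperature-responsive genes that confound the two ts comparisons.
    """
    rng = np.random.default_rng(seed)
    n_genes = int(round(n_probesets / (1.0 + redundancy_fraction)))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_dup = n_probesets - n_genes
    dup = list(rng.choice(genes, size=n_dup, replace=False)) if n_dup else []
    probeset_to_gene = {f"PS_{g}_a": g for g in genes}
    probeset_to_gene.update({f"PS_{g}_b": g for g in dup})

    counts = [n_common_up, n_common_down, n_ts_only_up, n_ts_only_down, n_tr_only, n_temperature_genes]
    if sum(counts) > n_genes:
        raise ConfigurationError("planted classes exceed the gene universe")
    perm = rng.permutation(n_genes)
    cut = np.cumsum(counts)
    pick = lambda a, b: [genes[i] for i in perm[a:b]]
    common_up, common_down = pick(0, cut[0]), pick(cut[0], cut[1])
    ts_up, ts_down = pick(cut[1], cut[2]), pick(cut[2], cut[3])
    tr_only = pick(cut[3], cut[4])
    temp_genes = pick(cut[4], cut[5])

    lo, hi = fold_change_range
    lfc = {}
    for g in common_up + ts_up:
        lfc[g] = float(np.log2(rng.uniform(lo, hi)))
    for g in common_down + ts_down:
        lfc[g] = -float(np.log2(rng.uniform(lo, hi)))
    tr_only_up = tr_only[: len(tr_only) // 2]
    for g in tr_only:
        s = 1.0 if g in set(tr_only_up) else -1.0
        lfc[g] = s * float(np.log2(rng.uniform(lo, hi)))
    tlo, thi = temperature_fold_range
    temp_lfc = {
        g: float(s) * float(np.log2(rng.uniform(tlo, thi)))
        for g, s in zip(temp_genes, rng.choice([-1.0, 1.0], size=len(temp_genes)))
    }

    base = pd.Series(rng.normal(7.0, 1.0, size=n_genes), index=genes)
    transformed_in_exp1 = set(common_up + common_down + tr_only)
    transformed_in_ts = set(common_up + common_down + ts_up + ts_down)

    def theta_for(conditions, transformed_conditions, transformed_genes, permissive_temp="37.5"):
        th = pd.DataFrame(
            np.tile(base.to_numpy()[:, None], (1, len(conditions))),
            index=genes,
            columns=[c for c, _ in conditions],
        )
        for cond, temp in conditions:
            if cond in transformed_conditions:
                for g in transformed_genes:
                    th.loc[g, cond] += lfc[g]
            if temp == permissive_temp:  # temperature response at the lower temperature
                for g, d in temp_lfc.items():
                    th.loc[g, cond] += d
        return th

    exp1_conditions = (("RCASBP-A", "41.5"), ("NY315", "41.5"), ("SR-A", "41.5"))
    ts_conditions = (("NY72-4@41.5", "41.5"), ("NY72-4@37.5", "37.5"))
    temp_conditions = (("RCASBP-A@41.5", "41.5"), ("RCASBP-A@37.5", "37.5"))

    bundles = {}
    for name, conditions, tset, tgenes in (
        ("exp1", exp1_conditions, {"SR-A"}, transformed_in_exp1),
        ("cef_ts", ts_conditions, {"NY72-4@37.5"}, transformed_in_ts),
        ("cnr_ts", ts_conditions, {"NY72-4@37.5"}, transformed_in_ts),
        ("temp_control", temp_conditions, set(), set()),
    ):
        th = theta_for(conditions, tset, tgenes)
        bundles[name] = _generate_probe_level(
            th, probeset_to_gene, conditions, replicates, probes_per_set,
            affinity_log2_sd, noise_sd, rng, name=name,
        )

    truth = GroundTruth(
        planted_up={g: float(2.0 ** lfc[g]) for g in common_up + ts_up + tr_only_up},
        planted_down={g: float(2.0 ** -lfc[g]) for g in common_down + ts_down + tr_only if lfc[g] < 0},
        temperature_genes={g: float(2.0**d) for g, d in temp_lfc.items()},
        probeset_to_gene=probeset_to_gene,
        extras={
            "common_up": common_up,
            "common_down": common_down,
            "ts_only_up": ts_up,
            "ts_only_down": ts_down,
            "tr_only": tr_only,
            "csr_genes": common_up + common_down + ts_up + ts_down,
        },
    )
    return bundles, truth
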