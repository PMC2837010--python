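"""Differential expression calls, permutation FDR, and gene-set algebra.

All tests run on log2 expression values; fold changes are ratios of group
geometric means reported on the linear scale with a direction label. A feature
passes the pairwise regime at fold change >= 2 and p <= 0.05 (unpaired
two-tailed t-test), and the transformation regime at ANOVA p <= 0.01 with a
>= 2-fold contrast that is specific to the test condition. The FDR of either
call rule is estimated by permuting sample-to-group labels within the
experimental group and re-applying the identical rule.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings
from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .containers import DifferentialResult, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_differential",
    "anova_transformation_test",
    "estimate_permutation_fdr",
    "filter_temperature_confounded",
    "build_gene_sets",
    "platform_concordance",
]

FdrEstimate = namedtuple("FdrEstimate", ["fdr_estimate", "observed_count", "mean_null_count"])
Concordance = namedtuple("Concordance", ["spearman_rho", "ols_slope", "spearman_p"])


def _direction(log2_ratio: np.ndarray) -> np.ndarray:
    return np.where(log2_ratio > 0, "up", np.where(log2_ratio < 0, "down", "none"))


def pairwise_differential(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    config: PipelineConfig | None = None,
) -> DifferentialResult:
    """Unpaired two-tailed t-test of group_b vs group_a with the two-fold rule.

    Fold change is the ratio of group geometric means; direction is the sign of
    the log2 mean difference (group_b relative to group_a).
    """
    config = config or PipelineConfig()
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    log = expr.log2()
    a = log[group_a].to_numpy()
    b = log[group_b].to_numpy()
    d = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate rows handled below
        res = stats.ttest_ind(b, a, axis=1, equal_var=not config.welch)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    # zero variance in both groups: p = 1 when means agree, p -> 0 otherwise
    p[degenerate & (d == 0)] = 1.0
    p[degenerate & (d != 0)] = 0.0
    table = pd.DataFrame(
        {
            "fold_change": np.exp2(np.abs(d)),
            "log2_ratio": d,
            "p_value": p,
            "direction": _direction(d),
        },
        index=expr.values.index,
    )
    table["passes"] = (table["fold_change"] >= config.fc_threshold) & (
        table["p_value"] <= config.alpha_pairwise
    )
    return DifferentialResult(table, "ttest", comparison=f"{'+'.join(group_b)} vs {'+'.join(group_a)}")


def anova_transformation_test(
    expr: ExpressionMatrix,
    control_groups: tuple[list[str], list[str]],
    test_group: list[str],
    config: PipelineConfig | None = None,
) -> DifferentialResult:
    """One-way ANOVA across two control groups and one test group.

    A feature passes when the ANOVA p-value is <= alpha_anova, the maximum
    pairwise ratio of group geometric means is >= the fold threshold, and the
    test group differs from the pooled controls in a consistent direction by
    >= the fold threshold. Features whose only large contrast is between the
    two control groups get direction "none" and do not pass.
    """
    config = config or PipelineConfig()
    if len(control_groups) != 2:
        raise ValueError("exactly two control groups are required")
    groups = [list(control_groups[0]), list(control_groups[1]), list(test_group)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two samples")
    log = expr.log2()
    mats = [log[g].to_numpy() for g in groups]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.f_oneway(*mats, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # all groups constant and equal

    m1, m2, mt = (m.mean(axis=1) for m in mats)
    pooled = np.concatenate([mats[0], mats[1]], axis=1).mean(axis=1)
    d = mt - pooled
    max_pair = np.maximum.reduce([np.abs(m1 - m2), np.abs(mt - m1), np.abs(mt - m2)])
    log_thr = np.log2(config.fc_threshold)
    consistent = (np.sign(mt - m1) == np.sign(mt - m2)) & (np.abs(d) >= log_thr)
    direction = np.where(consistent, _direction(d), "none")
    passes = (p <= config.alpha_anova) & (max_pair >= log_thr) & consistent
    table = pd.DataFrame(
        {
            "fold_change": np.exp2(max_pair),
            "log2_ratio": d,
            "p_value": p,
            "direction": direction,
            "passes": passes,
        },
        index=expr.values.index,
    )
    return DifferentialResult(table, "anova", comparison="transformation ANOVA")


def _n_distinct_arrangements(sizes: list[int]) -> int:
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    return total


def _enumerate_assignments(samples: list[str], sizes: list[int]):
    """All distinct partitions of samples into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield [list(samples)]
        return
    for combo in itertools.combinations(range(len(samples)), sizes[0]):
        chosen = [samples[i] for i in combo]
        rest = [s for i, s in enumerate(samples) if i not in set(combo)]
        for tail in _enumerate_assignments(rest, sizes[1:]):
            yield [chosen] + tail


def estimate_permutation_fdr(
    expr: ExpressionMatrix,
    groups: list[list[str]],
    call_rule,
    config: PipelineConfig | None = None,
) -> FdrEstimate:
    """Estimate the FDR of a call rule by within-group label permutation.

    ``call_rule(expr, groups, config) -> DifferentialResult`` is re-applied to
    permuted sample-to-group assignments; the estimate is the mean null pass
    count divided by the observed pass count. Arrangements that reproduce the
    observed partition (as unordered groups) are excluded — they carry the
    signal, not the null. Fewer than 20 distinct label arrangements triggers
    exact enumeration instead of random sampling.
    """
    config = config or PipelineConfig()
    observed = int(call_rule(expr, groups, config).table["passes"].sum())

    samples = [s for g in groups for s in g]
    sizes = [len(g) for g in groups]
    original = frozenset(frozenset(g) for g in groups)
    n_arrangements = _n_distinct_arrangements(sizes)
    null_counts = []
    if n_arrangements < 20:
        logger.warning(
            "only %d distinct label arrangements; enumerating exactly", n_arrangements
        )
        for assignment in _enumerate_assignments(samples, sizes):
            if frozenset(frozenset(g) for g in assignment) == original:
                continue
            null_counts.append(int(call_rule(expr, assignment, config).table["passes"].sum()))
    else:
        rng = np.random.default_rng(config.seed)
        drawn = 0
        while drawn < config.n_permutations:
            perm = [samples[i] for i in rng.permutation(len(samples))]
            assignment, k = [], 0
            for s in sizes:
                assignment.append(perm[k : k + s])
                k += s
            if frozenset(frozenset(g) for g in assignment) == original:
                continue
            drawn += 1
            null_counts.append(int(call_rule(expr, assignment, config).table["passes"].sum()))
    mean_null = float(np.mean(null_counts))
    if observed == 0:
        logger.warning("no observed calls; permutation FDR reported as 0")
        return FdrEstimate(0.0, 0, mean_null)
    return FdrEstimate(mean_null / observed, observed, mean_null)


def pairwise_rule(expr, groups, config) -> DifferentialResult:
    """Call-rule adapter: groups = [group_a, group_b]."""
    return pairwise_differential(expr, groups[0], groups[1], config)


def anova_rule(expr, groups, config) -> DifferentialResult:
    """Call-rule adapter: groups = [control_1, control_2, test]."""
    return anova_transformation_test(expr, (groups[0], groups[1]), groups[2], config)


def filter_temperature_confounded(
    ts_set: GeneSet,
    temperature_result: DifferentialResult,
    wt_result_at_41: DifferentialResult,
) -> tuple[GeneSet, GeneSet]:
    """Remove temperature-regulated genes from a temperature-sensitive call set.

    A gene is removed iff it is in the temperature-regulated list (passing the
    temperature-control comparison) and its temperature |log2 FC| is >= its
    |log2 FC| in the transforming-vs-control comparison at the non-permissive
    temperature. Genes absent from that comparison count as fold change 1
    (hence are removed), the conservative convention. The removed set carries
    both magnitudes in its ``evidence`` table.
    """
    temp_pass = temperature_result.table[temperature_result.table["passes"]]
    retained, removed, rows = {}, {}, []
    for gene, direction in ts_set.members.items():
        if gene not in temp_pass.index:
            retained[gene] = direction
            continue
        t_mag = abs(float(temp_pass.loc[gene, "log2_ratio"]))
        if gene in wt_result_at_41.table.index:
            w_mag = abs(float(wt_result_at_41.table.loc[gene, "log2_ratio"]))
        else:
            logger.info("gene %s absent from the wt comparison; treated as fold change 1", gene)
            w_mag = 0.0
        if t_mag >= w_mag:
            removed[gene] = direction
            rows.append({"gene_id": gene, "temperature_abs_log2fc": t_mag, "wt_abs_log2fc": w_mag})
        else:
            retained[gene] = direction
    evidence = pd.DataFrame(rows, columns=["gene_id", "temperature_abs_log2fc", "wt_abs_log2fc"])
    return (
        GeneSet(f"{ts_set.name}_filtered", retained, ts_set.provenance + ["temperature filter"]),
        GeneSet(f"{ts_set.name}_temperature_removed", removed, ts_set.provenance, evidence=evidence),
    )


def _carry_directions(ids: set[str], *sources: GeneSet) -> dict[str, str]:
    out = {}
    for g in sorted(ids):
        dirs = [s.members[g] for s in sources if g in s.members]
        if len(set(dirs)) > 1:
            logger.warning("direction conflict for %s: %s; keeping %s", g, dirs, dirs[0])
        out[g] = dirs[0]
    return out


def build_gene_sets(tr: GeneSet, cef_ts: GeneSet, cnr_ts: GeneSet) -> dict[str, GeneSet]:
    """Set algebra over the three discovery systems.

    common_all3 = TR ∩ CEF_ts ∩ CNR_ts; ts_only = (CEF_ts ∩ CNR_ts) \\ TR;
    CSR = common_all3 ∪ ts_only (a disjoint union); TR ∩ CEF_ts is also
    reported. Direction conflicts resolve to the TR direction when present,
    else the CEF_ts direction.
    """
    tr_ids, cef_ids, cnr_ids = tr.ids, cef_ts.ids, cnr_ts.ids
    common = tr_ids & cef_ids & cnr_ids
    ts_only = (cef_ids & cnr_ids) - tr_ids
    csr = common | ts_only
    tr_cef = tr_ids & cef_ids
    mk = lambda name, ids, prov: GeneSet(name, _carry_directions(ids, tr, cef_ts, cnr_ts), prov)
    return {
        "TR": tr,
        "CEF_ts": cef_ts,
        "CNR_ts": cnr_ts,
        "common_all3": mk("common_all3", common, ["TR ∩ CEF_ts ∩ CNR_ts"]),
        "ts_only": mk("ts_only", ts_only, ["(CEF_ts ∩ CNR_ts) \\ TR"]),
        "CSR": mk("CSR", csr, ["common_all3 ∪ ts_only"]),
        "TR∩CEF_ts": mk("TR∩CEF_ts", tr_cef, ["TR ∩ CEF_ts"]),
    }


def platform_concordance(paired_log_ratios) -> Concordance:
    """Spearman rank correlation and OLS slope (y on x) of paired log ratios."""
    pairs = np.asarray(list(paired_log_ratios), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least three (x, y) pairs")
    if not np.isfinite(pairs).all():
        raise ValueError("pairs must be finite")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, rho_p = stats.spearmanr(x, y)
    slope = stats.linregress(x, y).slope
    return Concordance(float(rho), float(slope), float(rho_p))
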