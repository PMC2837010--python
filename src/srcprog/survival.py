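"""Signature scoring and Kaplan-Meier / log-rank survival evaluation.

Tumors are scored by the average gene-wise mean-centered log2 expression of
the signature genes; the top quartile of scores forms the "aggressive-high"
group, compared with the remaining tumors by the product-limit estimator,
restricted mean survival (area under the KM curve up to a truncation time),
and the unweighted log-rank test. KM fitting and the k-group log-rank
statistic are delegated to lifelines; the restricted mean is integrated
directly from the step function.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .containers import ScoreVector, SurvivalCurve, TumorCohort

logger = logging.getLogger(__name__)

__all__ = [
    "km_estimate",
    "restricted_mean_survival",
    "logrank_test",
    "aggressive_score",
    "upper_quartile_split",
    "evaluate_signature",
    "EvaluationReport",
]


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit curve (events precede censorings at ties)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return SurvivalCurve(
        times=event_times,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
        survival=surv,
        max_time=float(t.max()),
        n=int(t.size),
    )


def restricted_mean_survival(curve: SurvivalCurve, tau: float) -> float:
    """Area under the KM step function on [0, tau]."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tau > curve.max_time:
        logger.warning(
            "tau %.4g beyond the last observed time %.4g; S held at its last value", tau, curve.max_time
        )
    area, prev_t, prev_s = 0.0, 0.0, 1.0
    for t, s in zip(curve.times, curve.survival):
        if t >= tau:
            break
        area += prev_s * (t - prev_t)
        prev_t, prev_s = float(t), float(s)
    area += prev_s * (tau - prev_t)
    return float(area)


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Unweighted k-group log-rank test; returns (chi_square, p).

    p is taken from the chi-square distribution with k-1 degrees of freedom.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    if not (t.size == e.size == g.size):
        raise ValueError("times, events and group labels must align")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def aggressive_score(cohort: TumorCohort, signature_features) -> ScoreVector:
    """Average gene-wise mean-centered log2 expression of the signature genes."""
    features = list(dict.fromkeys(signature_features))
    present = [f for f in features if f in cohort.expression.index]
    dropped = sorted(set(features) - set(present))
    if dropped:
        logger.info("%d signature features absent from the cohort: %s...", len(dropped), dropped[:5])
    if not present:
        raise ValueError("no signature features present in the cohort")
    sub = cohort.expression.loc[present]
    centered = sub.sub(sub.mean(axis=1), axis=0)
    return ScoreVector(scores=centered.mean(axis=0))


def upper_quartile_split(scores: ScoreVector, quartile: float = 0.25) -> pd.Series:
    """Label the ceil(n * quartile) highest-scoring tumors "aggressive-high".

    Boundary ties break by stable (lexicographic) tumor-ID order.
    """
    s = scores.scores
    n = len(s)
    if n < 4:
        raise ValueError("need at least four tumors")
    n_high = math.ceil(n * quartile)
    order = pd.DataFrame({"score": s, "tumor_id": s.index.astype(str)}).sort_values(
        ["score", "tumor_id"], ascending=[False, True], kind="stable"
    )
    high = set(order.index[:n_high])
    labels = pd.Series(
        ["aggressive-high" if t in high else "rest" for t in s.index], index=s.index, name="group"
    )
    scores.labels = labels
    return labels


@dataclass
class EvaluationReport:
    """Machine-readable outcome of one signature-vs-cohort evaluation."""

    group_sizes: dict[str, int]
    restricted_means: dict[str, float]
    tau: float
    time_unit: str
    endpoint: str
    chi_square: float
    p_value: float
    n_signature_used: int
    curves: dict[str, pd.DataFrame]
    scores: pd.Series
    labels: pd.Series

    def to_dict(self) -> dict:
        return {
            "group_sizes": self.group_sizes,
            "restricted_means": self.restricted_means,
            "tau": self.tau,
            "time_unit": self.time_unit,
            "endpoint": self.endpoint,
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "n_signature_used": self.n_signature_used,
        }


def evaluate_signature(
    cohort: TumorCohort, signature_features, quartile: float = 0.25
) -> EvaluationReport:
    """Score, split at the upper quartile, and compare survival between groups."""
    sv = aggressive_score(cohort, signature_features)
    labels = upper_quartile_split(sv, quartile=quartile)
    times = cohort.survival["time"].to_numpy(float)
    events = cohort.survival["event"].to_numpy(int)
    tau = float(times.max())
    chi2, p = logrank_test(times, events, labels.to_numpy())
    group_sizes, rmeans, curves = {}, {}, {}
    for grp in ("aggressive-high", "rest"):
        mask = (labels == grp).to_numpy()
        group_sizes[grp] = int(mask.sum())
        curve = km_estimate(times[mask], events[mask])
        rmeans[grp] = restricted_mean_survival(curve, tau)
        curves[grp] = curve.to_frame()
    n_used = sum(1 for f in dict.fromkeys(signature_features) if f in cohort.expression.index)
    return EvaluationReport(
        group_sizes=group_sizes,
        restricted_means=rmeans,
        tau=tau,
        time_unit=cohort.time_unit,
        endpoint=cohort.endpoint,
        chi_square=chi2,
        p_value=p,
        n_signature_used=n_used,
        curves=curves,
        scores=sv.scores,
        labels=labels,
    )
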