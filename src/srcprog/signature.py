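"""Derivation of the aggressive tumor gene signature by clustering enrichment.

Training tumors are clustered on the up-regulated, ortholog-mapped members of
the common regulated gene set (1 - Pearson correlation distance over gene-wise
mean-centered expression, average linkage, tree cut at k clusters). The
cluster with the poorest restricted mean survival supplies candidate genes
(one-tailed t-test, higher in the poor cluster, p < 0.05), and the signature
is the intersection of the candidate lists from two independent training
cohorts.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import GeneSet, ProbeAnnotation, SignatureResult, TumorCohort
from .survival import km_estimate, logrank_test, restricted_mean_survival

logger = logging.getLogger(__name__)

__all__ = [
    "map_orthologs",
    "cluster_samples",
    "select_poor_cluster",
    "candidate_genes_from_cluster",
    "derive_aggressive_signature",
    "PoorClusterResult",
]


def map_orthologs(
    gene_set: GeneSet, annotation: ProbeAnnotation, direction_filter: str = "up"
) -> list[str]:
    """Expand the up-regulated members of a gene set to target-platform features.

    Many-to-many mappings are kept; genes without an ortholog entry are dropped
    and logged. The output is de-duplicated and order-stable.
    """
    members = [g for g, d in gene_set.members.items() if d == direction_filter]
    out, dropped = [], []
    for g in members:
        targets = annotation.targets_of(g)
        if not targets:
            dropped.append(g)
        out.extend(targets)
    if dropped:
        logger.info("%d genes without orthologs dropped: %s...", len(dropped), dropped[:5])
    out = list(dict.fromkeys(out))
    if not out:
        raise ValueError("no ortholog-mapped features to cluster on")
    return out


def cluster_samples(
    cohort: TumorCohort, features, k: int = 4, center: bool = True
) -> pd.Series:
    """Agglomerative clustering of tumors with 1 - Pearson distance, average linkage.

    Rows are gene-wise mean-centered before computing tumor-tumor correlations;
    the dendrogram is cut to (at most) exactly k clusters. Deterministic for a
    fixed input.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if cohort.n_tumors < k:
        raise ValueError("fewer tumors than clusters")
    missing = [f for f in features if f not in cohort.expression.index]
    if missing:
        raise KeyError(f"features absent from cohort: {missing[:10]}")
    x = cohort.expression.loc[list(features)]
    if center:
        x = x.sub(x.mean(axis=1), axis=0)
    profiles = x.to_numpy().T  # tumor rows
    sds = profiles.std(axis=1)
    if (sds == 0).any():
        bad = [cohort.tumor_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance tumors over the clustering features: {bad}")
    d = pdist(profiles, metric="correlation")
    labels = fcluster(linkage(d, method="average"), t=k, criterion="maxclust")
    return pd.Series(labels, index=cohort.tumor_ids, name="cluster")


class PoorClusterResult:
    """Poor-prognosis cluster choice with per-cluster survival summaries."""

    def __init__(self, cluster_id: int, restricted_means: dict[int, float], logrank_p: float, tau: float):
        self.cluster_id = int(cluster_id)
        self.restricted_means = restricted_means
        self.logrank_p = float(logrank_p)
        self.tau = float(tau)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PoorClusterResult(cluster_id={self.cluster_id}, "
            f"restricted_means={self.restricted_means}, logrank_p={self.logrank_p:.3g})"
        )


def select_poor_cluster(
    labels: pd.Series, cohort: TumorCohort, min_cluster_size: int = 2
) -> PoorClusterResult:
    """Pick the cluster with the smallest restricted mean survival.

    The restricted mean truncates at the largest observed time in the cohort.
    Clusters smaller than ``min_cluster_size`` are excluded from candidacy with
    a warning; at least two eligible clusters are required. Ties resolve to the
    smallest cluster index with a warning. Also reports the k-group log-rank p
    over the eligible clusters.
    """
    surv = cohort.survival.loc[labels.index]
    times = surv["time"].to_numpy(float)
    events = surv["event"].to_numpy(int)
    tau = float(times.max())
    eligible, rmeans = [], {}
    for cid in sorted(labels.unique()):
        mask = (labels == cid).to_numpy()
        if mask.sum() < min_cluster_size:
            logger.warning("cluster %d has %d tumors (< %d); excluded", cid, mask.sum(), min_cluster_size)
            continue
        eligible.append(cid)
        rmeans[int(cid)] = restricted_mean_survival(km_estimate(times[mask], events[mask]), tau)
    if len(eligible) < 2:
        raise ValueError("need at least two clusters with enough tumors")
    elig_mask = labels.isin(eligible).to_numpy()
    _, p = logrank_test(times[elig_mask], events[elig_mask], labels.to_numpy()[elig_mask])
    best = min(rmeans.values())
    winners = [cid for cid in sorted(rmeans) if rmeans[cid] == best]
    if len(winners) > 1:
        logger.warning("restricted-mean tie between clusters %s; keeping %d", winners, winners[0])
    return PoorClusterResult(winners[0], rmeans, p, tau)


def candidate_genes_from_cluster(
    cohort: TumorCohort, labels: pd.Series, poor_id: int, alpha: float = 0.05
) -> GeneSet:
    """Genes significantly higher in the poor cluster than in all other tumors.

    One-tailed (greater) unpaired pooled-variance t-test per feature; features
    with zero variance in both groups are excluded with a log entry.
    """
    poor = labels.index[labels == poor_id]
    rest = labels.index[labels != poor_id]
    if len(poor) < 2 or len(rest) < 2:
        raise ValueError("poor cluster and its complement each need at least two tumors")
    a = cohort.expression[list(poor)].to_numpy()
    b = cohort.expression[list(rest)].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows excluded below
        res = stats.ttest_ind(a, b, axis=1, equal_var=True, alternative="greater")
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d zero-variance features excluded", int(degenerate.sum()))
    sel = (~degenerate) & (p < alpha)
    members = {str(g): "up" for g in cohort.expression.index[sel]}
    return GeneSet(
        name=f"{cohort.name or 'cohort'}_poor_cluster_candidates",
        members=members,
        provenance=[f"one-tailed t-test, cluster {poor_id} vs rest, p < {alpha}"],
    )


def derive_aggressive_signature(candidates_a: GeneSet, candidates_b: GeneSet) -> SignatureResult:
    """Intersect the two training candidate lists into the aggressive signature.

    Concordance is the intersection size over the smaller candidate list.
    """
    inter = sorted(candidates_a.ids & candidates_b.ids)
    smaller = min(len(candidates_a), len(candidates_b))
    concordance = len(inter) / smaller if smaller else 0.0
    return SignatureResult(
        genes=inter,
        candidates_a=candidates_a,
        candidates_b=candidates_b,
        concordance=concordance,
    )
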