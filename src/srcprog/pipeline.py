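"""End-to-end orchestration: discovery -> signature -> survival evaluation.

``run_discovery`` executes normalization, probe-set summarization, the three
differential regimes, permutation FDR, gene collapse, the temperature filter
and the set algebra on one bundle of experiments (simulated on the fly by
default). ``run_signature`` maps the up-regulated common-set genes onto two
training tumor cohorts, derives the aggressive signature by the
clustering-enrichment regime, and evaluates it on test cohorts with the
upper-quartile score split. Both return a RunManifest recording the config,
seeds, per-stage summaries and digests of written files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .containers import ExpressionMatrix, GeneSet, GroundTruth, ProbeAnnotation, TumorCohort
from .differential import (
    anova_rule,
    anova_transformation_test,
    build_gene_sets,
    estimate_permutation_fdr,
    filter_temperature_confounded,
    pairwise_differential,
    pairwise_rule,
)
from .io import write_differential, write_gene_set_tsv, write_gmt, write_json
from .preprocess import collapse_to_genes, compute_mbei, normalize_experiment, scale_to_common_median
from .signature import (
    candidate_genes_from_cluster,
    cluster_samples,
    derive_aggressive_signature,
    map_orthologs,
    select_poor_cluster,
)
from .simulate import simulate_discovery_scenario
from .survival import evaluate_signature

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "DiscoveryRun", "SignatureRun", "run_discovery", "run_signature"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, summaries, file digests."""

    config: dict
    seeds: dict[str, int]
    stage_summaries: dict = field(default_factory=dict)
    file_digests: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def register(self, path: Path) -> None:
        self.file_digests[str(path)] = _sha256(path)

    def to_json(self, path) -> Path:
        return write_json(dataclasses.asdict(self), path)


@dataclass
class DiscoveryRun:
    gene_sets: dict[str, GeneSet]
    gene_results: dict[str, object]
    fdr: dict[str, tuple]
    removed_by_temperature: dict[str, GeneSet]
    manifest: RunManifest
    truth: GroundTruth | None = None


def _split_by_temperature(expr: ExpressionMatrix) -> tuple[list[str], list[str]]:
    """(non-permissive group, permissive group) sample ids by temperature label."""
    temps = expr.samples["temperature"].astype(float)
    hi, lo = temps.max(), temps.min()
    if hi == lo:
        raise ValueError("experiment has a single temperature; cannot form a ts comparison")
    return list(temps.index[temps == hi]), list(temps.index[temps == lo])


def run_discovery(
    config: PipelineConfig | None = None,
    bundle: dict | None = None,
    annotation: ProbeAnnotation | None = None,
    seed: int | None = None,
    outdir=None,
    **scenario_kwargs,
) -> DiscoveryRun:
    """Discovery stage: preprocessing, differential calls, FDR, set algebra.

    ``bundle`` maps experiment names (exp1, cef_ts, cnr_ts, temp_control) to
    probe-level matrices; when omitted, a synthetic scenario is simulated with
    ``seed`` and any scenario keyword overrides. ``exp1`` must have its two
    control conditions first and the transforming condition last (sample-sheet
    order); the ts experiments and the temperature control are split by their
    temperature labels.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    truth = None
    if bundle is None:
        bundle, truth = simulate_discovery_scenario(seed=seed, **scenario_kwargs)
        annotation = ProbeAnnotation(
            pd.DataFrame(
                {
                    "gene_id": list(truth.probeset_to_gene.values()),
                    "gene_symbol": list(truth.probeset_to_gene.values()),
                },
                index=pd.Index(list(truth.probeset_to_gene), name="probeset_id"),
            )
        )
    if annotation is None:
        raise ValueError("an annotation is required for externally supplied bundles")
    for key in ("exp1", "cef_ts", "cnr_ts", "temp_control"):
        if key not in bundle:
            raise ValueError(f"bundle missing experiment {key!r}")

    manifest = RunManifest(config=dataclasses.asdict(config), seeds={"discovery": seed})

    names = ["exp1", "cef_ts", "cnr_ts", "temp_control"]
    scaled = dict(zip(names, scale_to_common_median([bundle[n] for n in names])))
    exprs = {}
    for name in names:
        norm = normalize_experiment(
            scaled[name], rank_threshold=config.rank_threshold, max_iter=config.invariant_max_iter
        )
        exprs[name] = compute_mbei(norm)

    # exp1: ANOVA regime; condition order = two controls then the transforming one
    e1 = exprs["exp1"]
    conds = list(dict.fromkeys(e1.samples["condition"]))
    if len(conds) != 3:
        raise ValueError(f"exp1 must have exactly three conditions, got {conds}")
    g_ctrl1, g_ctrl2, g_test = (e1.samples_for(c) for c in conds)
    tr_ps = anova_transformation_test(e1, (g_ctrl1, g_ctrl2), g_test, config)
    wt_ps = pairwise_differential(e1, g_ctrl1, g_test, config)  # transforming vs control

    pairwise_results = {}
    for name in ("cef_ts", "cnr_ts", "temp_control"):
        non_perm, perm = _split_by_temperature(exprs[name])
        pairwise_results[name] = pairwise_differential(exprs[name], non_perm, perm, config)

    fdr = {
        "TR": estimate_permutation_fdr(e1, [g_ctrl1, g_ctrl2, g_test], anova_rule, config),
        "CEF_ts": estimate_permutation_fdr(
            exprs["cef_ts"], list(_split_by_temperature(exprs["cef_ts"])), pairwise_rule, config
        ),
        "CNR_ts": estimate_permutation_fdr(
            exprs["cnr_ts"], list(_split_by_temperature(exprs["cnr_ts"])), pairwise_rule, config
        ),
    }

    gene_results = {
        "TR": collapse_to_genes(tr_ps, annotation),
        "CEF_ts": collapse_to_genes(pairwise_results["cef_ts"], annotation),
        "CNR_ts": collapse_to_genes(pairwise_results["cnr_ts"], annotation),
        "temperature": collapse_to_genes(pairwise_results["temp_control"], annotation),
        "wt_at_41": collapse_to_genes(wt_ps, annotation),
    }

    tr_set = gene_results["TR"].to_gene_set("TR", "transformation ANOVA")
    removed = {}
    filtered = {}
    for name in ("CEF_ts", "CNR_ts"):
        raw = gene_results[name].to_gene_set(name, "ts pairwise")
        kept, rem = filter_temperature_confounded(
            raw, gene_results["temperature"], gene_results["wt_at_41"]
        )
        kept.name = name
        filtered[name] = kept
        removed[name] = rem

    gene_sets = build_gene_sets(tr_set, filtered["CEF_ts"], filtered["CNR_ts"])

    manifest.stage_summaries = {
        "set_sizes": {k: len(v) for k, v in gene_sets.items()},
        "up_down": {k: [v.n_up, v.n_down] for k, v in gene_sets.items()},
        "temperature_removed": {k: len(v) for k, v in removed.items()},
        "fdr": {k: {"estimate": v.fdr_estimate, "observed": v.observed_count} for k, v in fdr.items()},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.register(write_gmt(gene_sets, outdir / "gene_sets.gmt"))
        manifest.register(write_gene_set_tsv(gene_sets, outdir / "gene_sets.tsv"))
        for name, res in gene_results.items():
            manifest.register(write_differential(res, outdir / f"differential_{name}.tsv"))
        manifest.to_json(outdir / "manifest.json")

    return DiscoveryRun(gene_sets, gene_results, fdr, removed, manifest, truth)


@dataclass
class SignatureRun:
    signature: object  # SignatureResult
    poor_clusters: dict[str, object]
    cluster_labels: dict[str, pd.Series]
    evaluations: dict[str, object]
    manifest: RunManifest


def _present_features(features: list[str], cohort: TumorCohort, name: str) -> list[str]:
    present = [f for f in features if f in cohort.expression.index]
    if len(present) < len(features):
        logger.info("%s: %d/%d clustering features present", name, len(present), len(features))
    if not present:
        raise ValueError(f"no clustering features present in cohort {name}")
    return present


def run_signature(
    csr_up: GeneSet | list[str],
    train_a: TumorCohort,
    train_b: TumorCohort,
    test_cohorts: dict[str, TumorCohort],
    config: PipelineConfig | None = None,
    annotation: ProbeAnnotation | None = None,
    outdir=None,
) -> SignatureRun:
    """Signature stage: cluster trainings, derive the signature, evaluate tests."""
    config = config or PipelineConfig()
    if isinstance(csr_up, GeneSet):
        if annotation is not None:
            features = map_orthologs(csr_up, annotation, direction_filter="up")
        else:
            features = sorted(csr_up.direction_subset("up").ids)
    else:
        features = list(csr_up)
    if not features:
        raise ValueError("empty clustering feature list")

    manifest = RunManifest(config=dataclasses.asdict(config), seeds={"signature": config.seed})

    candidates, poor, labels = {}, {}, {}
    for name, cohort in (("train_a", train_a), ("train_b", train_b)):
        feats = _present_features(features, cohort, name)
        lab = cluster_samples(cohort, feats, k=config.n_clusters)
        pc = select_poor_cluster(lab, cohort)
        cand = candidate_genes_from_cluster(cohort, lab, pc.cluster_id, alpha=config.alpha_signature)
        labels[name], poor[name], candidates[name] = lab, pc, cand

    signature = derive_aggressive_signature(candidates["train_a"], candidates["train_b"])
    if not signature.genes:
        raise RuntimeError(
            "empty signature: candidate counts were "
            f"A={len(candidates['train_a'])}, B={len(candidates['train_b'])}"
        )

    evaluations = {
        name: evaluate_signature(cohort, signature.genes, quartile=config.quartile)
        for name, cohort in test_cohorts.items()
    }

    manifest.stage_summaries = {
        "n_clustering_features": len(features),
        "candidate_counts": {k: len(v) for k, v in candidates.items()},
        "poor_clusters": {
            k: {"cluster": v.cluster_id, "logrank_p": v.logrank_p, "restricted_means": v.restricted_means}
            for k, v in poor.items()
        },
        "signature_size": len(signature.genes),
        "concordance": signature.concordance,
        "evaluations": {k: v.to_dict() for k, v in evaluations.items()},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sig_set = GeneSet("aggressive_signature", {g: "up" for g in signature.genes}, ["training intersection"])
        manifest.register(write_gmt([sig_set, candidates["train_a"], candidates["train_b"]], outdir / "signature.gmt"))
        report = {
            "signature": signature.genes,
            "concordance": signature.concordance,
            **manifest.stage_summaries,
        }
        manifest.register(write_json(report, outdir / "signature_report.json"))
        for name, ev in evaluations.items():
            for grp, curve in ev.curves.items():
                path = Path(outdir) / f"km_{name}_{grp.replace(' ', '_')}.tsv"
                curve.to_csv(path, sep="\t", index=False)
                manifest.register(path)
        manifest.to_json(outdir / "manifest.json")

    return SignatureRun(signature, poor, labels, evaluations, manifest)
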