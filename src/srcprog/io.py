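"""Plain-text readers and writers (TSV, GMT, JSON) for every pipeline stage."""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import (
    DifferentialResult,
    ExpressionMatrix,
    GeneSet,
    ProbeAnnotation,
    ProbeLevelMatrix,
    TumorCohort,
)

__all__ = [
    "write_probe_level",
    "read_probe_level",
    "write_expression",
    "read_expression",
    "write_cohort",
    "read_cohort",
    "write_gmt",
    "read_gmt",
    "write_gene_set_tsv",
    "write_differential",
    "read_annotation",
    "write_annotation",
]


def write_probe_level(plm: ProbeLevelMatrix, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = outdir / "probe_intensities.tsv"
    sheet = outdir / "sample_sheet.tsv"
    plm.intensities.to_csv(matrix, sep="\t")
    plm.samples.to_csv(sheet, sep="\t")
    return {"matrix": matrix, "samples": sheet}


def read_probe_level(outdir, name: str = "") -> ProbeLevelMatrix:
    outdir = Path(outdir)
    intensities = pd.read_csv(outdir / "probe_intensities.tsv", sep="\t", index_col=[0, 1])
    samples = pd.read_csv(outdir / "sample_sheet.tsv", sep="\t", index_col=0, dtype={"temperature": str})
    return ProbeLevelMatrix(intensities, samples, name=name or outdir.name)


def write_expression(expr: ExpressionMatrix, path) -> Path:
    path = Path(path)
    out = expr.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
    return path


def read_expression(path, samples: pd.DataFrame | None = None, name: str = "") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    if samples is None:
        samples = pd.DataFrame(index=pd.Index(values.columns, name="sample_id"))
    return ExpressionMatrix(values, samples, name=name)


def write_cohort(cohort: TumorCohort, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = outdir / "expression.tsv"
    surv = outdir / "survival.tsv"
    cohort.expression.rename_axis("gene_id").to_csv(expr, sep="\t")
    tab = cohort.survival.copy()
    tab["endpoint"] = cohort.endpoint
    tab["time_unit"] = cohort.time_unit
    tab.to_csv(surv, sep="\t")
    return {"expression": expr, "survival": surv}


def read_cohort(outdir, name: str = "") -> TumorCohort:
    outdir = Path(outdir)
    expression = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
    surv = pd.read_csv(outdir / "survival.tsv", sep="\t", index_col=0)
    endpoint = str(surv["endpoint"].iloc[0]) if "endpoint" in surv else "disease-free"
    unit = str(surv["time_unit"].iloc[0]) if "time_unit" in surv else "years"
    return TumorCohort(
        expression,
        surv[["time", "event"]],
        time_unit=unit,
        endpoint=endpoint,
        name=name or outdir.name,
    )


def write_gmt(gene_sets: dict[str, GeneSet] | list[GeneSet], path) -> Path:
    path = Path(path)
    sets = gene_sets.values() if isinstance(gene_sets, dict) else gene_sets
    with open(path, "w") as fh:
        for gs in sets:
            desc = ";".join(gs.provenance) or "na"
            fh.write("\t".join([gs.name, desc, *sorted(gs.members)]) + "\n")
    return path


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one named gene set per line (name, description, tab-separated IDs)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_gene_set_tsv(gene_sets: dict[str, GeneSet] | list[GeneSet], path) -> Path:
    """Direction/provenance sidecar for a GMT file."""
    path = Path(path)
    sets = gene_sets.values() if isinstance(gene_sets, dict) else gene_sets
    rows = []
    for gs in sets:
        for gene in sorted(gs.members):
            rows.append(
                {
                    "set_name": gs.name,
                    "gene_id": gene,
                    "direction": gs.members[gene],
                    "provenance": ";".join(gs.provenance),
                }
            )
    pd.DataFrame(rows, columns=["set_name", "gene_id", "direction", "provenance"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_differential(result: DifferentialResult, path) -> Path:
    path = Path(path)
    tab = result.table.copy()
    tab.index.name = "feature_id"
    tab.to_csv(path, sep="\t")
    return path


def write_annotation(annotation: ProbeAnnotation, table_path, ortholog_path=None) -> None:
    annotation.table.rename_axis("probeset_id").to_csv(table_path, sep="\t")
    if ortholog_path is not None:
        annotation.orthologs.to_csv(ortholog_path, sep="\t", index=False)


def read_annotation(table_path, ortholog_path=None) -> ProbeAnnotation:
    table = pd.read_csv(table_path, sep="\t", index_col=0, dtype=str)
    if ortholog_path is not None:
        orth = pd.read_csv(ortholog_path, sep="\t", dtype=str)
    else:
        orth = pd.DataFrame(columns=["source_id", "target_id"])
    return ProbeAnnotation(table, orth)


def write_json(payload: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
    return path
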