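"""Bundled reference fixtures and synthetic set-structure builders.

``load_aggressive_signature`` returns the published 42-gene v-Src aggressive
tumor signature shipped with the package. ``printed_structure_sets`` builds
synthetic gene lists whose marginals and intersections replicate the canonical
discovery-set structure of the originally published analysis: 953 transformation-regulated (TR)
genes (418 up / 535 down), 477 unique genes in the temperature-sensitive CEF
system (261/216), 947 unique genes over 1062 probe sets in the CNR system
(444/503), an 84-gene three-way common set, a 91-gene ts-only set (hence a
175-gene CSR set) and a 145-gene TR∩CEF overlap (61 up / 84 down). Gene IDs
are synthetic; only the set structure is real.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DifferentialResult, GeneSet, ProbeAnnotation
from .io import read_gmt

__all__ = [
    "load_aggressive_signature",
    "load_primer_table",
    "printed_structure_sets",
    "cnr_probeset_result",
    "load_concordance_table",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("srcprog").joinpath("data", name))


def load_aggressive_signature() -> list[str]:
    """The bundled 42-gene aggressive tumor signature (unique gene symbols)."""
    sets = read_gmt(_data_path("aggressive_signature.gmt"))
    return sets["aggressive_tumor_signature"]


def load_primer_table() -> pd.DataFrame:
    """Primer pairs of the northern-blot validation panel."""
    return pd.read_csv(_data_path("northern_probe_primers.tsv"), sep="\t")


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def printed_structure_sets() -> dict[str, GeneSet]:
    """Synthetic TR / CEF_ts / CNR_ts gene lists with the canonical structure.

    Direction splits inside the 84-gene common set are not printed anywhere;
    40 up / 44 down is chosen so the CSR up-regulated total is 80.
    """
    com_up, com_down = _ids("COMU", 40), _ids("COMD", 44)  # common to all three
    ts_up, ts_down = _ids("TSU", 40), _ids("TSD", 51)  # CEF_ts ∩ CNR_ts only
    tc_up, tc_down = _ids("TCU", 21), _ids("TCD", 40)  # TR ∩ CEF_ts beyond common
    tr_up, tr_down = _ids("TRU", 357), _ids("TRD", 451)  # TR only
    cef_up, cef_down = _ids("CEFU", 160), _ids("CEFD", 81)  # CEF_ts only
    cnr_up, cnr_down = _ids("CNRU", 364), _ids("CNRD", 408)  # CNR_ts only

    def mk(name, up, down):
        members = {g: "up" for g in up}
        members.update({g: "down" for g in down})
        return GeneSet(name, members, provenance=["printed-structure fixture"])

    tr = mk("TR", com_up + tc_up + tr_up, com_down + tc_down + tr_down)
    cef = mk("CEF_ts", com_up + tc_up + ts_up + cef_up, com_down + tc_down + ts_down + cef_down)
    cnr = mk("CNR_ts", com_up + ts_up + cnr_up, com_down + ts_down + cnr_down)
    return {"TR": tr, "CEF_ts": cef, "CNR_ts": cnr}


def cnr_probeset_result() -> tuple[DifferentialResult, ProbeAnnotation]:
    """Probe-set-level CNR call list: 1062 probe sets collapsing to 947 genes.

    115 genes carry a redundant second probe set, exercising the lowest-p
    collapse rule. p-values are deterministic placeholders.
    """
    cnr = printed_structure_sets()["CNR_ts"]
    genes = sorted(cnr.members)
    assert len(genes) == 947
    redundant = genes[:115]
    rows = []
    rng = np.random.default_rng(947)
    for g in genes:
        rows.append((f"{g}_at", g))
    for g in redundant:
        rows.append((f"{g}_x_at", g))
    probesets = [ps for ps, _ in rows]
    gene_of = {ps: g for ps, g in rows}
    p = rng.uniform(1e-6, 0.05, size=len(rows))
    direction = [cnr.members[gene_of[ps]] for ps in probesets]
    table = pd.DataFrame(
        {
            "fold_change": 2.5,
            "log2_ratio": [np.log2(2.5) if d == "up" else -np.log2(2.5) for d in direction],
            "p_value": p,
            "direction": direction,
            "passes": True,
        },
        index=pd.Index(probesets, name="probeset_id"),
    )
    ann_table = pd.DataFrame(
        {"gene_id": [gene_of[ps] for ps in probesets], "gene_symbol": [gene_of[ps] for ps in probesets]},
        index=pd.Index(probesets, name="probeset_id"),
    )
    return DifferentialResult(table, "ttest", comparison="CNR ts fixture"), ProbeAnnotation(ann_table)


def load_concordance_table(path=None) -> pd.DataFrame:
    """Paired northern/microarray log2-ratio validation table.

    The numeric table is part of the originally published supplementary
    material and is not bundled here; pass a local TSV with ``northern_log2_ratio``
    and ``array_log2_ratio`` columns, or drop it at
    ``src/srcprog/data/northern_vs_array_log2_ratios.tsv``.
    """
    path = Path(path) if path else _data_path("northern_vs_array_log2_ratios.tsv")
    if not path.exists():
        raise FileNotFoundError(
            f"paired northern/microarray log-ratio table not found at {path}; "
            "supply the supplementary validation table as TSV"
        )
    tab = pd.read_csv(path, sep="\t")
    return tab[["northern_log2_ratio", "array_log2_ratio"]]
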