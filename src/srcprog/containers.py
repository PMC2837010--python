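"""In-memory containers shared across the pipeline.

All expression containers are thin dataclasses around pandas objects so that
every stage can be inspected, written to TSV, and re-loaded without loss.
Conventions: probe-level and expression matrices are on the linear scale,
tumor cohorts on the log2 scale; fold changes are linear and >= 1 with a
separate direction label.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class ProbeLevelMatrix:
    """Perfect-match probe intensities for one experimental group.

    ``intensities`` is indexed by a (probeset_id, probe_index) MultiIndex with
    one column per array; ``samples`` is indexed by array_id and carries
    ``condition``, ``temperature`` and ``replicate`` columns.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.intensities.index, pd.MultiIndex):
            raise ValueError("intensities must have a (probeset_id, probe_index) MultiIndex")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("probe intensities must be nonnegative")
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"sample metadata missing for arrays: {sorted(missing)}")

    @property
    def array_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.intensities.index.get_level_values(0).unique())

    def arrays_for(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])

    def copy(self) -> "ProbeLevelMatrix":
        return ProbeLevelMatrix(self.intensities.copy(), self.samples.copy(), self.name)


@dataclass
class ExpressionMatrix:
    """Feature x sample expression on the linear scale (values > 0)."""

    values: pd.DataFrame
    samples: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def samples_for(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])


@dataclass
class ProbeAnnotation:
    """Probe-set -> gene annotation plus an optional cross-platform ortholog map."""

    table: pd.DataFrame  # index probeset_id; columns gene_id, gene_symbol
    orthologs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["source_id", "target_id"])
    )

    def gene_of(self, probeset_id: str) -> str:
        return str(self.table.loc[probeset_id, "gene_id"])

    def targets_of(self, source_id: str) -> list[str]:
        sub = self.orthologs[self.orthologs["source_id"] == source_id]
        return list(dict.fromkeys(sub["target_id"].astype(str)))

    @classmethod
    def identity(cls, gene_ids: Iterable[str]) -> "ProbeAnnotation":
        """1:1 annotation/ortholog map for synthetic gene-level data."""
        ids = list(gene_ids)
        table = pd.DataFrame({"gene_id": ids, "gene_symbol": ids}, index=pd.Index(ids, name="probeset_id"))
        orth = pd.DataFrame({"source_id": ids, "target_id": ids})
        return cls(table, orth)


@dataclass
class DifferentialResult:
    """Per-feature call for one comparison regime.

    ``table`` columns: fold_change (linear, >= 1), log2_ratio (signed, test vs
    reference), p_value, direction (up/down/none), passes (bool).
    """

    table: pd.DataFrame
    test_kind: str  # "anova" | "ttest"
    comparison: str = ""

    REQUIRED = ("fold_change", "log2_ratio", "p_value", "direction", "passes")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"DifferentialResult table missing column {col!r}")
        p = self.table["p_value"].to_numpy(float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def passing_ids(self) -> list[str]:
        return list(self.table.index[self.table["passes"]])

    def to_gene_set(self, name: str, provenance: str = "") -> "GeneSet":
        sub = self.table[self.table["passes"]]
        return GeneSet(
            name=name,
            members=dict(zip(sub.index.astype(str), sub["direction"])),
            provenance=[provenance or self.comparison],
        )


@dataclass
class GeneSet:
    """Named set of gene IDs, each with an up/down direction label."""

    name: str
    members: dict[str, str]  # gene id -> "up" | "down"
    provenance: list[str] = field(default_factory=list)
    evidence: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = {d for d in self.members.values()} - {"up", "down"}
        if bad:
            raise ValueError(f"invalid directions in gene set {self.name!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    @property
    def ids(self) -> set[str]:
        return set(self.members)

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.members.values() if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.members.values() if d == "down")

    def subset(self, ids: Iterable[str], name: str | None = None) -> "GeneSet":
        keep = set(ids)
        return GeneSet(
            name=name or self.name,
            members={g: d for g, d in self.members.items() if g in keep},
            provenance=list(self.provenance),
        )

    def direction_subset(self, direction: str) -> "GeneSet":
        return GeneSet(
            name=f"{self.name}_{direction}",
            members={g: d for g, d in self.members.items() if d == direction},
            provenance=list(self.provenance),
        )


@dataclass
class TumorCohort:
    """Gene x tumor log2 expression with right-censored survival annotation."""

    expression: pd.DataFrame  # gene rows x tumor columns, log2 scale
    survival: pd.DataFrame  # index tumor_id; columns time, event
    time_unit: str = "years"
    endpoint: str = "disease-free"
    name: str = ""

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.survival.index):
            self.survival = self.survival.loc[self.expression.columns]
        t = self.survival["time"].to_numpy(float)
        e = self.survival["event"].to_numpy()
        if (t <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(np.unique(e)) <= {0, 1}:
            raise ValueError("event indicators must be 0/1")

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_tumors(self) -> int:
        return self.expression.shape[1]


@dataclass
class GroundTruth:
    """Planted truth of a synthetic experiment, sufficient to score recovery."""

    planted_up: dict[str, float] = field(default_factory=dict)  # gene -> linear FC
    planted_down: dict[str, float] = field(default_factory=dict)
    temperature_genes: dict[str, float] = field(default_factory=dict)
    probeset_to_gene: dict[str, str] = field(default_factory=dict)
    aggressive_tumors: list[str] = field(default_factory=list)
    true_hazard_ratio: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit curve over distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    max_time: float  # largest observed (event or censoring) time
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "at_risk": self.at_risk, "events": self.events, "survival": self.survival}
        )


@dataclass
class ScoreVector:
    """Per-tumor signature score (log2, gene-wise mean-centered average)."""

    scores: pd.Series
    labels: pd.Series | None = None  # "aggressive-high" | "rest"


@dataclass
class SignatureResult:
    """Aggressive signature derived as the intersection of two candidate lists."""

    genes: list[str]
    candidates_a: GeneSet
    candidates_b: GeneSet
    concordance: float

    def __post_init__(self) -> None:
        sig = set(self.genes)
        if not (sig <= self.candidates_a.ids and sig <= self.candidates_b.ids):
            raise ValueError("signature must be a subset of both candidate lists")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must lie in [0, 1]")
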