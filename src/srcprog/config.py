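"""Configuration objects for simulation and the analysis pipeline.

Defaults follow the study design the package emulates: a minimum of three
biological replicates per condition, a two-fold change rule on log2 expression,
pairwise alpha 0.05, ANOVA alpha 0.01, permutation-based FDR (10,000
permutations at full scale, 200 as the desk-scale default), four tumor
clusters, and an upper-quartile (25%) signature split.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .containers import ConfigurationError

#: (condition label, temperature label) pairs; the last condition is the
#: transforming one by default.
DEFAULT_CONDITIONS: tuple[tuple[str, str], ...] = (
    ("RCASBP-A", "41.5"),
    ("NY315", "41.5"),
    ("SR-A", "41.5"),
)


@dataclass
class SimulationConfig:
    """Probe-level microarray simulation parameters.

    noise_sd is the sd of additive Gaussian noise on the log2 intensity scale;
    fold_change_range is on the linear scale with lower bound > 1;
    redundancy_fraction is the fraction of genes carried by two probe sets.
    """

    n_probesets: int = 2000
    probes_per_set: int = 11
    conditions: tuple[tuple[str, str], ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 3
    n_planted_up: int = 100
    n_planted_down: int = 100
    fold_change_range: tuple[float, float] = (2.0, 8.0)
    n_temperature_genes: int = 20
    temperature_fold_range: tuple[float, float] = (1.5, 3.0)
    noise_sd: float = 0.25
    redundancy_fraction: float = 0.1
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    affinity_log2_sd: float = 0.7
    test_condition: str | None = None  # default: last condition
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probesets <= 0 or self.probes_per_set <= 0:
            raise ConfigurationError("counts must be positive")
        if len(self.conditions) < 2:
            raise ConfigurationError("need at least two conditions")
        if self.replicates_per_condition < 3:
            raise ConfigurationError("a minimum of three biological replicates per condition is required")
        if min(self.n_planted_up, self.n_planted_down, self.n_temperature_genes) < 0:
            raise ConfigurationError("planted counts must be nonnegative")
        if self.n_planted_up + self.n_planted_down > self.n_probesets:
            raise ConfigurationError("planted counts exceed the number of probe sets")
        if self.fold_change_range[0] <= 1:
            raise ConfigurationError("fold_change_range lower bound must exceed 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not 0 <= self.redundancy_fraction <= 1:
            raise ConfigurationError("redundancy_fraction must lie in [0, 1]")
        labels = [c for c, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("condition labels must be unique")
        if self.test_condition is not None and self.test_condition not in labels:
            raise ConfigurationError(f"unknown test_condition {self.test_condition!r}")

    @property
    def resolved_test_condition(self) -> str:
        return self.test_condition or self.conditions[-1][0]

    @property
    def n_genes(self) -> int:
        return int(round(self.n_probesets / (1.0 + self.redundancy_fraction)))


@dataclass
class CohortConfig:
    """Synthetic tumor cohort: expression plus proportional-hazards survival.

    Survival times are exponential with hazard baseline_hazard *
    hazard_ratio**is_aggressive; censoring is independent exponential with the
    rate solved numerically to hit censoring_rate.
    """

    n_tumors: int = 200
    n_background_genes: int = 970
    n_signature_genes: int = 30
    aggressive_fraction: float = 0.25
    expression_shift: float = 2.0  # log2 units added to signature genes in aggressive tumors
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.1  # events per time unit
    censoring_rate: float = 0.3
    noise_sd: float = 1.0  # log2 within-gene sd around the gene baseline
    time_unit: str = "years"
    endpoint: str = "disease-free"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 4:
            raise ConfigurationError("need at least four tumors")
        if self.n_signature_genes < 0 or self.n_background_genes < 0:
            raise ConfigurationError("gene counts must be nonnegative")
        if self.n_signature_genes > self.n_signature_genes + self.n_background_genes:
            raise ConfigurationError("n_signature_genes exceeds total genes")
        if not 0 < self.aggressive_fraction < 1:
            raise ConfigurationError("aggressive_fraction must lie in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ConfigurationError("hazard_ratio must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must lie in [0, 1)")


@dataclass
class PipelineConfig:
    """Thresholds of the discovery/signature/evaluation pipeline."""

    fc_threshold: float = 2.0  # linear
    alpha_pairwise: float = 0.05
    alpha_anova: float = 0.01
    n_permutations: int = 200  # desk default; full-scale profile uses 10,000
    alpha_signature: float = 0.05  # one-tailed
    n_clusters: int = 4
    quartile: float = 0.25
    welch: bool = False
    rank_threshold: float = 0.005
    invariant_max_iter: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ConfigurationError("fc_threshold must be >= 1")
        for a in (self.alpha_pairwise, self.alpha_anova, self.alpha_signature):
            if not 0 < a < 1:
                raise ConfigurationError("alpha thresholds must lie in (0, 1)")
        if self.n_permutations < 20:
            raise ConfigurationError("n_permutations must be >= 20")
        if self.n_clusters < 2:
            raise ConfigurationError("n_clusters must be >= 2")
        if not 0 < self.quartile < 1:
            raise ConfigurationError("quartile must lie in (0, 1)")

    @classmethod
    def full_profile(cls, **overrides) -> "PipelineConfig":
        """Full-scale profile: 10,000 label permutations for the FDR estimate."""
        overrides.setdefault("n_permutations", 10_000)
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
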