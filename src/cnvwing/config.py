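"""Configuration objects and the controlled vocabularies shared by all stages.

The screen scores five qualitative wing phenotypes per wing on an ordinal
1 (no phenotype) to 5 (lethal) scale; lethality is a line-level terminal
category rather than a per-wing observation.  All stage parameters that the
analysis fixes up front (significance level, cluster count, expression bin
edges, network edge threshold) live in :class:`AnalysisConfig` so that a run
is fully described by one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

#: The five qualitative wing phenotypes scored per wing.
PHENOTYPES: tuple[str, ...] = (
    "wrinkled",
    "discoloration",
    "ectopic_vein",
    "missing_vein",
    "bristle_polarity",
)

#: Ordinal severity levels per phenotype; 5 marks the lethal terminal category.
SEVERITY_LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Severity classes in increasing order, as used for line-level clustering.
SEVERITY_CLASSES: tuple[str, ...] = (
    "no_phenotype",
    "mild",
    "moderate",
    "severe",
    "lethal",
)

#: Wing measurements: total area plus six vein lengths.
MEASURES: tuple[str, ...] = ("area", "L2", "L3", "L4", "L5", "ACV", "PCV")

#: RNAi libraries and their matched controls.
LIBRARIES: tuple[str, ...] = ("GD", "KK")

#: Cellular markers counted in larval wing discs.
MARKERS: tuple[str, ...] = ("pH3", "dcp1")

#: Expression bin edges (left-closed, right-open) per species/unit.
EXPRESSION_BIN_EDGES: dict[str, tuple[float, ...]] = {
    "fly": (10.0, 100.0, 500.0, 1000.0),    # FPKM
    "human": (3.0, 10.0, 25.0, 100.0),      # TPM
}

EXPRESSION_CATEGORIES: tuple[str, ...] = (
    "none", "low", "moderate", "high", "very_high",
)

#: Eye fold-change severity boundaries (closed on the right).
EYE_FC_EDGES: tuple[float, ...] = (1.1, 1.5, 2.0)
EYE_CATEGORIES: tuple[str, ...] = ("no_change", "mild", "moderate", "severe")


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its invariants."""


def _default_severity_profiles() -> dict[str, dict[str, list[float]]]:
    """Per-class, per-phenotype multinomials over the five severity levels.

    The classes are well separated: a line's wings concentrate around the
    severity its class names.  "severe" places most mass on level 4, which
    also triggers the wrinkled-wing override downstream.  "lethal" lines
    produce no wings at all, so their profile is never sampled.
    """
    base = {
        "no_phenotype": [0.90, 0.10, 0.00, 0.00, 0.0],
        "mild":         [0.35, 0.55, 0.10, 0.00, 0.0],
        "moderate":     [0.10, 0.30, 0.55, 0.05, 0.0],
        "severe":       [0.05, 0.10, 0.15, 0.70, 0.0],
        "lethal":       [0.00, 0.00, 0.00, 0.00, 1.0],
    }
    return {cls: {ph: list(base[cls]) for ph in PHENOTYPES} for cls in base}


def _default_class_sizes() -> dict[str, int]:
    # Screen-scale composition: 136 lines split across the five classes.
    return {"no_phenotype": 75, "mild": 24, "moderate": 10, "severe": 21, "lethal": 6}


@dataclass
class NetworkParams:
    """Shape of the synthetic tissue network with planted shortest paths."""

    n_nodes: int = 120
    edge_prob: float = 0.03
    beta_a: float = 1.2           # Beta parameters for background posteriors
    beta_b: float = 4.0
    planted_posterior: float = 0.95
    n_planted_paths: int = 3
    n_connectors_per_path: int = 2

    def validate(self) -> None:
        if self.n_nodes <= 0:
            raise ConfigurationError("n_nodes must be positive")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ConfigurationError("edge_prob must be in [0, 1]")
        if not 0.0 < self.planted_posterior <= 1.0:
            raise ConfigurationError("planted_posterior must be in (0, 1]")
        need = self.n_planted_paths * (2 + self.n_connectors_per_path)
        if need > self.n_nodes:
            raise ConfigurationError(
                f"planted paths need {need} distinct nodes but only "
                f"{self.n_nodes} are available"
            )


@dataclass
class GoParams:
    """Annotation-table shape: one planted enriched term among background terms."""

    n_terms: int = 12
    background_rate: float = 0.10
    planted_rate: float = 0.80

    def validate(self) -> None:
        for name in ("background_rate", "planted_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.n_terms < 1:
            raise ConfigurationError("n_terms must be >= 1")


@dataclass
class SimulationConfig:
    """Ground-truth description of one synthetic screen.

    ``seed`` fully determines every generated table; each generator derives
    its own independent stream from (seed, generator name) so adding one
    generator never perturbs another's draws.
    """

    seed: int = 0
    n_wings_per_line: int = 22          # within the screen's 20-25 wings/line
    class_sizes: dict[str, int] = field(default_factory=_default_class_sizes)
    severity_profiles: dict[str, dict[str, list[float]]] = field(
        default_factory=_default_severity_profiles
    )
    # morphometry: line -> multiplicative effect on area and vein lengths
    measurement_effects: dict[str, float] = field(default_factory=dict)
    n_wings_measured: int = 30          # per group, within the 9-91 range
    # eye scores: line -> true fold change relative to control median
    eye_fc_effects: dict[str, float] = field(default_factory=dict)
    eye_n_range: tuple[int, int] = (7, 40)
    eye_sigma: float = 0.25             # lognormal shape of per-fly scores
    eye_control_median: float = 30.0
    # cell counts: line -> Poisson rate ratio vs control
    cell_rate_ratios: dict[str, float] = field(default_factory=dict)
    cell_n_range: tuple[int, int] = (6, 18)
    cell_control_rate: float = 30.0
    # expression matrix
    n_genes: int = 77
    n_tissues: int = 8
    preferential_fraction: float = 0.2
    expression_unit: str = "FPKM"
    expression_species: str = "fly"
    network_params: NetworkParams = field(default_factory=NetworkParams)
    go_params: GoParams = field(default_factory=GoParams)

    @property
    def n_lines(self) -> int:
        return int(sum(self.class_sizes.values()))

    def validate(self) -> None:
        if self.n_wings_per_line <= 0:
            raise ConfigurationError("n_wings_per_line must be positive")
        for cls, n in self.class_sizes.items():
            if cls not in SEVERITY_CLASSES:
                raise ConfigurationError(f"unknown severity class {cls!r}")
            if n < 0:
                raise ConfigurationError(f"class size for {cls!r} must be >= 0")
        for cls, per_ph in self.severity_profiles.items():
            for ph, probs in per_ph.items():
                p = np.asarray(probs, dtype=float)
                if p.size != len(SEVERITY_LEVELS):
                    raise ConfigurationError(
                        f"profile for ({cls}, {ph}) must have 5 entries"
                    )
                if (p < 0).any():
                    raise ConfigurationError(
                        f"profile for ({cls}, {ph}) has negative mass"
                    )
                if not np.isclose(p.sum(), 1.0, atol=1e-9):
                    raise ConfigurationError(
                        f"profile for ({cls}, {ph}) sums to {p.sum()!r}, not 1"
                    )
        if not 0.0 <= self.preferential_fraction <= 1.0:
            raise ConfigurationError("preferential_fraction must be in [0, 1]")
        for line, eff in self.measurement_effects.items():
            if eff <= 0:
                raise ConfigurationError(f"measurement effect for {line!r} must be > 0")
        for line, r in self.cell_rate_ratios.items():
            if r <= 0:
                raise ConfigurationError(f"cell rate ratio for {line!r} must be > 0")
        if self.eye_control_median <= 0 or self.cell_control_rate <= 0:
            raise ConfigurationError("control baselines must be positive")
        if self.expression_species not in EXPRESSION_BIN_EDGES:
            raise ConfigurationError(
                f"unknown species {self.expression_species!r}"
            )
        self.network_params.validate()
        self.go_params.validate()

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnalysisConfig:
    """Fixed analysis constants for one pipeline run."""

    alpha: float = 0.05
    k_clusters: int = 5
    kmeans_restarts: int = 100
    kmeans_seed: int = 0
    network_threshold: float = 0.2
    connectors: str = "canonical"   # or "union" over all tied shortest paths
    presence_min_severity: int = 2  # line-level presence for sex contrasts

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.k_clusters < 2:
            raise ConfigurationError("k_clusters must be >= 2")
        if not 0.0 <= self.network_threshold < 1.0:
            raise ConfigurationError("network_threshold must be in [0, 1)")
        if self.connectors not in ("canonical", "union"):
            raise ConfigurationError("connectors must be 'canonical' or 'union'")
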