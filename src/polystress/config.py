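"""Configuration objects shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its documented constraints."""


# Layer keys for planted-effect proportions.
TRANSLATION_LABELS = ("translation_up", "translation_down")
MRNA_LABELS = ("mrna_up", "mrna_down")
PROTEIN_LABELS = (
    "protein_linear_up",
    "protein_linear_down",
    "protein_convex",
    "protein_concave",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic three-layer stress-response dataset.

    The defaults encode the study design the generator emulates: an
    unstressed control plus 15- and 60-minute stress samples with
    biological repeats for the four-pool polysome layer, a 7-time-point
    stress grid for the mRNA expression layer, and a 6-time-point,
    duplicated (12-sample) spectrum-count proteome time course.
    """

    n_genes: int = 2000
    n_replicates_control: int = 3
    n_replicates_stress: int = 3
    stress_timepoints_min: tuple[int, ...] = (15, 60)
    mrna_timepoints_min: tuple[int, ...] = (15, 30, 45, 60, 90, 120, 180)
    proteome_timepoints_min: tuple[int, ...] = (0, 15, 30, 60, 120, 180)
    fraction_count: int = 4
    planted_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "translation_up": 0.1,
            "translation_down": 0.1,
            "mrna_up": 0.1,
            "mrna_down": 0.1,
            "protein_linear_up": 0.025,
            "protein_linear_down": 0.025,
            "protein_convex": 0.025,
            "protein_concave": 0.025,
        }
    )
    effect_size_shift: float = 30.0  # percentage points moved between pooled fractions
    mrna_log2_effect: float = 1.0
    mrna_effect_spread: float = 0.0  # relative per-gene effect-size heterogeneity
    mrna_peak_time_min: int = 60
    protein_log2_effect: float = 1.0
    count_depth: float = 200.0
    noise_sd_log: float = 0.1
    sample_scale_sd_log: float = 0.0  # per-sample proteome gain variation
    dropout_fraction: float = 0.0
    concordant: bool = True
    protein_half_life_min: float = 300.0
    protein_half_life_repressed_min: float = 1200.0
    condition: str = "stress"
    seed: int = 0

    def __post_init__(self) -> None:
        self.stress_timepoints_min = tuple(self.stress_timepoints_min)
        self.mrna_timepoints_min = tuple(self.mrna_timepoints_min)
        self.proteome_timepoints_min = tuple(self.proteome_timepoints_min)
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.fraction_count != 4:
            raise ConfigurationError("fraction_count is fixed at 4")
        if not 0 < self.effect_size_shift < 100:
            raise ConfigurationError("effect_size_shift must lie in (0, 100)")
        if self.count_depth <= 0:
            raise ConfigurationError("count_depth must be > 0")
        if not 0 <= self.dropout_fraction < 1:
            raise ConfigurationError("dropout_fraction must lie in [0, 1)")
        for key, value in self.planted_fractions.items():
            if not 0 <= value <= 1:
                raise ConfigurationError(f"planted fraction {key!r} outside [0, 1]")
        for layer in (TRANSLATION_LABELS, MRNA_LABELS, PROTEIN_LABELS):
            total = sum(self.planted_fractions.get(k, 0.0) for k in layer)
            if total > 1 + 1e-12:
                raise ConfigurationError(
                    f"planted fractions for layer {layer} sum to {total} > 1"
                )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


@dataclass
class CallingThresholds:
    """Cutoffs for calling translational regulation.

    ``D_cutoff`` applies to the replicate-averaged sum of absolute
    profile differences; ``R_cutoff`` to the replicate-averaged
    translation ratio, symmetrically (up if R >= R_cutoff, down if
    R <= 1/R_cutoff by default, or R <= 2 - R_cutoff when
    ``reciprocal_down`` is False).
    """

    D_cutoff: float = 30.0
    R_cutoff: float = 1.15
    min_fraction_delta: float = 0.0
    reciprocal_down: bool = True

    def __post_init__(self) -> None:
        if self.D_cutoff <= 0:
            raise ConfigurationError("D_cutoff must be > 0")
        if self.R_cutoff <= 1:
            raise ConfigurationError("R_cutoff must be > 1")
        if self.min_fraction_delta < 0:
            raise ConfigurationError("min_fraction_delta must be >= 0")

    @property
    def R_cutoff_down(self) -> float:
        return 1.0 / self.R_cutoff if self.reciprocal_down else 2.0 - self.R_cutoff


@dataclass
class RunConfig:
    """End-to-end pipeline settings."""

    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    alpha: float = 0.05
    pseudocount: float = 0.5
    fold_cutoff: float = 1.5
    min_timepoints: int = 4
    strict: bool = False
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.pseudocount < 0:
            raise ConfigurationError("pseudocount must be >= 0")
        if self.fold_cutoff <= 1:
            raise ConfigurationError("fold_cutoff must be > 1")
        if self.min_timepoints < 1:
            raise ConfigurationError("min_timepoints must be >= 1")

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        thr = data.pop("thresholds", None)
        cfg = cls(**data)
        if thr is not None:
            cfg.thresholds = CallingThresholds(**thr)
        return cfg
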