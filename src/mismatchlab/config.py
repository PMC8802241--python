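"""Trait registry and analysis configuration.

The trait registry describes each measured trait: whether it is a linear
measurement (mm, ln-transformed and size-corrected) or a meristic count
(standardized only), whether fixation posture affects it, and whether an
absent structure is recorded as 0 and substituted with 0.1 mm before
log-transformation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

GENERATIONS = ("PM", "PF", "F1", "F2")
HYBRID_GENERATIONS = ("F1", "F2")

#: metadata columns every wide-format trait table carries
META_COLUMNS = [
    "individual_id",
    "population",
    "cross_id",
    "generation",
    "family_id",
]


@dataclass(frozen=True)
class TraitSpec:
    """Per-trait attributes driving preprocessing."""

    kind: str  # "linear" | "count"
    size_correct: bool = True
    fixation_affected: bool = False
    absence_substitution_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "count"):
            raise ValueError(f"trait kind must be 'linear' or 'count', got {self.kind!r}")
        if self.kind == "count" and self.size_correct:
            object.__setattr__(self, "size_correct", False)


@dataclass
class TraitConfig:
    """Registry of traits plus analysis-wide settings.

    Parameters
    ----------
    traits
        Mapping trait name -> :class:`TraitSpec`.
    alpha
        Significance level for per-trait tests (parent difference, dominance
        deviation, pairwise mismatch screening).
    coincident_tolerance
        Euclidean tolerance below which two parental mean vectors are treated
        as coincident (the parent line is then undefined and mismatch falls
        back to distance-to-point).
    """

    traits: dict[str, TraitSpec] = field(default_factory=dict)
    alpha: float = 0.05
    coincident_tolerance: float = 1e-10

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    @property
    def linear_traits(self) -> list[str]:
        return [t for t, s in self.traits.items() if s.kind == "linear"]

    @property
    def count_traits(self) -> list[str]:
        return [t for t, s in self.traits.items() if s.kind == "count"]

    @property
    def fixation_traits(self) -> list[str]:
        return [t for t, s in self.traits.items() if s.fixation_affected]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "coincident_tolerance": self.coincident_tolerance,
            "traits": {t: asdict(s) for t, s in self.traits.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitConfig":
        payload = yaml.safe_load(Path(path).read_text())
        traits = {t: TraitSpec(**spec) for t, spec in payload.get("traits", {}).items()}
        return cls(
            traits=traits,
            alpha=float(payload.get("alpha", 0.05)),
            coincident_tolerance=float(payload.get("coincident_tolerance", 1e-10)),
        )


def default_trait_config() -> TraitConfig:
    """The 15-trait registry used throughout: 11 linear measurements and
    4 meristic counts (eye diameter is excluded from analysis by default
    because of poor measurement repeatability).

    Spines and the pelvic girdle can be absent (recorded 0, substituted with
    0.1 mm); gape width, snout length and head length are affected by the
    openness of the mouth at fixation.
    """
    linear = {
        "body_depth": TraitSpec("linear"),
        "body_width": TraitSpec("linear"),
        "head_length": TraitSpec("linear", fixation_affected=True),
        "snout_length": TraitSpec("linear", fixation_affected=True),
        "gape_width": TraitSpec("linear", fixation_affected=True),
        "pectoral_fin_length": TraitSpec("linear"),
        "gill_raker_length": TraitSpec("linear"),
        "first_dorsal_spine": TraitSpec("linear", absence_substitution_mm=0.1),
        "second_dorsal_spine": TraitSpec("linear"),
        "pelvic_spine": TraitSpec("linear", absence_substitution_mm=0.1),
        "pelvic_girdle_length": TraitSpec("linear", absence_substitution_mm=0.1),
    }
    counts = {
        "dorsal_fin_rays": TraitSpec("count"),
        "anal_fin_rays": TraitSpec("count"),
        "gill_raker_number": TraitSpec("count"),
        "lateral_plate_number": TraitSpec("count"),
    }
    return TraitConfig(traits={**linear, **counts})
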