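"""Psychometric rubric engines for trail classification.

The rubrics quantify Ecosystem Health Potentials (EHP: geodiversity,
biodiversity, aquatic diversity, climate exposure) and Opportunities
(EHO: infrastructure, wellness experience) plus the three trail-condition
scales of the NBR 15505-2 / MIDE family: severity of the environment,
course orientation and surface/ground conditions.

Every total is the plain sum or count of its components; a prevalence is
``100 · total / reference``. Full precision is kept internally — rounding
happens only at rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from trailmetrics.errors import ValidationError

__all__ = [
    "SEVERITY_ITEMS",
    "SEVERITY_BLOCKS",
    "SeverityChecklist",
    "ScoreResult",
    "AquaticIndicators",
    "ClimateGrid",
    "score_severity",
    "classify_orientation",
    "classify_surface",
    "score_aquatic",
    "score_climate",
    "score_wellness",
    "geodiversity_prevalence",
    "shannon_index",
    "ORIENTATION_LABELS",
    "SURFACE_LABELS",
    "DEFAULT_SURFACE_SPEEDS",
]

SEVERITY_ITEMS = tuple("abcdefghijklmnopqrstuvwxyz")

#: The 26 hazard items grouped into rubric blocks.
SEVERITY_BLOCKS: Mapping[str, tuple[str, ...]] = {
    "ehp_geo_bio": tuple("abcdefghi"),
    "ehp_aquatic": tuple("jklm"),
    "ehp_climate": tuple("nopqrstuv"),
    "eho_infrastructure": tuple("wxyz"),
}

_SEVERITY_BANDS = (
    (3, "slightly_severe"),
    (5, "moderately_severe"),
    (8, "severe"),
    (12, "quite_severe"),
    (math.inf, "very_severe"),
)


@dataclass(frozen=True)
class SeverityChecklist:
    """26 boolean hazard items keyed ``a``..``z``."""

    items: Mapping[str, bool]

    def __post_init__(self) -> None:
        unknown = set(self.items) - set(SEVERITY_ITEMS)
        if unknown:
            raise ValidationError(f"unknown severity item ids: {sorted(unknown)}")
        missing = set(SEVERITY_ITEMS) - set(self.items)
        if missing:
            raise ValidationError(f"missing severity item ids: {sorted(missing)}")

    @classmethod
    def from_checked(cls, checked: Sequence[str]) -> "SeverityChecklist":
        checked_set = set(checked)
        unknown = checked_set - set(SEVERITY_ITEMS)
        if unknown:
            raise ValidationError(f"unknown severity item ids: {sorted(unknown)}")
        return cls({item: item in checked_set for item in SEVERITY_ITEMS})


@dataclass(frozen=True)
class ScoreResult:
    """A rubric total against its reference maximum."""

    total: float
    reference: float
    class_label: str | None = None
    subtotals: tuple[float, ...] | None = None

    @property
    def prevalence_pct(self) -> float:
        return 100.0 * self.total / self.reference

    def render_prevalence(self, decimals: int = 1) -> str:
        return f"{self.prevalence_pct:.{decimals}f}%"


def score_severity(checklist: SeverityChecklist) -> ScoreResult:
    """Count checked hazard items and band the count into five classes.

    Bands: up to 3 slightly severe, 4–5 moderately severe, 6–8 severe,
    9–12 quite severe, 13+ very severe.
    """
    total = sum(bool(v) for v in checklist.items.values())
    for upper, label in _SEVERITY_BANDS:
        if total <= upper:
            return ScoreResult(total=total, reference=len(SEVERITY_ITEMS), class_label=label)
    raise AssertionError("unreachable")  # pragma: no cover


ORIENTATION_LABELS = {
    1: "well-defined paths and intersections",
    2: "path or signage that indicates continuity",
    3: "requires identification of landmarks and cardinal points",
    4: "requires off-track navigation skills",
    5: "requires navigation on alternative, previously unknown routes",
}

SURFACE_LABELS = {
    1: "traveling on flat surfaces",
    2: "pathfinding, no obstacles",
    3: "traveling over graded trails or uneven terrain",
    4: "obstacle course",
    5: "route that requires vertical techniques",
}

#: Suggested horizontal speed (km/h) per surface class. Level 5 routes are
#: vertical-technique terrain; the hard-surface walking speed is retained
#: as the suggestion. An explicitly supplied per-trail speed always wins.
DEFAULT_SURFACE_SPEEDS = {1: 5.0, 2: 4.0, 3: 3.0, 4: 2.0, 5: 2.0}


def classify_orientation(level: int) -> ScoreResult:
    """Validate a course-orientation level (1–5) and attach its label."""
    if level not in ORIENTATION_LABELS:
        raise ValidationError(f"orientation level must be in 1..5, got {level}")
    return ScoreResult(total=level, reference=5, class_label=ORIENTATION_LABELS[level])


def classify_surface(
    level: int, speed_map: Mapping[int, float] | None = None
) -> tuple[str, float]:
    """Surface/ground class label and the suggested horizontal speed Has."""
    if level not in SURFACE_LABELS:
        raise ValidationError(f"surface level must be in 1..5, got {level}")
    speeds = dict(DEFAULT_SURFACE_SPEEDS)
    if speed_map:
        speeds.update(speed_map)
    return SURFACE_LABELS[level], float(speeds[level])


@dataclass(frozen=True)
class AquaticIndicators:
    """Salutogenic aquatic-diversity components, each 0–3 (0 = absent)."""

    availability: int
    interaction: int
    bathing: int
    potability: int
    risk: int

    def __post_init__(self) -> None:
        for name in ("availability", "interaction", "bathing", "potability", "risk"):
            v = getattr(self, name)
            if not 0 <= v <= 3:
                raise ValidationError(f"aquatic component {name!r} must be in 0..3, got {v}")

    def components(self) -> tuple[int, ...]:
        return (self.availability, self.interaction, self.bathing, self.potability, self.risk)


def score_aquatic(ind: AquaticIndicators, reference: float = 15) -> ScoreResult:
    """Sum the five aquatic components against a reference of 15."""
    return ScoreResult(total=sum(ind.components()), reference=reference)


@dataclass(frozen=True)
class ClimateGrid:
    """6 exposure indicators × 4 seasonal cycles, each cell scored 1–3.

    Indicator rows: insolation, temperature, rainfall, humidity, winds,
    green tunnel. Cycles: I Dec–Apr, II May–Jul, III Aug–Sep, IV Oct–Nov.
    """

    scores: tuple[tuple[int, ...], ...]  # 6 rows × 4 cycles

    def __post_init__(self) -> None:
        grid = tuple(tuple(int(c) for c in row) for row in self.scores)
        object.__setattr__(self, "scores", grid)
        if len(grid) != 6 or any(len(row) != 4 for row in grid):
            raise ValidationError("climate grid must be 6 indicators x 4 cycles")
        for row in grid:
            for cell in row:
                if cell not in (1, 2, 3):
                    raise ValidationError(f"climate cell must be in {{1,2,3}}, got {cell}")


def score_climate(grid: ClimateGrid, reference: float = 72) -> ScoreResult:
    """Total exposure score with per-cycle column subtotals (reference 72)."""
    arr = np.asarray(grid.scores)
    cycles = tuple(int(c) for c in arr.sum(axis=0))
    return ScoreResult(total=int(arr.sum()), reference=reference, subtotals=cycles)


def score_wellness(
    counts: Mapping[str, int], reference: float = 60
) -> ScoreResult:
    """Sum wellness-experience item counts (visions, sounds, odors, interaction).

    The reference of 60 corresponds to the listed offers of adventure
    activities used as the national totality.
    """
    expected = {"visions", "sounds", "odors", "interaction"}
    unknown = set(counts) - expected
    if unknown:
        raise ValidationError(f"unknown wellness categories: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise ValidationError("wellness counts must be >= 0")
    return ScoreResult(total=sum(counts.values()), reference=reference)


def geodiversity_prevalence(
    components: Mapping[str, float], reference: float = 1600
) -> ScoreResult:
    """Sum the four geodiversity value components against a 1600 reference.

    Components: scientific, degradation_risk, educational, touristic.
    """
    expected = {"scientific", "degradation_risk", "educational", "touristic"}
    unknown = set(components) - expected
    if unknown:
        raise ValidationError(f"unknown geodiversity components: {sorted(unknown)}")
    if any(v < 0 for v in components.values()):
        raise ValidationError("geodiversity components must be >= 0")
    return ScoreResult(total=sum(components.values()), reference=reference)


def shannon_index(
    abundances: Sequence[float], reference_h: float = 5.5, base: float = math.e
) -> tuple[float, float]:
    """Shannon–Weaver diversity H = −Σ pᵢ·log pᵢ and its prevalence.

    Abundances (counts or proportions) are normalized to proportions;
    zero entries drop out of the sum. The prevalence compares H to a
    reference diversity (5.5, the tropical-forest convention used here).
    Natural log by default; ``base`` is configurable.
    """
    v = np.asarray(abundances, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("abundance vector must be a non-empty 1-D sequence")
    if np.any(v < 0):
        raise ValidationError("abundances must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValidationError("abundance vector must have at least one positive entry")
    p = v[v > 0] / total
    h = float(-(p * (np.log(p) / math.log(base))).sum())
    return h, 100.0 * h / reference_h
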