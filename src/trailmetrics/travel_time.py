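"""Travel-time model and effort-index classification for hiking trails.

The travel time of a trail stretch is modelled as the sum of a horizontal
term and a slope correction:

* horizontal: distance / Has, expressed in **minutes** (Has is the average
  horizontal speed chosen from the surface difficulty class);
* slope: distance / Us (uphill) or distance / Ds (downhill), expressed in
  **seconds** (Us and Ds are fixed correction "speeds"); a flat stretch
  adds nothing.

The mixed minutes/seconds convention is deliberate and hard-coded: it is
what the underlying trail-classification standard (an NBR 15505-2 / MIDE
style rubric) uses, and the published worked tables are only reproduced to
the second under exactly this convention.  Writing the formula in seconds,
a stretch of ``d`` km at horizontal speed ``Has`` with an uphill gradient
contributes ``d/Has·3600 + d/Us·60`` seconds.

All arithmetic is exact rational (``fractions.Fraction`` seconds); values
are rounded only when rendered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from trailmetrics.errors import ValidationError
from trailmetrics.trail_model import Direction, TrailProfile

__all__ = [
    "Duration",
    "TravelTimeParams",
    "EffortResult",
    "EFFORT_BANDS",
    "segment_time",
    "trail_time",
    "classify_effort",
]


@dataclass(frozen=True, order=True)
class Duration:
    """An exact non-negative time span stored in rational seconds."""

    seconds: Fraction

    def __post_init__(self) -> None:
        sec = Fraction(self.seconds)
        if sec < 0:
            raise ValidationError(f"duration must be non-negative, got {sec} s")
        object.__setattr__(self, "seconds", sec)

    @classmethod
    def from_hms(cls, hours: int = 0, minutes: int = 0, seconds: int | Fraction = 0) -> "Duration":
        return cls(Fraction(hours) * 3600 + Fraction(minutes) * 60 + Fraction(seconds))

    @classmethod
    def parse(cls, text: str) -> "Duration":
        """Parse the human rendering used in trail tables, e.g. ``1 h 35 min 30 s``."""
        pattern = r"^\s*(?:(\d+)\s*h)?\s*(?:(\d+)\s*min)?\s*(?:(\d+)\s*s)?\s*$"
        m = re.match(pattern, text)
        if m is None or not any(m.groups()):
            raise ValidationError(f"unparseable duration: {text!r}")
        h, mi, s = (int(g) if g else 0 for g in m.groups())
        return cls.from_hms(h, mi, s)

    # --- arithmetic -----------------------------------------------------
    def __add__(self, other: "Duration") -> "Duration":
        return Duration(self.seconds + other.seconds)

    def __sub__(self, other: "Duration") -> "Duration":
        return Duration(self.seconds - other.seconds)

    # --- rendering ------------------------------------------------------
    @property
    def total_seconds(self) -> float:
        return float(self.seconds)

    def hms(self) -> tuple[int, int, int]:
        """Whole hours, minutes and (rounded) seconds."""
        total = int(round(self.seconds))
        h, rem = divmod(total, 3600)
        m, s = divmod(rem, 60)
        return h, m, s

    def render(self) -> str:
        """Human form, e.g. ``58 min 40 s``; zero trailing parts are omitted."""
        h, m, s = self.hms()
        parts = []
        if h:
            parts.append(f"{h} h")
        if m or (h and s):
            parts.append(f"{m} min")
        if s or not parts:
            parts.append(f"{s} s")
        return " ".join(parts)

    def isoformat(self) -> str:
        """ISO-8601 duration, e.g. ``PT58M40S``."""
        h, m, s = self.hms()
        out = "PT"
        if h:
            out += f"{h}H"
        if m:
            out += f"{m}M"
        if s or out == "PT":
            out += f"{s}S"
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


ZERO = Duration(Fraction(0))


def _speed_map() -> dict[str, float]:
    return {"very_easy": 5.0, "easy": 4.0, "moderate": 3.0, "hard": 2.0}


@dataclass(frozen=True)
class TravelTimeParams:
    """Model constants: surface speeds Has and the slope corrections Us/Ds.

    Defaults follow the published convention: 5/4/3/2 km/h for very-easy
    through hard surfaces, 0.2 km/h uphill and 0.3 km/h downhill.
    """

    has_by_surface: Mapping[str, float] = field(default_factory=_speed_map)
    uphill_speed_us: float = 0.2
    downhill_speed_ds: float = 0.3

    def __post_init__(self) -> None:
        for name, v in self.has_by_surface.items():
            if v <= 0:
                raise ValidationError(f"surface speed for {name!r} must be > 0, got {v}")
        if self.uphill_speed_us <= 0 or self.downhill_speed_ds <= 0:
            raise ValidationError("slope correction speeds must be > 0")


#: Effort-index bands, half-open on the right: the upper endpoint belongs to
#: the lower class ("up to 1 h" is inclusive). Durations in hours.
EFFORT_BANDS: tuple[tuple[float, str, int], ...] = (
    (1, "little", 1),
    (3, "moderate", 2),
    (6, "significant", 3),
    (10, "intense", 4),
    (float("inf"), "extraordinary", 5),
)


@dataclass(frozen=True)
class EffortResult:
    """Effort-index classification of a total travel time."""

    total: Duration
    class_label: str
    points: int


def segment_time(
    distance_km: float,
    has_kmh: float,
    direction: Direction | str,
    params: TravelTimeParams | None = None,
) -> Duration:
    """Travel time of a single monotone stretch.

    ``distance/Has`` minutes plus ``distance/Us`` (uphill) or
    ``distance/Ds`` (downhill) seconds; flat stretches take only the
    horizontal term.
    """
    params = params or TravelTimeParams()
    direction = Direction(direction)
    if distance_km < 0:
        raise ValidationError(f"distance must be >= 0, got {distance_km}")
    if has_kmh <= 0:
        raise ValidationError(f"horizontal speed must be > 0, got {has_kmh}")
    d = Fraction(distance_km).limit_denominator(10**9)
    seconds = d / Fraction(has_kmh).limit_denominator(10**9) * 3600
    if direction is Direction.UPHILL:
        seconds += d / Fraction(params.uphill_speed_us).limit_denominator(10**9) * 60
    elif direction is Direction.DOWNHILL:
        seconds += d / Fraction(params.downhill_speed_ds).limit_denominator(10**9) * 60
    return Duration(seconds)


def trail_time(
    profile: TrailProfile, params: TravelTimeParams | None = None
) -> tuple[list[Duration], Duration]:
    """Per-segment travel times and their exact total."""
    params = params or TravelTimeParams()
    per_segment = [
        segment_time(seg.distance_km, seg.surface_speed_kmh, seg.direction, params)
        for seg in profile.segments
    ]
    total = sum(per_segment, start=ZERO)
    return per_segment, total


def classify_effort(total: Duration) -> EffortResult:
    """Classify a total travel time into the five effort-index bands."""
    hours = total.seconds / 3600
    for upper, label, points in EFFORT_BANDS:
        if hours <= upper:
            return EffortResult(total=total, class_label=label, points=points)
    raise AssertionError("unreachable")  # pragma: no cover
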