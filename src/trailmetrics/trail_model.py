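"""Domain types for trails plus ingestion from GPX tracks and route tables.

A trail is represented as an ordered list of monotone-slope *route
segments*; each segment carries its along-track distance, its endpoint
altitudes, the horizontal speed implied by its surface class, and a slope
direction. Elevation profiles (ordered waypoints) can be segmented into
such routes by breaking wherever the sign of the elevation change flips,
after merging sub-threshold runs into their neighbours.

File formats: GPX 1.1 tracks (elevation required) and a small delimited
route-table layout with header ``route,altitude_end_m,distance_km,
speed_kmh,direction`` whose first data row, labelled ``start``, fixes the
start altitude of the first segment.
"""

from __future__ import annotations

import csv
import io
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from trailmetrics.errors import FormatError, ValidationError

__all__ = [
    "Direction",
    "Waypoint",
    "RouteSegment",
    "TrailProfile",
    "read_segment_table",
    "write_segment_table",
    "read_gpx",
    "segment_profile",
]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


class Direction(str, Enum):
    UPHILL = "uphill"
    DOWNHILL = "downhill"
    FLAT = "flat"


@dataclass(frozen=True)
class Waypoint:
    """A point on an elevation profile: along-track distance (km) and altitude (m)."""

    cumulative_distance_km: float
    altitude_m: float

    def __post_init__(self) -> None:
        if self.cumulative_distance_km < 0:
            raise ValidationError("cumulative distance must be >= 0")


@dataclass(frozen=True)
class RouteSegment:
    """One monotone-slope stretch of trail."""

    label: str
    distance_km: float
    altitude_start_m: float
    altitude_end_m: float
    surface_speed_kmh: float
    direction: Direction
    flat_tolerance_m: float = 0.0

    def __post_init__(self) -> None:
        if self.distance_km <= 0:
            raise ValidationError(
                f"segment {self.label!r}: distance must be > 0, got {self.distance_km}"
            )
        if self.surface_speed_kmh <= 0:
            raise ValidationError(
                f"segment {self.label!r}: surface speed must be > 0"
            )
        delta = self.altitude_end_m - self.altitude_start_m
        d = Direction(self.direction)
        object.__setattr__(self, "direction", d)
        tol = self.flat_tolerance_m
        if d is Direction.UPHILL and delta <= tol:
            raise ValidationError(
                f"segment {self.label!r}: marked uphill but altitude change is {delta} m"
            )
        if d is Direction.DOWNHILL and delta >= -tol:
            raise ValidationError(
                f"segment {self.label!r}: marked downhill but altitude change is {delta} m"
            )
        if d is Direction.FLAT and abs(delta) > tol:
            raise ValidationError(
                f"segment {self.label!r}: marked flat but altitude change is {delta} m"
            )

    @property
    def altitude_change_m(self) -> float:
        return self.altitude_end_m - self.altitude_start_m

    @property
    def gradient_pct(self) -> float:
        """Signed mean gradient of the segment in percent."""
        return 100.0 * self.altitude_change_m / (self.distance_km * 1000.0)


@dataclass(frozen=True)
class TrailProfile:
    """An ordered sequence of route segments forming a named trail."""

    name: str
    segments: tuple[RouteSegment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValidationError(f"trail {self.name!r} has no segments")
        for prev, cur in zip(self.segments, self.segments[1:]):
            if not math.isclose(
                prev.altitude_end_m, cur.altitude_start_m, abs_tol=1e-9
            ):
                raise ValidationError(
                    f"trail {self.name!r}: segment {cur.label!r} does not chain "
                    f"from the previous end altitude"
                )

    @property
    def total_distance_km(self) -> float:
        return sum(s.distance_km for s in self.segments)

    @property
    def ascent_m(self) -> float:
        """Accumulated positive altimetric variation."""
        return sum(max(s.altitude_change_m, 0.0) for s in self.segments)

    @property
    def descent_m(self) -> float:
        """Accumulated negative altimetric variation (as a positive number)."""
        return sum(max(-s.altitude_change_m, 0.0) for s in self.segments)


# ---------------------------------------------------------------------------
# Route-table I/O
# ---------------------------------------------------------------------------

_COLUMNS = ("route", "altitude_end_m", "distance_km", "speed_kmh", "direction")


def _sniff_delimiter(sample: str) -> str:
    return "\t" if "\t" in sample.splitlines()[0] else ","


def read_segment_table(path: str | Path, name: str | None = None) -> TrailProfile:
    """Read a delimited route table into a :class:`TrailProfile`.

    The first data row must be labelled ``start`` and provides the start
    altitude; each subsequent row gives one route's end altitude, distance,
    surface speed and slope direction, chaining altitudes row to row.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    reader = csv.DictReader(io.StringIO(text), delimiter=_sniff_delimiter(text))
    header = [h.strip() for h in (reader.fieldnames or [])]
    for col in _COLUMNS:
        if col not in header:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    rows = [
        {k.strip(): (v or "").strip() for k, v in row.items() if k}
        for row in reader
    ]
    rows = [r for r in rows if any(r.values())]
    if not rows:
        raise ValidationError(f"{path.name}: table has no data rows")
    first = rows[0]
    if first["route"].lower() != "start":
        raise FormatError(f"{path.name}: first data row must be the 'start' row")
    altitude = float(first["altitude_end_m"])
    segments: list[RouteSegment] = []
    for row in rows[1:]:
        distance = float(row["distance_km"])
        if distance <= 0:
            raise ValidationError(
                f"{path.name}: route {row['route']!r} has non-positive distance"
            )
        end_alt = float(row["altitude_end_m"])
        segments.append(
            RouteSegment(
                label=row["route"],
                distance_km=distance,
                altitude_start_m=altitude,
                altitude_end_m=end_alt,
                surface_speed_kmh=float(row["speed_kmh"]),
                direction=Direction(row["direction"].lower()),
            )
        )
        altitude = end_alt
    if not segments:
        raise ValidationError(f"{path.name}: table contains only the start row")
    return TrailProfile(name=name or path.stem, segments=tuple(segments))


def write_segment_table(profile: TrailProfile, path: str | Path) -> None:
    """Write a profile in the delimited layout read by :func:`read_segment_table`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        writer.writerow(
            ["start", _fmt(profile.segments[0].altitude_start_m), "0", "", ""]
        )
        for seg in profile.segments:
            writer.writerow(
                [
                    seg.label,
                    _fmt(seg.altitude_end_m),
                    _fmt(seg.distance_km),
                    _fmt(seg.surface_speed_kmh),
                    seg.direction.value,
                ]
            )


def _fmt(x: float) -> str:
    return f"{x:.10g}"


# ---------------------------------------------------------------------------
# GPX ingestion
# ---------------------------------------------------------------------------


def _haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two WGS-84 points, in km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def read_gpx(path: str | Path) -> list[Waypoint]:
    """Read track points of a GPX 1.1 file into waypoints.

    Cumulative distance is the running great-circle distance between
    successive track points; elevations are used verbatim (no datum
    handling). Every track point must carry an ``<ele>`` element.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    points = root.findall(f".//{ns}trkpt")
    if not points:
        raise FormatError(f"{path.name}: no track points found")
    waypoints: list[Waypoint] = []
    cum = 0.0
    prev: tuple[float, float] | None = None
    for pt in points:
        lat, lon = float(pt.get("lat")), float(pt.get("lon"))
        ele = pt.find(f"{ns}ele")
        if ele is None or ele.text is None:
            raise FormatError(
                f"{path.name}: track point without elevation; elevation is required"
            )
        if prev is not None:
            cum += _haversine_km(prev[0], prev[1], lat, lon)
        waypoints.append(Waypoint(cumulative_distance_km=cum, altitude_m=float(ele.text)))
        prev = (lat, lon)
    return waypoints


# ---------------------------------------------------------------------------
# Profile segmentation
# ---------------------------------------------------------------------------


def segment_profile(
    waypoints: Sequence[Waypoint],
    min_elev_change_m: float = 1.0,
    surface_speed_kmh: float = 4.0,
    name: str = "trail",
    flat_tolerance_m: float = 0.0,
) -> TrailProfile:
    """Split an elevation profile into monotone-slope route segments.

    Consecutive steps with the same elevation-change sign form a run; runs
    whose total absolute elevation change is below ``min_elev_change_m``
    are merged into their left neighbour (the first run merges rightward).
    Segment distances always sum to the track length.
    """
    if len(waypoints) < 2:
        raise ValidationError("at least 2 waypoints are required")
    for a, b in zip(waypoints, waypoints[1:]):
        if b.cumulative_distance_km < a.cumulative_distance_km:
            raise ValidationError("cumulative distance must be non-decreasing")

    # runs: [start_idx, end_idx, sign] over waypoint indices
    runs: list[list[float]] = []
    for i in range(len(waypoints) - 1):
        delta = waypoints[i + 1].altitude_m - waypoints[i].altitude_m
        sign = 0 if delta == 0 else (1 if delta > 0 else -1)
        if runs and (sign == runs[-1][2] or sign == 0):
            runs[-1][1] = i + 1
        elif runs and runs[-1][2] == 0:
            runs[-1][1] = i + 1
            runs[-1][2] = sign
        else:
            runs.append([i, i + 1, sign])

    def run_change(r: list[float]) -> float:
        return abs(
            waypoints[int(r[1])].altitude_m - waypoints[int(r[0])].altitude_m
        )

    # merge sub-threshold runs into their neighbour until stable
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, r in enumerate(runs):
            if run_change(r) < min_elev_change_m:
                if k > 0:
                    runs[k - 1][1] = r[1]
                else:
                    runs[1][0] = r[0]
                del runs[k]
                changed = True
                break
    # adjacent runs may now share a sign; coalesce
    merged: list[list[float]] = []
    for r in runs:
        sign = _net_sign(waypoints, r, flat_tolerance_m)
        if merged and sign == merged[-1][2]:
            merged[-1][1] = r[1]
        else:
            merged.append([r[0], r[1], sign])

    segments: list[RouteSegment] = []
    for k, (i0, i1, sign) in enumerate(merged, start=1):
        i0, i1 = int(i0), int(i1)
        dist = (
            waypoints[i1].cumulative_distance_km - waypoints[i0].cumulative_distance_km
        )
        if dist <= 0:
            continue  # zero-length run (duplicate points)
        direction = {1: Direction.UPHILL, -1: Direction.DOWNHILL, 0: Direction.FLAT}[sign]
        segments.append(
            RouteSegment(
                label=f"Route {k}",
                distance_km=dist,
                altitude_start_m=waypoints[i0].altitude_m,
                altitude_end_m=waypoints[i1].altitude_m,
                surface_speed_kmh=surface_speed_kmh,
                direction=direction,
                flat_tolerance_m=max(flat_tolerance_m, 1e-12),
            )
        )
    if not segments:
        raise ValidationError("profile has zero total length")
    return TrailProfile(name=name, segments=tuple(segments))


def _net_sign(
    waypoints: Sequence[Waypoint], run: list[float], flat_tolerance_m: float
) -> int:
    delta = waypoints[int(run[1])].altitude_m - waypoints[int(run[0])].altitude_m
    if abs(delta) <= flat_tolerance_m:
        return 0
    return 1 if delta > 0 else -1
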