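"""Synthetic input generators emulating the study's data shapes.

Three generators cover the pipeline's inputs: segmented elevation
profiles with mixed slope signs (and a GPX-track variant with a known
arc length), rubric responses with set marginal probabilities, and
multivariate-normal indicator data drawn from a known sparse precision
matrix. Each generator is a pure function of its configuration and seed;
one global seed fans out to independent per-generator streams, so adding
a generator never perturbs existing fixtures.

Defaults emulate the study conditions: ~10 routes per trail of
0.05–0.4 km with elevation changes of a few metres to ~20 m on a hard
(2 km/h) surface; 26-item severity checklists with item probability
0.35 (matching observed severity scores of 7–11); and a 7-variable
chain-structured precision matrix with partial correlations of 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trailmetrics.errors import ValidationError
from trailmetrics.scoring import SEVERITY_ITEMS, SeverityChecklist
from trailmetrics.trail_model import (
    Direction,
    RouteSegment,
    TrailProfile,
    Waypoint,
)

__all__ = [
    "SynthConfig",
    "TrailTruth",
    "synth_trail",
    "synth_gpx",
    "synth_checklist",
    "synth_indicator_data",
    "chain_precision",
]

# fixed spawn keys: one independent stream per generator
_STREAM_TRAIL = 0
_STREAM_GPX = 1
_STREAM_CHECKLIST = 2
_STREAM_INDICATORS = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition defaults for the generators."""

    seed: int = 0
    n_routes: int = 10
    route_length_km: tuple[float, float] = (0.05, 0.4)
    elev_change_mean_m: float = 10.0
    elev_change_sd_m: float = 4.0
    start_altitude_m: float = 450.0
    surface_speed_kmh: float = 2.0
    alternate_signs: bool = True
    checklist_p: float = 0.35
    n_waypoints_per_route: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.checklist_p <= 1.0:
            raise ValidationError("checklist_p must be in [0, 1]")
        if self.n_routes < 1:
            raise ValidationError("n_routes must be >= 1")
        lo, hi = self.route_length_km
        if not 0 < lo <= hi:
            raise ValidationError("route_length_km bounds must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class TrailTruth:
    """Ground truth recorded alongside a generated trail."""

    total_km: float
    breakpoints: tuple[int, ...]  # waypoint indices where segments start/end
    n_segments: int
    segment_signs: tuple[int, ...]


def synth_trail(cfg: SynthConfig) -> tuple[TrailProfile, list[Waypoint], TrailTruth]:
    """Generate a trail profile, its waypoint track and the ground truth.

    Per-route elevation changes are normal draws (clipped away from zero)
    with alternating or random signs; each route is sampled at several
    intermediate waypoints so segmentation has something to do. The truth
    records the total length and the waypoint indices of the true
    monotone-run boundaries (consecutive same-sign routes merged).
    """
    rng = _rng(cfg.seed, _STREAM_TRAIL)
    lo, hi = cfg.route_length_km
    lengths = rng.uniform(lo, hi, size=cfg.n_routes)
    changes = np.abs(rng.normal(cfg.elev_change_mean_m, cfg.elev_change_sd_m, cfg.n_routes))
    changes = np.maximum(changes, 0.5)
    if cfg.alternate_signs:
        signs = np.array([1 if i % 2 == 0 else -1 for i in range(cfg.n_routes)])
    else:
        signs = rng.choice([-1, 1], size=cfg.n_routes)

    waypoints = [Waypoint(0.0, cfg.start_altitude_m)]
    segments: list[RouteSegment] = []
    cum, alt = 0.0, cfg.start_altitude_m
    route_end_idx = [0]
    for k in range(cfg.n_routes):
        end_alt = alt + signs[k] * changes[k]
        n_steps = cfg.n_waypoints_per_route
        # strictly monotone interior altitudes
        fracs = np.sort(rng.uniform(0.05, 0.95, size=n_steps - 1))
        for f in fracs:
            waypoints.append(
                Waypoint(cum + f * lengths[k], alt + f * (end_alt - alt))
            )
        cum += lengths[k]
        waypoints.append(Waypoint(cum, end_alt))
        route_end_idx.append(len(waypoints) - 1)
        segments.append(
            RouteSegment(
                label=f"Route {k + 1}",
                distance_km=float(lengths[k]),
                altitude_start_m=float(alt),
                altitude_end_m=float(end_alt),
                surface_speed_kmh=cfg.surface_speed_kmh,
                direction=Direction.UPHILL if signs[k] > 0 else Direction.DOWNHILL,
            )
        )
        alt = end_alt

    # merge consecutive same-sign routes for the true segmentation
    true_breaks = [0]
    seg_signs: list[int] = []
    for k in range(cfg.n_routes):
        if seg_signs and signs[k] == seg_signs[-1]:
            true_breaks[-1] = route_end_idx[k + 1]
        else:
            true_breaks.append(route_end_idx[k + 1])
            seg_signs.append(int(signs[k]))
    truth = TrailTruth(
        total_km=float(lengths.sum()),
        breakpoints=tuple(true_breaks),
        n_segments=len(seg_signs),
        segment_signs=tuple(seg_signs),
    )
    profile = TrailProfile(name=f"synthetic-{cfg.seed}", segments=tuple(segments))
    return profile, waypoints, truth


def synth_gpx(
    cfg: SynthConfig, n_points: int = 100, latitude: float = -7.23
) -> tuple[str, float]:
    """A GPX 1.1 track heading east along a parallel, plus its true arc length.

    Step lengths are drawn uniformly from 10–50 m and converted to
    longitude increments at the given latitude; altitudes follow a smooth
    random walk. Returns the GPX document text and the exact arc length
    (km) the generator laid down.
    """
    from trailmetrics.trail_model import EARTH_RADIUS_KM

    rng = _rng(cfg.seed, _STREAM_GPX)
    steps_km = rng.uniform(0.010, 0.050, size=n_points - 1)
    lat_rad = math.radians(latitude)
    lon = -39.44
    alts = cfg.start_altitude_m + np.cumsum(rng.normal(0.0, 1.0, size=n_points))
    rows = []
    rows.append(f'<trkpt lat="{latitude:.8f}" lon="{lon:.8f}"><ele>{alts[0]:.2f}</ele></trkpt>')
    for k, step in enumerate(steps_km, start=1):
        dlon = math.degrees(step / (EARTH_RADIUS_KM * math.cos(lat_rad)))
        lon += dlon
        rows.append(
            f'<trkpt lat="{latitude:.8f}" lon="{lon:.8f}"><ele>{alts[k]:.2f}</ele></trkpt>'
        )
    body = "\n      ".join(rows)
    gpx = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<gpx version="1.1" creator="trailmetrics" '
        'xmlns="http://www.topografix.com/GPX/1/1">\n'
        "  <trk>\n    <trkseg>\n      " + body + "\n    </trkseg>\n  </trk>\n</gpx>\n"
    )
    return gpx, float(steps_km.sum())


def synth_checklist(cfg: SynthConfig) -> SeverityChecklist:
    """Bernoulli(p) severity checklist; expected score is 26·p."""
    rng = _rng(cfg.seed, _STREAM_CHECKLIST)
    draws = rng.random(len(SEVERITY_ITEMS)) < cfg.checklist_p
    return SeverityChecklist(dict(zip(SEVERITY_ITEMS, (bool(d) for d in draws))))


def chain_precision(p: int = 7, partial: float = 0.3) -> np.ndarray:
    """Chain-structured precision matrix with equal partial correlations.

    Unit diagonal with −``partial`` on the first off-diagonal, so each of
    the p−1 chain edges has partial correlation ``partial``.
    """
    theta = np.eye(p)
    for i in range(p - 1):
        theta[i, i + 1] = theta[i + 1, i] = -partial
    return theta


def synth_indicator_data(
    precision: np.ndarray,
    n: int,
    seed: int,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw n observations from N(0, Θ⁻¹) for a known precision matrix Θ."""
    theta = np.asarray(precision, dtype=float)
    p = theta.shape[0]
    if theta.shape != (p, p) or not np.allclose(theta, theta.T):
        raise ValidationError("precision must be a symmetric square matrix")
    eigmin = float(np.linalg.eigvalsh(theta).min())
    if eigmin <= 0:
        raise ValidationError(
            f"precision matrix must be positive definite (min eigenvalue {eigmin:.3e})"
        )
    cov = np.linalg.inv(theta)
    rng = _rng(seed, _STREAM_INDICATORS)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    cols = list(labels) if labels is not None else [f"V{i+1}" for i in range(p)]
    return pd.DataFrame(X, columns=cols)
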