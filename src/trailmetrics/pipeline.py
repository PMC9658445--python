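"""Pipeline orchestration: per-trail classification and cross-trail networks.

A YAML/JSON configuration describes each trail (route table, rubric
responses, overload inputs) and the network settings. ``run_pipeline``
classifies every trail independently — a failure in one trail is recorded
and does not abort the others — then assembles the prevalence matrix and
estimates the partial-correlation network across trails.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Any, Mapping

import yaml

import trailmetrics
from trailmetrics.errors import TrailmetricsError, ValidationError
from trailmetrics.network import (
    CentralityResult,
    NetworkConfig,
    NetworkModel,
    build_prevalence_matrix,
    correlation,
    select_network,
    strength,
)
from trailmetrics.overload import (
    OverloadResult,
    additional_time,
    effort_with_overload,
    overload_percent,
)
from trailmetrics.scoring import (
    AquaticIndicators,
    ClimateGrid,
    ScoreResult,
    SeverityChecklist,
    classify_orientation,
    classify_surface,
    score_aquatic,
    score_climate,
    score_severity,
    score_wellness,
    geodiversity_prevalence,
    shannon_index,
)
from trailmetrics.trail_model import TrailProfile, read_segment_table
from trailmetrics.travel_time import Duration, EffortResult, classify_effort, trail_time

__all__ = [
    "TrailReport",
    "PipelineResult",
    "load_config",
    "run_pipeline",
    "write_report",
    "report_from_dict",
]

_CLIMATE_ROWS = ("insolation", "temperature", "rainfall", "humidity", "winds", "green_tunnel")


@dataclass(frozen=True)
class TrailReport:
    """Everything the pipeline computed for one trail."""

    trail: str
    segment_labels: tuple[str, ...]
    segment_times: tuple[Duration, ...]
    total_time: Duration
    effort: EffortResult
    effort_with_overload: EffortResult | None
    severity: ScoreResult
    orientation: ScoreResult
    surface_level: int
    surface_label: str
    aquatic: ScoreResult
    climate: ScoreResult
    wellness: ScoreResult
    geodiversity: ScoreResult
    shannon_h: float | None
    shannon_prevalence_pct: float | None
    overload: OverloadResult | None
    att_pct: float | None
    total_distance_km: float
    provenance: Mapping[str, str] = field(default_factory=dict)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def dur(d: Duration) -> dict[str, str]:
            return {"seconds": str(d.seconds), "human": d.render(), "iso": d.isoformat()}

        def score(s: ScoreResult) -> dict[str, Any]:
            return {
                "total": s.total,
                "reference": s.reference,
                "prevalence_pct": s.prevalence_pct,
                "class_label": s.class_label,
                "subtotals": list(s.subtotals) if s.subtotals else None,
            }

        out: dict[str, Any] = {
            "trail": self.trail,
            "segments": [
                {"label": lab, "time": dur(t)}
                for lab, t in zip(self.segment_labels, self.segment_times)
            ],
            "total_time": dur(self.total_time),
            "total_distance_km": self.total_distance_km,
            "effort": {
                "class": self.effort.class_label,
                "points": self.effort.points,
            },
            "severity": score(self.severity),
            "orientation": score(self.orientation),
            "surface": {"level": self.surface_level, "label": self.surface_label},
            "aquatic": score(self.aquatic),
            "climate": score(self.climate),
            "wellness": score(self.wellness),
            "geodiversity": score(self.geodiversity),
            "shannon": (
                {"h": self.shannon_h, "prevalence_pct": self.shannon_prevalence_pct}
                if self.shannon_h is not None
                else None
            ),
            "overload": (
                {
                    "measured_km": self.overload.measured_km,
                    "equivalent_km": self.overload.equivalent_km,
                    "percent_increase": self.overload.percent_increase,
                    "additional_time": dur(self.overload.additional_time),
                }
                if self.overload
                else None
            ),
            "att_pct": self.att_pct,
            "effort_with_overload": (
                {
                    "class": self.effort_with_overload.class_label,
                    "points": self.effort_with_overload.points,
                    "total_time": dur(self.effort_with_overload.total),
                }
                if self.effort_with_overload
                else None
            ),
            "provenance": dict(self.provenance),
        }
        return out

    def to_markdown(self) -> str:
        lines = [f"# Trail report: {self.trail}", ""]
        lines += [
            "| Route | Travel time |",
            "|---|---|",
        ]
        for lab, t in zip(self.segment_labels, self.segment_times):
            lines.append(f"| {lab} | {t.render()} |")
        lines.append(f"| **Total ({self.total_distance_km:g} km)** | **{self.total_time.render()}** |")
        lines += [
            "",
            f"Effort index: {self.effort.class_label} ({self.effort.points} pt)",
        ]
        if self.effort_with_overload is not None:
            e = self.effort_with_overload
            lines.append(
                f"Effort with overload: {e.class_label} ({e.points} pt), "
                f"total {e.total.render()}"
            )
        lines += [
            "",
            "| Rubric | Score | Reference | Prevalence |",
            "|---|---|---|---|",
        ]
        for name, s in (
            ("Severity", self.severity),
            ("Orientation", self.orientation),
            ("Aquatic diversity", self.aquatic),
            ("Climate exposure", self.climate),
            ("Wellness experience", self.wellness),
            ("Geodiversity", self.geodiversity),
        ):
            cls = f" ({s.class_label})" if s.class_label else ""
            lines.append(
                f"| {name} | {s.total:g}{cls} | {s.reference:g} | {s.prevalence_pct:.1f}% |"
            )
        if self.shannon_h is not None:
            lines.append(
                f"| Shannon–Weaver H | {self.shannon_h:g} | 5.5 | "
                f"{self.shannon_prevalence_pct:.1f}% |"
            )
        if self.overload is not None:
            o = self.overload
            lines += [
                "",
                f"Knee-overload equivalent distance: {o.equivalent_km:g} km "
                f"({o.percent_increase:+.1f}% over {o.measured_km:g} km); "
                f"additional time {o.additional_time.render()}.",
            ]
        lines.append("")
        return "\n".join(lines)


def report_from_dict(data: Mapping[str, Any]) -> TrailReport:
    """Inverse of :meth:`TrailReport.to_dict` (lossless round-trip)."""

    def dur(d: Mapping[str, str]) -> Duration:
        return Duration(Fraction(d["seconds"]))

    def score(s: Mapping[str, Any]) -> ScoreResult:
        return ScoreResult(
            total=s["total"],
            reference=s["reference"],
            class_label=s["class_label"],
            subtotals=tuple(s["subtotals"]) if s["subtotals"] else None,
        )

    effort = classify_effort(dur(data["total_time"]))
    ewo = None
    if data.get("effort_with_overload"):
        ewo = classify_effort(dur(data["effort_with_overload"]["total_time"]))
    overload = None
    if data.get("overload"):
        o = data["overload"]
        overload = OverloadResult(
            measured_km=o["measured_km"],
            equivalent_km=o["equivalent_km"],
            percent_increase=o["percent_increase"],
            additional_time=dur(o["additional_time"]),
        )
    shannon = data.get("shannon") or {}
    return TrailReport(
        trail=data["trail"],
        segment_labels=tuple(s["label"] for s in data["segments"]),
        segment_times=tuple(dur(s["time"]) for s in data["segments"]),
        total_time=dur(data["total_time"]),
        effort=effort,
        effort_with_overload=ewo,
        severity=score(data["severity"]),
        orientation=score(data["orientation"]),
        surface_level=data["surface"]["level"],
        surface_label=data["surface"]["label"],
        aquatic=score(data["aquatic"]),
        climate=score(data["climate"]),
        wellness=score(data["wellness"]),
        geodiversity=score(data["geodiversity"]),
        shannon_h=shannon.get("h"),
        shannon_prevalence_pct=shannon.get("prevalence_pct"),
        overload=overload,
        att_pct=data.get("att_pct"),
        total_distance_km=data["total_distance_km"],
        provenance=dict(data.get("provenance", {})),
    )


@dataclass
class PipelineResult:
    """Per-trail reports plus the cross-trail network stage."""

    reports: list[TrailReport]
    failures: dict[str, str]
    matrix: Any  # pandas DataFrame or None
    network: NetworkModel | None
    centrality: CentralityResult | None


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config root must be a mapping")
    cfg["_config_dir"] = str(path.parent)
    return cfg


def _require(mapping: Mapping[str, Any], key: str, path: str) -> Any:
    if not isinstance(mapping, Mapping) or key not in mapping:
        raise ValidationError(f"config error at {path}.{key}: key is missing")
    return mapping[key]


def _classify_trail(
    tcfg: Mapping[str, Any], idx: int, config_dir: Path, provenance: Mapping[str, str]
) -> TrailReport:
    where = f"trails[{idx}]"
    name = _require(tcfg, "name", where)
    table = config_dir / _require(tcfg, "route_table", where)
    profile = read_segment_table(table, name=name)
    per_segment, total = trail_time(profile)
    effort = classify_effort(total)

    severity = score_severity(
        SeverityChecklist.from_checked(_require(tcfg, "severity_checked", where))
    )
    orientation = classify_orientation(int(_require(tcfg, "orientation", where)))
    surface_level = int(_require(tcfg, "surface", where))
    surface_label, _ = classify_surface(surface_level)
    aquatic = score_aquatic(AquaticIndicators(**_require(tcfg, "aquatic", where)))
    climate_cfg = _require(tcfg, "climate", where)
    grid = ClimateGrid(
        tuple(tuple(_require(climate_cfg, row, f"{where}.climate")) for row in _CLIMATE_ROWS)
    )
    climate = score_climate(grid)
    wellness = score_wellness(dict(_require(tcfg, "wellness", where)))
    geodiv = geodiversity_prevalence(dict(_require(tcfg, "geodiversity", where)))

    shannon_h = tcfg.get("shannon_h")
    shannon_prev = None
    if shannon_h is not None:
        # a supplied H is compared to the tropical-forest reference directly
        shannon_prev = 100.0 * float(shannon_h) / 5.5
    elif tcfg.get("abundances") is not None:
        shannon_h, shannon_prev = shannon_index(tcfg["abundances"])

    measured = profile.total_distance_km
    overload = None
    att_pct = tcfg.get("att_pct")
    ewo = None
    if tcfg.get("equivalent_km") is not None:
        equivalent = float(tcfg["equivalent_km"])
        has = _predominant_speed(profile)
        if tcfg.get("att") is not None:
            att = Duration.parse(str(tcfg["att"]))
        else:
            att = additional_time(measured, equivalent, has)
        overload = OverloadResult(
            measured_km=measured,
            equivalent_km=equivalent,
            percent_increase=overload_percent(measured, equivalent),
            additional_time=att,
        )
        ewo = effort_with_overload(total, att)

    return TrailReport(
        trail=name,
        segment_labels=tuple(s.label for s in profile.segments),
        segment_times=tuple(per_segment),
        total_time=total,
        effort=effort,
        effort_with_overload=ewo,
        severity=severity,
        orientation=orientation,
        surface_level=surface_level,
        surface_label=surface_label,
        aquatic=aquatic,
        climate=climate,
        wellness=wellness,
        geodiversity=geodiv,
        shannon_h=float(shannon_h) if shannon_h is not None else None,
        shannon_prevalence_pct=shannon_prev,
        overload=overload,
        att_pct=float(att_pct) if att_pct is not None else None,
        total_distance_km=measured,
        provenance=provenance,
    )


def _predominant_speed(profile: TrailProfile) -> float:
    speeds = [s.surface_speed_kmh for s in profile.segments]
    return max(set(speeds), key=speeds.count)


def run_pipeline(config: str | Path | Mapping[str, Any], seed: int = 0) -> PipelineResult:
    """Classify every configured trail, then run the network stage.

    Per-trail failures are collected in ``failures`` (trail name → error
    message) without aborting the remaining trails. The network stage
    runs only if at least two trails classified successfully.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = dict(config)
    config_dir = Path(cfg.get("_config_dir", "."))
    trails = cfg.get("trails")
    if not trails:
        raise ValidationError("config error at trails: at least one trail is required")

    canon = json.dumps(
        {k: v for k, v in cfg.items() if not k.startswith("_")},
        sort_keys=True,
        default=str,
    )
    provenance = {
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "package_version": trailmetrics.__version__,
        "seed": str(seed),
    }

    reports: list[TrailReport] = []
    failures: dict[str, str] = {}
    for idx, tcfg in enumerate(trails):
        name = tcfg.get("name", f"trails[{idx}]")
        try:
            reports.append(_classify_trail(tcfg, idx, config_dir, provenance))
        except Exception as exc:  # a bad trail must not abort the others
            failures[str(name)] = f"{type(exc).__name__}: {exc}"

    matrix = network = centrality = None
    if len(reports) >= 2 and all(r.overload is not None for r in reports):
        indicators = {
            r.trail: {
                "es": r.severity.total,
                "cg": r.orientation.total,
                "sg": r.surface_level,
                "td_km": r.total_distance_km,
                "bok_km": r.overload.equivalent_km,
                "tt": r.total_time,
                "att": r.overload.additional_time,
                "att_pct": r.att_pct,
            }
            for r in reports
        }
        matrix = build_prevalence_matrix(indicators)
        ncfg = NetworkConfig(**cfg.get("network", {}))
        corr = correlation(matrix, method=ncfg.correlation_method)
        network = select_network(corr, n=len(matrix), config=ncfg)
        centrality = strength(network)
    return PipelineResult(
        reports=reports,
        failures=failures,
        matrix=matrix,
        network=network,
        centrality=centrality,
    )


def write_report(report: TrailReport, path: str | Path, format: str = "json") -> Path:
    """Serialize a report as deterministic JSON or as a markdown table."""
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(report.to_dict(), sort_keys=True, indent=2, ensure_ascii=False)
            + "\n",
            encoding="utf-8",
        )
    elif format == "markdown":
        path.write_text(report.to_markdown(), encoding="utf-8")
    else:
        raise ValidationError(f"unknown report format {format!r}")
    return path
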