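"""Biomechanical knee-overload as an equivalent horizontal distance.

Walking on a gradient raises the maximum plantar pressure (and, through
the patellofemoral chain, knee load) relative to level walking. A linear
gradient→relative-load regression, normalized so that the zero-gradient
multiplier is exactly 1, converts each sloped stretch into the length of
flat walk that would accumulate the same load. Summing over stretches
yields the trail's *equivalent horizontal distance*; the excess over the
measured distance is the biomechanical overload of the knee (BOK), and
walking that excess at the trail's horizontal speed gives the Additional
Travel Time (ATT).

The regression coefficients come from external gait studies and are a
configurable input; published equivalent distances can also be supplied
directly, bypassing the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np

from trailmetrics.errors import FitError, ValidationError
from trailmetrics.trail_model import TrailProfile
from trailmetrics.travel_time import Duration, EffortResult, classify_effort

__all__ = [
    "LoadModel",
    "OverloadResult",
    "fit_load_model",
    "equivalent_distance",
    "overload_percent",
    "additional_time",
    "effort_with_overload",
]

R2_GATE = 0.8  # minimum coefficient of determination for an acceptable fit


@dataclass(frozen=True)
class LoadModel:
    """Linear gradient→relative-load model, multiplier(g) = intercept + slope·g.

    ``intercept`` is 1 by construction (level walking is its own reference)
    and ``slope`` is the load multiplier per percent gradient. With
    ``gradient_transform="absolute"`` (default) both uphill and downhill
    stretches load the knee; ``"signed"`` treats descent as relief.
    ``reference_steps`` records the flat-walk reference the accumulated
    load is expressed against (5000 steps ≈ 5 km).
    """

    slope: float
    intercept: float = 1.0
    r_squared: float = 1.0
    reference_steps: int = 5000
    gradient_transform: Literal["absolute", "signed"] = "absolute"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValidationError("r_squared must be in [0, 1]")
        if abs(self.intercept - 1.0) > 1e-9:
            raise ValidationError(
                "load model must be normalized: multiplier at zero gradient is 1"
            )

    def multiplier(self, gradient_pct: float) -> float:
        g = abs(gradient_pct) if self.gradient_transform == "absolute" else gradient_pct
        return self.intercept + self.slope * g

    @classmethod
    def identity(cls) -> "LoadModel":
        return cls(slope=0.0)


@dataclass(frozen=True)
class OverloadResult:
    """Measured vs load-equivalent distance and the implied extra time."""

    measured_km: float
    equivalent_km: float
    percent_increase: float
    additional_time: Duration


def fit_load_model(
    pairs: Sequence[tuple[float, float]],
    reference_steps: int = 5000,
    gradient_transform: Literal["absolute", "signed"] = "absolute",
) -> LoadModel:
    """Fit the gradient→load regression by ordinary least squares.

    ``pairs`` are (gradient in percent, representative maximum plantar
    pressure) observations. The fitted line is rescaled by its own
    zero-gradient prediction so the multiplier at g=0 is exactly 1. Fits
    with R² below 0.8 are rejected.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("at least 3 (gradient, load) pairs are required")
    g, y = arr[:, 0], arr[:, 1]
    if np.ptp(g) == 0:
        raise ValidationError("degenerate design: gradients are all equal")
    slope, intercept = np.polyfit(g, y, 1)
    resid = y - (intercept + slope * g)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    if r2 < R2_GATE:
        raise FitError(
            f"gradient-load regression rejected: R² = {r2:.3f} is below the "
            f"acceptance threshold of {R2_GATE}"
        )
    if intercept == 0:
        raise ValidationError("zero-gradient load is zero; cannot normalize")
    return LoadModel(
        slope=float(slope / intercept),
        intercept=1.0,
        r_squared=r2,
        reference_steps=reference_steps,
        gradient_transform=gradient_transform,
    )


def equivalent_distance(profile: TrailProfile, model: LoadModel) -> float:
    """Load-equivalent horizontal distance of a trail, in km.

    Each segment contributes its distance times the load multiplier at
    the segment's mean gradient; the identity model returns the measured
    distance exactly.
    """
    return sum(
        seg.distance_km * model.multiplier(seg.gradient_pct)
        for seg in profile.segments
    )


def overload_percent(measured_km: float, equivalent_km: float) -> float:
    """Percent increase of the equivalent over the measured distance."""
    if measured_km <= 0:
        raise ValidationError("measured distance must be > 0")
    return 100.0 * (equivalent_km / measured_km - 1.0)


def additional_time(
    measured_km: float, equivalent_km: float, has_kmh: float
) -> Duration:
    """Extra travel time for the overload-equivalent extra distance.

    The excess distance is walked at the trail's horizontal speed Has:
    (equivalent − measured)/Has hours, clamped at zero.
    """
    if has_kmh <= 0:
        raise ValidationError("horizontal speed must be > 0")
    extra_km = max(equivalent_km - measured_km, 0.0)
    seconds = (
        Fraction(extra_km).limit_denominator(10**9)
        / Fraction(has_kmh).limit_denominator(10**9)
        * 3600
    )
    return Duration(seconds)


def effort_with_overload(base: Duration, additional: Duration) -> EffortResult:
    """Effort classification of the base travel time plus the overload time."""
    return classify_effort(base + additional)


def overload_result(
    measured_km: float, equivalent_km: float, has_kmh: float
) -> OverloadResult:
    """Bundle the overload outputs for one trail."""
    return OverloadResult(
        measured_km=measured_km,
        equivalent_km=equivalent_km,
        percent_increase=overload_percent(measured_km, equivalent_km),
        additional_time=additional_time(measured_km, equivalent_km, has_kmh),
    )
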