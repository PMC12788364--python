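"""Speed-zone prescription from ventilatory thresholds, with altitude
adjustment that holds relative cardiovascular effort approximately constant.

Zones: v1 = 90% of the speed at the first ventilatory threshold, v2 = the
midpoint of the two threshold speeds, v3 = the speed at the second
threshold.  Under acute hypoxia the relative effort at a fixed submaximal
speed rises because submaximal heart rate increases while maximal heart
rate drops; the combined multiplicative factor motivates a uniform speed
reduction per 1000 m of elevation gain.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SpeedZones",
    "HypoxiaParams",
    "STUDY_SPEED_REDUCTIONS",
    "speed_zones",
    "hypoxia_intensity_factor",
    "adjust_speed",
    "pace_from_speed",
    "speed_from_pace",
]

#: literal per-elevation uniform speed reductions used at the three study
#: sites; other elevations fall back to the linear per-km rate.
STUDY_SPEED_REDUCTIONS: dict[int, float] = {50: 0.0, 1000: 0.033, 2300: 0.078}


@dataclass(frozen=True)
class SpeedZones:
    """Threshold speeds and the three derived training speeds, km/h."""

    vVT1_kmh: float
    vVT2_kmh: float
    v1_kmh: float
    v2_kmh: float
    v3_kmh: float

    def speed(self, level: str) -> float:
        return {"v1": self.v1_kmh, "v2": self.v2_kmh, "v3": self.v3_kmh}[level]


@dataclass(frozen=True)
class HypoxiaParams:
    """Parameters of the hypoxia effort model (all rates per 1000 m).

    submax_fraction is the reference submaximal-to-peak oxygen-uptake ratio
    at which the submaximal heart-rate response was characterised.
    """

    submax_fraction: float = 55.00 / 62.17
    submax_hr_rate: float = 0.05113
    max_hr_drop: float = 0.0101
    speed_correction_rate: float = 0.033

    def __post_init__(self) -> None:
        for name in ("submax_hr_rate", "max_hr_drop", "speed_correction_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


def speed_zones(vVT1_kmh: float, vVT2_kmh: float) -> SpeedZones:
    """Derive v1, v2, v3 from the two ventilatory-threshold speeds."""
    if vVT1_kmh <= 0:
        raise ValueError("vVT1 must be > 0")
    if vVT1_kmh > vVT2_kmh:
        raise ValueError(f"vVT1 ({vVT1_kmh}) must not exceed vVT2 ({vVT2_kmh})")
    return SpeedZones(
        vVT1_kmh=vVT1_kmh,
        vVT2_kmh=vVT2_kmh,
        v1_kmh=0.9 * vVT1_kmh,
        v2_kmh=0.5 * (vVT1_kmh + vVT2_kmh),
        v3_kmh=vVT2_kmh,
    )


def hypoxia_intensity_factor(
    elevation_gain_km: float, params: HypoxiaParams | None = None
) -> float:
    """Multiplicative increase in relative effort (%HRmax) per elevation gain.

    Per 1000 m the factor is
    ``(1 + submax_fraction * submax_hr_rate) * (1 - max_hr_drop)``,
    composed multiplicatively over the gain; identity at zero gain.
    """
    params = params or HypoxiaParams()
    if elevation_gain_km < 0:
        raise ValueError("elevation gain must be >= 0")
    per_km = (1.0 + params.submax_fraction * params.submax_hr_rate) * (
        1.0 - params.max_hr_drop
    )
    return per_km**elevation_gain_km


def adjust_speed(
    v_kmh: float, elevation_m: float, params: HypoxiaParams | None = None
) -> float:
    """Reduce a prescribed speed for altitude.

    At the three study elevations the literal reduction table
    (:data:`STUDY_SPEED_REDUCTIONS`) applies; elsewhere the linear
    ``speed_correction_rate`` per 1000 m is used as a documented
    extrapolation.
    """
    params = params or HypoxiaParams()
    if v_kmh <= 0:
        raise ValueError("speed must be > 0")
    if elevation_m < 0:
        raise ValueError("elevation must be >= 0")
    key = int(elevation_m)
    if key in STUDY_SPEED_REDUCTIONS:
        r = STUDY_SPEED_REDUCTIONS[key]
    else:
        r = params.speed_correction_rate * elevation_m / 1000.0
    return v_kmh * (1.0 - r)


def pace_from_speed(v_kmh: float) -> float:
    """Speed in km/h -> pace in seconds per km."""
    if v_kmh <= 0:
        raise ValueError("speed must be > 0")
    return 3600.0 / v_kmh


def speed_from_pace(pace_s_per_km: float) -> float:
    """Pace in seconds per km -> speed in km/h."""
    if pace_s_per_km <= 0:
        raise ValueError("pace must be > 0")
    return 3600.0 / pace_s_per_km
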