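"""Impact-peak segmentation and bout-level gait loading metrics.

The analysis chain is: 3-D vector magnitude -> adaptive peak detection per
sensor site -> 15 s margin trimming -> cadence (union of left/right tibial
events), mean peak tibial acceleration per leg, signed/absolute lateral
asymmetry and residual shock at the sacrum.

All accelerations are in g (1 g = 9.80665 m s^-2). Asymmetry and residual
shock are dimensionless fractions internally; reports render them as
percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

G_MS2 = 9.80665

L_TIBIA = "L_TIBIA"
R_TIBIA = "R_TIBIA"
SACRUM = "SACRUM"
SITES = (L_TIBIA, R_TIBIA, SACRUM)

#: default margin discarded at both ends of every bout, seconds
DEFAULT_MARGIN_S = 15.0


@dataclass(frozen=True)
class TriaxialStream:
    """Time-indexed 3-axis acceleration series for one sensor site.

    Parameters
    ----------
    t : array of sample times in seconds, strictly increasing
    ax, ay, az : per-axis acceleration in g
    fs_hz : nominal sampling rate
    site : one of ``L_TIBIA``, ``R_TIBIA``, ``SACRUM``
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs_hz: float
    site: str

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"channel {name} has length {len(getattr(self, name))}, "
                    f"expected {n} to match t"
                )
        if n == 0:
            raise ValueError("stream is empty")
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be > 0, got {self.fs_hz}")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "ax_g": self.ax, "ay_g": self.ay, "az_g": self.az}
        )


@dataclass(frozen=True)
class BoutRecording:
    """Three synchronized streams plus condition metadata for one bout."""

    streams: Mapping[str, TriaxialStream]
    duration_s: float
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {site: len(s) for site, s in self.streams.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"streams are not synchronized: lengths {lengths}")

    def stream(self, site: str) -> TriaxialStream:
        try:
            return self.streams[site]
        except KeyError:
            raise ValueError(f"recording is missing the {site} stream") from None


@dataclass(frozen=True)
class StepEvent:
    """A single detected impact peak."""

    time_s: float
    site: str
    peak_magnitude_g: float

    def __post_init__(self) -> None:
        if self.peak_magnitude_g <= 0:
            raise ValueError("peak_magnitude_g must be > 0")


@dataclass(frozen=True)
class PeakPolicy:
    """Detection policy for impact peaks on the magnitude series.

    The threshold is adaptive: median + ``mad_multiplier`` * MAD of the
    magnitude series.  Minimum inter-peak separation is site-specific: one
    stride per leg at tibial sites, one step at the sacrum.  The sacral
    multiplier is lower because sacral peaks are weaker, and the tight
    step-to-step spacing there geometrically suppresses noise candidates
    within the separation window.
    """

    mad_multiplier: float = 8.0
    mad_multiplier_sacrum: float = 4.0
    min_separation_tibia_s: float = 0.35
    min_separation_sacrum_s: float = 0.20
    margin_s: float = DEFAULT_MARGIN_S

    def __post_init__(self) -> None:
        if self.mad_multiplier < 0 or self.mad_multiplier_sacrum < 0:
            raise ValueError("mad_multiplier must be >= 0")
        if self.min_separation_tibia_s <= 0 or self.min_separation_sacrum_s <= 0:
            raise ValueError("minimum peak separations must be > 0")
        if self.margin_s < 0:
            raise ValueError("margin_s must be >= 0")

    def min_separation_s(self, site: str) -> float:
        if site == SACRUM:
            return self.min_separation_sacrum_s
        return self.min_separation_tibia_s

    def threshold_multiplier(self, site: str) -> float:
        return self.mad_multiplier_sacrum if site == SACRUM else self.mad_multiplier


@dataclass(frozen=True)
class BoutMetrics:
    """Per-bout loading metrics."""

    cad_spm: float
    pta_left_g: float
    pta_right_g: float
    sacral_peak_g: float
    la: float
    ala: float
    rsh: float
    n_steps: int
    effective_duration_s: float

    @property
    def pta_mean_g(self) -> float:
        return 0.5 * (self.pta_left_g + self.pta_right_g)

    def to_dict(self) -> dict:
        return {
            "cad_spm": self.cad_spm,
            "pta_left_g": self.pta_left_g,
            "pta_right_g": self.pta_right_g,
            "pta_mean_g": self.pta_mean_g,
            "sacral_peak_g": self.sacral_peak_g,
            "la": self.la,
            "ala": self.ala,
            "rsh": self.rsh,
            "n_steps": self.n_steps,
            "effective_duration_s": self.effective_duration_s,
        }


def vector_magnitude(stream: TriaxialStream) -> np.ndarray:
    """Elementwise 3-D Euclidean magnitude sqrt(ax^2 + ay^2 + az^2), in g."""
    return np.sqrt(stream.ax**2 + stream.ay**2 + stream.az**2)


def detect_impact_peaks(
    magnitude: np.ndarray,
    fs_hz: float,
    site: str,
    policy: PeakPolicy | None = None,
) -> list[StepEvent]:
    """Detect impact peaks in a magnitude series.

    Local maxima exceeding an adaptive threshold (median + k * MAD), with a
    site-specific minimum separation; ties within the separation window keep
    the larger magnitude.  A flat or sub-threshold series yields an empty
    list, not an error.
    """
    policy = policy or PeakPolicy()
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.ndim != 1 or len(magnitude) <= 2:
        raise ValueError("magnitude series must be 1-D with length > 2")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be > 0")

    med = float(np.median(magnitude))
    mad = float(np.median(np.abs(magnitude - med)))
    threshold = med + policy.threshold_multiplier(site) * mad
    distance = max(1, int(round(policy.min_separation_s(site) * fs_hz)))
    idx, props = find_peaks(magnitude, height=threshold, distance=distance)
    return [
        StepEvent(time_s=i / fs_hz, site=site, peak_magnitude_g=float(h))
        for i, h in zip(idx, props["peak_heights"])
    ]


def trim_margins(
    events: Sequence[StepEvent],
    bout_duration_s: float,
    margin_s: float = DEFAULT_MARGIN_S,
) -> list[StepEvent]:
    """Drop events inside the initialisation/finalisation margins.

    Retains events with ``margin_s <= t < bout_duration_s - margin_s`` (the
    window is half-open at the far end so that a perfectly regular step grid
    is counted exactly once per interval).
    """
    if bout_duration_s <= 2 * margin_s:
        raise ValueError(
            f"bout too short for margins: duration {bout_duration_s} s "
            f"<= 2 x {margin_s} s"
        )
    hi = bout_duration_s - margin_s
    return [e for e in events if margin_s <= e.time_s < hi]


def mean_peak_acceleration(events: Sequence[StepEvent]) -> float:
    """Arithmetic mean of event peak magnitudes, in g."""
    if len(events) == 0:
        raise ValueError("no steps detected")
    return float(np.mean([e.peak_magnitude_g for e in events]))


def compute_cadence(
    events_left: Sequence[StepEvent],
    events_right: Sequence[StepEvent],
    effective_duration_s: float,
) -> float:
    """Step frequency in steps per minute from the union of both legs."""
    if effective_duration_s <= 0:
        raise ValueError("effective_duration_s must be > 0")
    n = len(events_left) + len(events_right)
    if n == 0:
        raise ValueError("no steps detected")
    return n / effective_duration_s * 60.0


def lateral_asymmetry(a_left_g: float, a_right_g: float) -> tuple[float, float]:
    """Signed and absolute lateral asymmetry of the per-leg mean peaks.

    LA = (aL - aR) / ((aL + aR)/2); positive when the left leg loads harder.
    Returns ``(la, abs(la))``; ``la`` is bounded in (-2, 2) for positive
    inputs.
    """
    if a_left_g <= 0 or a_right_g <= 0:
        raise ValueError("per-leg mean peak accelerations must be > 0")
    la = (a_left_g - a_right_g) / (0.5 * (a_left_g + a_right_g))
    return la, abs(la)


def residual_shock(a_sacrum_g: float, a_left_g: float, a_right_g: float) -> float:
    """Sacral mean peak divided by the bilateral tibial mean peak.

    1 - RSh is the shock attenuation when expressed in percentage points.
    """
    if a_sacrum_g <= 0 or a_left_g <= 0 or a_right_g <= 0:
        raise ValueError("mean peak accelerations must be > 0")
    return a_sacrum_g / (0.5 * (a_left_g + a_right_g))


def analyse_bout(
    recording: BoutRecording, policy: PeakPolicy | None = None
) -> BoutMetrics:
    """Full per-bout analysis: peaks -> trim -> CAD, PTA, LA/aLA, RSh."""
    policy = policy or PeakPolicy()
    duration = recording.duration_s
    if duration <= 2 * policy.margin_s:
        raise ValueError(
            f"bout duration {duration} s too short for {policy.margin_s} s margins"
        )

    trimmed: dict[str, list[StepEvent]] = {}
    for site in SITES:
        stream = recording.stream(site)
        mag = vector_magnitude(stream)
        try:
            events = detect_impact_peaks(mag, stream.fs_hz, site, policy)
            trimmed[site] = trim_margins(events, duration, policy.margin_s)
        except ValueError as exc:
            raise ValueError(f"{site}: {exc}") from exc
        if not trimmed[site]:
            raise ValueError(f"{site}: no steps detected")

    effective = duration - 2 * policy.margin_s
    left, right, sac = trimmed[L_TIBIA], trimmed[R_TIBIA], trimmed[SACRUM]

    cad = compute_cadence(left, right, effective)
    sacral_cad = len(sac) / effective * 60.0
    if abs(sacral_cad - cad) > 0.02 * cad:
        logger.warning(
            "sacral cadence cross-check deviates: tibial %.1f vs sacral %.1f spm",
            cad,
            sacral_cad,
        )

    a_l = mean_peak_acceleration(left)
    a_r = mean_peak_acceleration(right)
    a_sac = mean_peak_acceleration(sac)
    la, ala = lateral_asymmetry(a_l, a_r)
    rsh = residual_shock(a_sac, a_l, a_r)

    return BoutMetrics(
        cad_spm=cad,
        pta_left_g=a_l,
        pta_right_g=a_r,
        sacral_peak_g=a_sac,
        la=la,
        ala=ala,
        rsh=rsh,
        n_steps=len(left) + len(right),
        effective_duration_s=effective,
    )


# ---------------------------------------------------------------------------
# CSV interchange


def write_stream_csv(stream: TriaxialStream, path) -> None:
    """Write one sensor stream as CSV with columns t_s, ax_g, ay_g, az_g."""
    with open(path, "w") as fh:
        fh.write(f"# runload stream v1 site={stream.site} fs_hz={stream.fs_hz}\n")
        stream.to_frame().to_csv(fh, index=False)


def read_stream_csv(path, site: str | None = None, fs_hz: float | None = None) -> TriaxialStream:
    """Read a stream CSV written by :func:`write_stream_csv`."""
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#"):
            for tok in header.split():
                if tok.startswith("site=") and site is None:
                    site = tok.split("=", 1)[1]
                if tok.startswith("fs_hz=") and fs_hz is None:
                    fs_hz = float(tok.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
    if site is None or fs_hz is None:
        raise ValueError("site and fs_hz must be given or present in the header")
    return TriaxialStream(
        t=df["t_s"].to_numpy(),
        ax=df["ax_g"].to_numpy(),
        ay=df["ay_g"].to_numpy(),
        az=df["az_g"].to_numpy(),
        fs_hz=fs_hz,
        site=site,
    )


METRICS_COLUMNS = [
    "subject",
    "elevation_m",
    "speed_level",
    "surface",
    "cad_spm",
    "pta_left_g",
    "pta_right_g",
    "pta_mean_g",
    "sacral_peak_g",
    "la",
    "ala",
    "rsh",
    "n_steps",
]


def metrics_to_row(meta: Mapping[str, object], metrics: BoutMetrics) -> dict:
    row = {k: meta.get(k) for k in ("subject", "elevation_m", "speed_level", "surface")}
    row.update({k: v for k, v in metrics.to_dict().items() if k in METRICS_COLUMNS})
    return row


def write_metrics_csv(rows: Iterable[Mapping[str, object]], path) -> None:
    df = pd.DataFrame(list(rows))[METRICS_COLUMNS]
    with open(path, "w") as fh:
        fh.write("# runload metrics v1\n")
        df.to_csv(fh, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
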