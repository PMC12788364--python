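"""Synthetic tri-axial IMU signal generation for running bouts and cohorts.

A bout is modelled as an alternating left/right train of impact transients
riding on a 1 g gravity baseline, sampled at 120 Hz at three sites (both
distal tibiae and the sacrum).  Step timing encodes cadence, per-leg peak
amplitudes encode peak tibial acceleration and lateral asymmetry, and the
sacral amplitude encodes residual shock.  With all variability sources set
to zero the programmed values are embedded exactly and the analysis stage
recovers them to discretization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from runload import reference
from runload.gait import (
    L_TIBIA,
    R_TIBIA,
    SACRUM,
    BoutRecording,
    TriaxialStream,
    read_stream_csv,
    write_stream_csv,
)
from runload.prescription import adjust_speed, speed_zones

ELEVATIONS_M = reference.ELEVATIONS_M
SPEED_LEVELS = reference.SPEED_LEVELS
SURFACES = reference.SURFACES

#: all 18 condition cells in canonical order
CELLS = tuple(
    (e, v, s) for e in ELEVATIONS_M for v in SPEED_LEVELS for s in SURFACES
)


@dataclass(frozen=True)
class TransientShape:
    """Shape of a single impact transient: damped sinusoid, normalised so
    its sampled maximum equals the programmed amplitude exactly."""

    center_freq_hz: float = 12.0
    decay_s: float = 0.025
    # <= half the minimum combined step interval at 240 spm (0.125 s)
    duration_s: float = 0.125


@dataclass(frozen=True)
class BoutSimParams:
    """Programmed ground truth for one synthetic bout."""

    cadence_spm: float
    pta_target_g: float
    la_target: float = 0.0
    rsh_target: float = 0.5
    duration_s: float = 300.0
    fs_hz: float = 120.0
    amp_cv: float = 0.0
    timing_jitter_cv: float = 0.0
    noise_sd_g: float = 0.0
    seed: int | None = None
    transient: TransientShape = field(default_factory=TransientShape)

    def validate(self) -> None:
        if self.cadence_spm <= 0:
            raise ValueError(f"cadence_spm must be > 0, got {self.cadence_spm}")
        if self.pta_target_g <= 0:
            raise ValueError(f"pta_target_g must be > 0, got {self.pta_target_g}")
        if abs(self.la_target) >= 2:
            raise ValueError(f"la_target must satisfy |la| < 2, got {self.la_target}")
        if self.rsh_target <= 0:
            raise ValueError(f"rsh_target must be > 0, got {self.rsh_target}")
        if self.duration_s <= 30:
            raise ValueError(
                f"duration_s must exceed 30 s (two 15 s margins), got {self.duration_s}"
            )
        if self.fs_hz <= 2 * self.transient.center_freq_hz:
            raise ValueError(
                f"fs_hz must exceed twice the transient centre frequency "
                f"({2 * self.transient.center_freq_hz} Hz), got {self.fs_hz}"
            )
        if self.amp_cv < 0 or self.timing_jitter_cv < 0 or self.noise_sd_g < 0:
            raise ValueError("amp_cv, timing_jitter_cv and noise_sd_g must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject random effects and threshold speeds.

    Offsets shift every condition-cell mean for that subject; ``la_sign``
    fixes which leg loads harder (asymmetry as a stable individual trait).
    The sensitivity coefficients document the subject's expected response
    per km/h and per 1000 m; the calibrated cohort path encodes these in the
    calibration table instead.
    """

    subject_id: str
    vVT1_kmh: float
    vVT2_kmh: float
    cad_offset_spm: float = 0.0
    pta_offset_g: float = 0.0
    ala_offset: float = 0.0
    rsh_offset: float = 0.0
    la_sign: int = 1
    cad_per_kmh: float = 2.2
    pta_per_kmh: float = 0.9
    cad_per_km_elev: float = -1.0
    pta_per_km_elev: float = -0.27

    def __post_init__(self) -> None:
        if not 0 < self.vVT1_kmh < self.vVT2_kmh:
            raise ValueError(
                f"{self.subject_id}: need 0 < vVT1 < vVT2, "
                f"got vVT1={self.vVT1_kmh}, vVT2={self.vVT2_kmh}"
            )
        if self.la_sign not in (-1, 1):
            raise ValueError("la_sign must be +1 or -1")


@dataclass(frozen=True)
class CellTargets:
    """Target mean and between-subject SD per metric for one design cell."""

    cad_mean: float
    cad_sd: float
    pta_mean: float
    pta_sd: float
    ala_mean: float
    ala_sd: float
    rsh_mean: float
    rsh_sd: float

    def validate(self, key) -> None:
        for name in ("cad_sd", "pta_sd", "ala_sd", "rsh_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {key}: {name} must be >= 0")
        for name in ("cad_mean", "pta_mean", "rsh_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell {key}: {name} must be > 0")


@dataclass(frozen=True)
class CohortCalibration:
    """Per-cell target means/SDs for CAD, PTA, aLA and RSh over the full
    3 elevations x 3 speeds x 2 surfaces design."""

    cells: dict[tuple[int, str, str], CellTargets]

    def validate(self) -> None:
        missing = [key for key in CELLS if key not in self.cells]
        if missing:
            raise ValueError(f"calibration is missing cells: {missing}")
        for key in CELLS:
            self.cells[key].validate(key)

    @classmethod
    def default(cls) -> "CohortCalibration":
        """Additive cell model from the default group-summary targets:
        cell mean = speed-level marginal + centred elevation offset; surface
        adds no mean shift."""
        cad_off = reference.centred_offsets(reference.CAD_ELEVATION_MEANS)
        pta_off = reference.centred_offsets(reference.PTA_ELEVATION_MEANS)
        ala_off = reference.centred_offsets(reference.ALA_ELEVATION_MEANS)
        rsh_off = reference.centred_offsets(reference.RSH_ELEVATION_MEANS)
        cells = {}
        for e, v, s in CELLS:
            cells[(e, v, s)] = CellTargets(
                cad_mean=reference.CAD_SPEED_MEANS[v] + cad_off[e],
                cad_sd=reference.CAD_SPEED_SDS[v],
                pta_mean=reference.PTA_SPEED_MEANS[v] + pta_off[e],
                pta_sd=reference.PTA_SPEED_SDS[v],
                ala_mean=reference.ALA_SPEED_MEANS[v] + ala_off[e],
                ala_sd=reference.ALA_SPEED_SDS[v],
                rsh_mean=reference.RSH_SPEED_MEANS[v] + rsh_off[e],
                rsh_sd=reference.RSH_SPEED_SDS[v],
            )
        return cls(cells=cells)


@dataclass(frozen=True)
class CohortNoise:
    """Variability sources for cohort simulation.

    Within-subject SDs perturb the programmed bout-level truth; signal-level
    settings (amplitude CV, timing jitter, additive noise) perturb the raw
    streams.  Trail bouts scale amplitude CV and timing jitter by
    ``trail_variability_factor`` instead of shifting means.
    """

    amp_cv: float = 0.05
    timing_jitter_cv: float = 0.03
    noise_sd_g: float = 0.1
    trail_variability_factor: float = 1.5
    within_cad_spm: float = 0.7
    within_pta_g: float = 0.3
    within_ala: float = 0.015
    within_rsh: float = 0.02

    @classmethod
    def silent(cls) -> "CohortNoise":
        return cls(0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Signal primitives


def simulate_step_train(
    cadence_spm: float,
    duration_s: float,
    timing_jitter_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating-leg step event times for one bout.

    Returns ``(times_s, sides)`` with sides alternating ``'L', 'R', ...``.
    With zero jitter the events sit on an exact grid of 60/cadence seconds;
    jitter perturbs each inter-step interval multiplicatively with the given
    coefficient of variation.
    """
    if cadence_spm <= 0:
        raise ValueError(f"cadence_spm must be > 0, got {cadence_spm}")
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    if timing_jitter_cv < 0:
        raise ValueError("timing_jitter_cv must be >= 0")

    step = 60.0 / cadence_spm
    if timing_jitter_cv == 0:
        n = int(np.ceil(duration_s / step))
        times = np.arange(n) * step
        times = times[times < duration_s]
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n_max = int(np.ceil(duration_s / step)) + 64
        intervals = step * np.clip(
            rng.normal(1.0, timing_jitter_cv, n_max), 0.1, None
        )
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        times = times[times < duration_s]
    sides = np.where(np.arange(len(times)) % 2 == 0, "L", "R")
    return times, sides


def impact_transient(
    amplitude_g: float,
    fs_hz: float = 120.0,
    shape: TransientShape | None = None,
) -> np.ndarray:
    """A single impact transient sampled at ``fs_hz``.

    Damped sinusoid (exponential decay x sine), renormalised so the sampled
    maximum equals ``amplitude_g`` exactly; decays below 5% of the peak by
    the end of the segment.
    """
    if amplitude_g <= 0:
        raise ValueError(f"amplitude_g must be > 0, got {amplitude_g}")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be > 0")
    shape = shape or TransientShape()
    t = np.arange(int(round(shape.duration_s * fs_hz))) / fs_hz
    w = np.exp(-t / shape.decay_s) * np.sin(2 * np.pi * shape.center_freq_hz * t)
    peak = w.max()
    if peak <= 0:
        raise ValueError("transient shape yields no positive peak at this fs")
    return amplitude_g * w / peak


def _place_transients(
    n_samples: int,
    fs_hz: float,
    times: np.ndarray,
    amplitudes: np.ndarray,
    unit_wave: np.ndarray,
) -> np.ndarray:
    """Axial channel: 1 g gravity baseline + (A - 1) * unit transient per
    event, so the magnitude peaks at exactly A."""
    az = np.ones(n_samples)
    lw = len(unit_wave)
    for t_ev, amp in zip(times, amplitudes):
        i0 = int(round(t_ev * fs_hz))
        if i0 >= n_samples:
            continue
        seg = unit_wave[: n_samples - i0]
        az[i0 : i0 + len(seg)] += (amp - 1.0) * seg
    return az


def simulate_bout(params: BoutSimParams) -> BoutRecording:
    """Generate the three synchronized streams for one bout.

    Left/right per-step amplitude means invert the asymmetry index:
    aL = PTA (1 + LA/2), aR = PTA (1 - LA/2); the sacral amplitude mean is
    RSh x PTA.  Per-step amplitudes vary with ``amp_cv``; white Gaussian
    noise of ``noise_sd_g`` is added per axis.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.fs_hz
    n = int(round(params.duration_s * fs))

    times, sides = simulate_step_train(
        params.cadence_spm, params.duration_s, params.timing_jitter_cv, rng
    )
    left_mask = sides == "L"

    a_left = params.pta_target_g * (1.0 + params.la_target / 2.0)
    a_right = params.pta_target_g * (1.0 - params.la_target / 2.0)
    a_sac = params.rsh_target * params.pta_target_g

    def draw_amps(mean: float, count: int) -> np.ndarray:
        if params.amp_cv == 0:
            return np.full(count, mean)
        # keep amplitudes above the gravity baseline
        return np.clip(
            mean * rng.normal(1.0, params.amp_cv, count), max(1.05, 0.3 * mean), None
        )

    wave = impact_transient(1.0, fs, params.transient)
    t_axis = np.arange(n) / fs
    streams = {}
    for site, ev_times, mean in (
        (L_TIBIA, times[left_mask], a_left),
        (R_TIBIA, times[~left_mask], a_right),
        (SACRUM, times, a_sac),
    ):
        amps = draw_amps(mean, len(ev_times))
        az = _place_transients(n, fs, ev_times, amps, wave)
        ax = np.zeros(n)
        ay = np.zeros(n)
        if params.noise_sd_g > 0:
            az = az + rng.normal(0.0, params.noise_sd_g, n)
            ax = rng.normal(0.0, params.noise_sd_g, n)
            ay = rng.normal(0.0, params.noise_sd_g, n)
        streams[site] = TriaxialStream(
            t=t_axis, ax=ax, ay=ay, az=az, fs_hz=fs, site=site
        )

    meta = {
        "cadence_spm": params.cadence_spm,
        "pta_target_g": params.pta_target_g,
        "la_target": params.la_target,
        "rsh_target": params.rsh_target,
        "duration_s": params.duration_s,
        "fs_hz": fs,
        "seed": params.seed,
    }
    return BoutRecording(streams=streams, duration_s=params.duration_s, meta=meta)


# ---------------------------------------------------------------------------
# Cohort generation


def generate_profiles(
    n_subjects: int,
    seed: int | None = None,
    balanced: bool = True,
) -> list[SubjectProfile]:
    """Draw subject profiles from the default cohort distribution.

    With ``balanced=True`` (default) the per-metric random offsets are
    centred to a zero sample mean, so programmed cell means equal the
    calibration targets exactly for any cohort size.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)

    vvt1 = rng.normal(reference.VVT1_MEAN_KMH, reference.VVT1_SD_KMH, n_subjects)
    vvt2 = rng.normal(reference.VVT2_MEAN_KMH, reference.VVT2_SD_KMH, n_subjects)
    vvt1 = np.clip(vvt1, 7.0, None)
    vvt2 = np.maximum(vvt2, vvt1 + 1.0)

    def offsets(sd: float) -> np.ndarray:
        z = rng.normal(0.0, 1.0, n_subjects)
        if balanced:
            z = z - z.mean()
        return sd * z

    cad = offsets(float(np.mean(list(reference.CAD_SPEED_SDS.values()))))
    pta = offsets(float(np.mean(list(reference.PTA_SPEED_SDS.values()))))
    ala = offsets(float(np.mean(list(reference.ALA_SPEED_SDS.values()))))
    rsh = offsets(float(np.mean(list(reference.RSH_SPEED_SDS.values()))))
    signs = rng.choice([-1, 1], n_subjects)

    return [
        SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            vVT1_kmh=float(vvt1[i]),
            vVT2_kmh=float(vvt2[i]),
            cad_offset_spm=float(cad[i]),
            pta_offset_g=float(pta[i]),
            ala_offset=float(ala[i]),
            rsh_offset=float(rsh[i]),
            la_sign=int(signs[i]),
        )
        for i in range(n_subjects)
    ]


DESIGN_COLUMNS = [
    "subject",
    "elevation_m",
    "speed_level",
    "surface",
    "v_sea_level_kmh",
    "v_prescribed_kmh",
    "programmed_cad_spm",
    "programmed_pta_g",
    "programmed_la",
    "programmed_rsh",
    "bout_seed",
]


def simulate_cohort(
    profiles: list[SubjectProfile],
    calibration: CohortCalibration | None = None,
    seed: int | None = None,
    noise: CohortNoise | None = None,
    bout_duration_s: float = 300.0,
    fs_hz: float = 120.0,
) -> tuple[list[BoutRecording], pd.DataFrame]:
    """Simulate the full crossed design: 18 bouts per subject.

    Returns the bout recordings (subject-major, cells in canonical order)
    and a design table recording conditions, prescribed speeds and the
    programmed ground truth per bout.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 subjects")
    calibration = calibration or CohortCalibration.default()
    calibration.validate()
    noise = noise or CohortNoise()
    rng = np.random.default_rng(seed)

    recordings: list[BoutRecording] = []
    rows = []
    for prof in profiles:
        zones = speed_zones(prof.vVT1_kmh, prof.vVT2_kmh)
        for elevation, level, surface in CELLS:
            cell = calibration.cells[(elevation, level, surface)]
            cad = cell.cad_mean + prof.cad_offset_spm + rng.normal(0, noise.within_cad_spm)
            pta = cell.pta_mean + prof.pta_offset_g + rng.normal(0, noise.within_pta_g)
            ala = cell.ala_mean + prof.ala_offset + rng.normal(0, noise.within_ala)
            rsh = cell.rsh_mean + prof.rsh_offset + rng.normal(0, noise.within_rsh)
            cad = max(cad, 60.0)
            pta = max(pta, 2.0)
            ala = float(np.clip(ala, 0.002, 1.9))
            # physiological floor; also keeps sacral peaks well above noise
            rsh = float(np.clip(rsh, 0.2, 1.9))
            la = prof.la_sign * ala

            trail = surface == "TRAIL"
            factor = noise.trail_variability_factor if trail else 1.0
            bout_seed = int(rng.integers(0, 2**31 - 1))
            params = BoutSimParams(
                cadence_spm=float(cad),
                pta_target_g=float(pta),
                la_target=float(la),
                rsh_target=float(rsh),
                duration_s=bout_duration_s,
                fs_hz=fs_hz,
                amp_cv=noise.amp_cv * factor,
                timing_jitter_cv=noise.timing_jitter_cv * factor,
                noise_sd_g=noise.noise_sd_g,
                seed=bout_seed,
            )
            rec = simulate_bout(params)
            v_sea = zones.speed(level)
            v_adj = adjust_speed(v_sea, elevation)
            meta = dict(rec.meta)
            meta.update(
                subject=prof.subject_id,
                elevation_m=elevation,
                speed_level=level,
                surface=surface,
                v_sea_level_kmh=v_sea,
                v_prescribed_kmh=v_adj,
            )
            recordings.append(replace(rec, meta=meta))
            rows.append(
                {
                    "subject": prof.subject_id,
                    "elevation_m": elevation,
                    "speed_level": level,
                    "surface": surface,
                    "v_sea_level_kmh": v_sea,
                    "v_prescribed_kmh": v_adj,
                    "programmed_cad_spm": float(cad),
                    "programmed_pta_g": float(pta),
                    "programmed_la": float(la),
                    "programmed_rsh": float(rsh),
                    "bout_seed": bout_seed,
                }
            )
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    return recordings, design


# ---------------------------------------------------------------------------
# Disk interchange


def write_bout(recording: BoutRecording, directory, stem: str) -> None:
    """Write the three stream CSVs plus a JSON sidecar of the metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for site, stream in recording.streams.items():
        write_stream_csv(stream, directory / f"{stem}_{site}.csv")
    sidecar = {"duration_s": recording.duration_s, **dict(recording.meta)}
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))


def read_bout(directory, stem: str) -> BoutRecording:
    """Read a bout previously written by :func:`write_bout`."""
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    streams = {
        site: read_stream_csv(directory / f"{stem}_{site}.csv")
        for site in (L_TIBIA, R_TIBIA, SACRUM)
    }
    return BoutRecording(
        streams=streams, duration_s=float(meta["duration_s"]), meta=meta
    )
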