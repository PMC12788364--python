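"""End-to-end synthetic study: cohort generation -> bout analysis ->
cell summaries -> repeated-measures statistics, with all artifacts on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from runload import gait, stats, synthetic

logger = logging.getLogger(__name__)

SUMMARY_METRICS = ("cad_spm", "pta_mean_g", "ala", "rsh")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration for a full synthetic study run."""

    n_subjects: int = 10
    seed: int = 0
    out_dir: str | Path = "study_out"
    bout_duration_s: float = 300.0
    fs_hz: float = 120.0
    noise: synthetic.CohortNoise = field(default_factory=synthetic.CohortNoise)
    calibration: synthetic.CohortCalibration | None = None
    run_stats: bool = True
    write_streams: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")


@dataclass(frozen=True)
class StudyResult:
    design: pd.DataFrame
    metrics: pd.DataFrame
    cell_summary: pd.DataFrame
    effects: dict[str, pd.DataFrame]
    out_dir: Path


def analyse_recordings(
    recordings, policy: gait.PeakPolicy | None = None
) -> pd.DataFrame:
    """Analyse a list of bout recordings into a long metrics table."""
    rows = []
    for rec in recordings:
        meta = dict(rec.meta)
        try:
            metrics = gait.analyse_bout(rec, policy)
        except ValueError as exc:
            raise ValueError(
                f"analysis failed for subject {meta.get('subject')} cell "
                f"({meta.get('elevation_m')}, {meta.get('speed_level')}, "
                f"{meta.get('surface')}): {exc}"
            ) from exc
        logger.info(
            "analysed bout subject=%s cell=(%s,%s,%s) n_steps=%d cad=%.1f",
            meta.get("subject"),
            meta.get("elevation_m"),
            meta.get("speed_level"),
            meta.get("surface"),
            metrics.n_steps,
            metrics.cad_spm,
        )
        rows.append(gait.metrics_to_row(meta, metrics))
    return pd.DataFrame(rows, columns=gait.METRICS_COLUMNS)


def summarise_cells(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and SD of each metric over subjects."""
    if metrics.empty:
        raise ValueError("metrics table is empty")
    grouped = metrics.groupby(
        ["elevation_m", "speed_level", "surface"], observed=True
    )[list(SUMMARY_METRICS)]
    summary = grouped.agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    # a single-subject cell has no between-subject spread
    std_cols = [c for c in summary.columns if c.endswith("_std")]
    summary[std_cols] = summary[std_cols].fillna(0.0)
    return summary.reset_index()


def marginal_summary(metrics: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Mean and SD of each metric per level of a single factor.

    The SD is over per-subject level means (between-subject spread), which
    is the convention of the group-summary targets.
    """
    per_subject = (
        metrics.groupby(["subject", factor], observed=True)[list(SUMMARY_METRICS)]
        .mean()
        .reset_index()
    )
    grouped = per_subject.groupby(factor, observed=True)[list(SUMMARY_METRICS)]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


def run_study(config: StudyConfig) -> StudyResult:
    """Run the complete pipeline and write CSV artifacts.

    Writes design.csv, metrics.csv, cell_summary.csv, the per-factor
    marginal summaries, and (when statistics are enabled) one effects table
    and one post hoc table per metric.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    profiles = synthetic.generate_profiles(config.n_subjects, seed=config.seed)
    recordings, design = synthetic.simulate_cohort(
        profiles,
        calibration=config.calibration,
        seed=config.seed,
        noise=config.noise,
        bout_duration_s=config.bout_duration_s,
        fs_hz=config.fs_hz,
    )
    _write_csv(design, out / "design.csv", "design")

    if config.write_streams:
        for rec in recordings:
            meta = rec.meta
            stem = (
                f"{meta['subject']}_{meta['elevation_m']}m_"
                f"{meta['speed_level']}_{meta['surface']}"
            )
            synthetic.write_bout(rec, out / "streams", stem)

    metrics = analyse_recordings(recordings)
    gait.write_metrics_csv(metrics.to_dict("records"), out / "metrics.csv")

    summary = summarise_cells(metrics)
    _write_csv(summary, out / "cell_summary.csv", "cell_summary")
    for factor in ("elevation_m", "speed_level", "surface"):
        _write_csv(
            marginal_summary(metrics, factor),
            out / f"marginal_{factor}.csv",
            f"marginal_{factor}",
        )

    effects_tables: dict[str, pd.DataFrame] = {}
    if config.run_stats:
        if config.n_subjects < 3:
            raise ValueError(
                "insufficient subjects for rmANOVA (need >= 3); "
                "metrics were still written"
            )
        for metric in SUMMARY_METRICS:
            effects = stats.rm_anova_3way(metrics, metric)
            eff_df = stats.anova_effects_frame(effects)
            _write_csv(eff_df, out / f"effects_{metric}.csv", f"effects_{metric}")
            posthoc = stats.pairwise_posthoc(metrics, metric, "speed_level")
            _write_csv(
                stats.posthoc_frame(posthoc),
                out / f"posthoc_speed_{metric}.csv",
                f"posthoc_{metric}",
            )
            effects_tables[metric] = eff_df

    return StudyResult(
        design=design,
        metrics=metrics,
        cell_summary=summary,
        effects=effects_tables,
        out_dir=out,
    )


def _write_csv(df: pd.DataFrame, path: Path, kind: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# runload {kind} v1\n")
        df.to_csv(fh, index=False)
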