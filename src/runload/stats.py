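"""Three-way within-subject ANOVA and companion statistics.

Univariate repeated-measures decomposition on a balanced subject x A x B x C
table: every effect (3 mains, 3 two-way, 1 three-way interaction) is tested
against its own subject-by-effect error term.  Sphericity is assessed per
effect (Mauchly) and degrees of freedom are rescaled with the
Greenhouse-Geisser epsilon when sphericity is rejected.  Post hoc paired
comparisons use Bonferroni adjustment and Cohen's d; effect sizes in the
ANOVA are partial eta squared with Cohen's rating bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "RmAnovaEffect",
    "PostHocComparison",
    "rm_anova_3way",
    "greenhouse_geisser_epsilon",
    "mauchly_sphericity",
    "shapiro_wilk",
    "bonferroni_adjust",
    "cohens_d_paired",
    "cohens_d_av",
    "partial_eta_squared",
    "condition_slopes",
    "pairwise_posthoc",
    "rate_cohens_d",
    "rate_partial_eta_sq",
]

DEFAULT_FACTORS = ("elevation_m", "speed_level", "surface")


def rate_cohens_d(d: float) -> str:
    """Cohen's rating bands for d: 0.2 / 0.5 / 0.8."""
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def rate_partial_eta_sq(v: float) -> str:
    """Cohen's rating bands for partial eta squared: 0.01 / 0.06 / 0.14."""
    if v < 0.01:
        return "negligible"
    if v < 0.06:
        return "small"
    if v < 0.14:
        return "medium"
    return "large"


@dataclass(frozen=True)
class RmAnovaEffect:
    """One tested effect of the within-subject ANOVA."""

    effect: str
    F: float
    df_num: float
    df_den: float
    gg_epsilon: float
    mauchly_w: float
    mauchly_p: float
    p_uncorrected: float
    p_gg: float
    p: float  #: reported p: GG-corrected when Mauchly rejects sphericity
    partial_eta_sq: float
    rating: str

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "gg_epsilon": self.gg_epsilon,
            "mauchly_w": self.mauchly_w,
            "mauchly_p": self.mauchly_p,
            "p_uncorrected": self.p_uncorrected,
            "p_gg": self.p_gg,
            "p": self.p,
            "partial_eta_sq": self.partial_eta_sq,
            "rating": self.rating,
        }


@dataclass(frozen=True)
class PostHocComparison:
    """One Bonferroni-adjusted paired comparison."""

    level_a: object
    level_b: object
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    p_raw: float
    p_bonferroni: float
    cohens_dz: float
    cohens_d_av: float
    rating: str


# ---------------------------------------------------------------------------
# Core decomposition


def _balanced_cube(
    table: pd.DataFrame,
    outcome: str,
    subject: str,
    factors: Sequence[str],
) -> tuple[np.ndarray, list[list], list]:
    """Pivot a long table into a dense subject x levels... array, enforcing a
    complete balanced within-subject design."""
    levels = [sorted(table[f].unique()) for f in factors]
    subjects = sorted(table[subject].unique())
    counts = table.groupby([subject, *factors], observed=True)[outcome].count()
    expected = int(np.prod([len(lv) for lv in levels]))
    bad = []
    for s in subjects:
        got = counts.loc[s].sum() if s in counts.index.get_level_values(0) else 0
        if got != expected or (counts.loc[s] != 1).any():
            bad.append(s)
    if bad:
        raise ValueError(
            f"design is not balanced/complete for subjects: {bad} "
            f"(need exactly one observation in each of {expected} cells)"
        )
    pivot = table.pivot_table(
        index=subject, columns=list(factors), values=outcome, observed=True
    )
    # canonical cell order: product of sorted factor levels
    order = pd.MultiIndex.from_product(levels, names=list(factors))
    pivot = pivot.reindex(index=subjects, columns=order)
    cube = pivot.to_numpy().reshape(len(subjects), *[len(lv) for lv in levels])
    return cube, levels, subjects


def _project(y: np.ndarray, subset: tuple[int, ...]) -> np.ndarray:
    """Tensor ANOVA projection: centre along axes in ``subset``, average
    along all the others (grand-mean axis conventions; full shape kept)."""
    out = y
    for axis in range(y.ndim):
        mean = out.mean(axis=axis, keepdims=True)
        out = (out - mean) if axis in subset else np.broadcast_to(
            mean, out.shape
        ).copy()
    return out


def _effect_contrast(levels: list[list], subset: tuple[int, ...]) -> np.ndarray:
    """Orthonormal contrast matrix over the flattened cells for the given
    effect (Kronecker of Helmert blocks and averaging rows)."""
    mat = np.ones((1, 1))
    for axis, lv in enumerate(levels):
        k = len(lv)
        block = helmert(k) if axis in subset else np.full((1, k), 1.0 / np.sqrt(k))
        mat = np.kron(mat, block)
    return mat


def _gg_from_scores(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from per-subject orthonormal contrast
    scores (n x d)."""
    d = scores.shape[1]
    if d == 1:
        return 1.0
    s = np.cov(scores, rowvar=False)
    tr = np.trace(s)
    denom = d * np.sum(s * s)
    if denom <= 0:
        raise ValueError("degenerate covariance: cannot estimate epsilon")
    return float(min(1.0, tr * tr / denom))


def _mauchly_from_scores(scores: np.ndarray) -> tuple[float, float]:
    """Mauchly's W and its chi-square p from contrast scores (n x d)."""
    n, d = scores.shape
    if d == 1:
        return 1.0, 1.0
    if n - 1 < d:
        return float("nan"), float("nan")
    s = np.cov(scores, rowvar=False)
    tr = np.trace(s)
    if tr <= 0:
        raise ValueError("degenerate covariance: cannot run Mauchly test")
    det = float(np.linalg.det(s))
    w = det / (tr / d) ** d
    w = float(np.clip(w, np.finfo(float).tiny, 1.0))
    nr = n - 1
    correction = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * nr)
    chi2 = -nr * correction * np.log(w)
    df = d * (d + 1) // 2 - 1
    return w, float(sps.chi2.sf(chi2, df))


def rm_anova_3way(
    table: pd.DataFrame,
    outcome: str,
    subject: str = "subject",
    factors: Sequence[str] = DEFAULT_FACTORS,
) -> list[RmAnovaEffect]:
    """Three-way repeated-measures ANOVA on a balanced long table.

    Returns the 7 effects (mains, two-way and three-way interactions), each
    with F, degrees of freedom, Greenhouse-Geisser epsilon, uncorrected and
    GG-corrected p, Mauchly test and partial eta squared.
    """
    if len(factors) != 3:
        raise ValueError("exactly three within-subject factors are required")
    cube, levels, subjects = _balanced_cube(table, outcome, subject, factors)
    n = len(subjects)
    if n < 3:
        raise ValueError(f"insufficient subjects for rmANOVA: {n} < 3")

    cells = cube.reshape(n, -1)
    effects: list[RmAnovaEffect] = []
    # factor axes in the cube are 1..3 (axis 0 is subject)
    for r in (1, 2, 3):
        for combo in combinations((1, 2, 3), r):
            name = " x ".join(factors[a - 1] for a in combo)
            ss_eff = float(np.sum(_project(cube, combo) ** 2))
            ss_err = float(np.sum(_project(cube, (0, *combo)) ** 2))
            df_num = int(np.prod([len(levels[a - 1]) - 1 for a in combo]))
            df_den = df_num * (n - 1)
            ms_eff = ss_eff / df_num
            ms_err = ss_err / df_den
            if ms_err <= 0:
                raise ValueError(f"zero error variance for effect {name}")
            f_stat = ms_eff / ms_err

            contrast = _effect_contrast(levels, tuple(a - 1 for a in combo))
            scores = cells @ contrast.T
            eps = _gg_from_scores(scores)
            w, w_p = _mauchly_from_scores(scores)

            p_unc = float(sps.f.sf(f_stat, df_num, df_den))
            p_gg = float(sps.f.sf(f_stat, df_num * eps, df_den * eps))
            p_rep = p_gg if (not np.isnan(w_p) and w_p < 0.05) else p_unc
            eta, rating = partial_eta_squared(ss_eff, ss_err)
            effects.append(
                RmAnovaEffect(
                    effect=name,
                    F=float(f_stat),
                    df_num=df_num,
                    df_den=df_den,
                    gg_epsilon=eps,
                    mauchly_w=w,
                    mauchly_p=w_p,
                    p_uncorrected=p_unc,
                    p_gg=p_gg,
                    p=p_rep,
                    partial_eta_sq=eta,
                    rating=rating,
                )
            )
    return effects


def anova_effects_frame(effects: Sequence[RmAnovaEffect]) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in effects])


# ---------------------------------------------------------------------------
# Sphericity


def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the k x k covariance matrix of the
    within-factor cell scores.

    Equals 1 under compound symmetry; bounded below by 1/(k-1).
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within-factor levels")
    h = helmert(k)
    s = h @ cov @ h.T
    tr = np.trace(s)
    denom = (k - 1) * np.sum(s * s)
    if denom <= 0:
        raise ValueError("degenerate covariance: cannot estimate epsilon")
    return float(min(1.0, tr * tr / denom))


def mauchly_sphericity(
    table: pd.DataFrame,
    factor: str,
    outcome: str,
    subject: str = "subject",
) -> tuple[float, float]:
    """Mauchly's sphericity test for one within-subject factor.

    Collapses the table to subject x level means (averaging any other
    conditions), then tests the orthonormal-contrast covariance.  With two
    levels the test is degenerate: (W, p) = (1, 1).
    """
    wide = (
        table.groupby([subject, factor], observed=True)[outcome]
        .mean()
        .unstack(factor)
    )
    if wide.isna().any().any():
        raise ValueError("incomplete subject x level table")
    scores = wide.to_numpy() @ helmert(wide.shape[1]).T
    return _mauchly_from_scores(scores)


# ---------------------------------------------------------------------------
# Scalar statistics


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; rejects degenerate constant input."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(values) == 0:
        raise ValueError("constant input is degenerate for normality testing")
    res = sps.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p); order preserving."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def cohens_d_paired(x, y) -> tuple[float, str]:
    """Paired Cohen's d (d_z): mean difference / SD of the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, "negligible"
        raise ValueError("zero-variance differences")
    d = float(diff.mean() / sd)
    return d, rate_cohens_d(d)


def cohens_d_av(x, y) -> float:
    """Mean difference divided by the average of the two SDs (d_av)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sd = 0.5 * (x.std(ddof=1) + y.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance in both samples")
    return float((x.mean() - y.mean()) / sd)


def partial_eta_squared(ss_effect: float, ss_error: float) -> tuple[float, str]:
    """Partial eta squared SS_eff / (SS_eff + SS_err), with Cohen rating."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be >= 0")
    total = ss_effect + ss_error
    if total == 0:
        raise ValueError("both sums of squares are zero")
    v = float(ss_effect / total)
    return v, rate_partial_eta_sq(v)


def condition_slopes(cell_means, covariate_values) -> float:
    """Ordinary least-squares slope of condition means against a covariate
    (e.g. cadence means vs. prescribed speed in km/h)."""
    y = np.asarray(cell_means, dtype=float)
    x = np.asarray(covariate_values, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 (covariate, mean) points of equal length")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    return float(np.polyfit(x, y, 1)[0])


# ---------------------------------------------------------------------------
# Post hoc comparisons


def pairwise_posthoc(
    table: pd.DataFrame,
    outcome: str,
    factor: str,
    subject: str = "subject",
    alpha: float = 0.05,
) -> list[PostHocComparison]:
    """Bonferroni-adjusted paired t-tests between the levels of one factor.

    Observations are collapsed to subject x level means over the remaining
    conditions; the family size m is the number of level pairs.
    """
    wide = (
        table.groupby([subject, factor], observed=True)[outcome]
        .mean()
        .unstack(factor)
    )
    if wide.isna().any().any():
        raise ValueError("incomplete subject x level table")
    lvls = list(wide.columns)
    pairs = list(combinations(lvls, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        x = wide[a].to_numpy()
        y = wide[b].to_numpy()
        diff = x - y
        n = len(diff)
        sd = diff.std(ddof=1)
        if sd == 0 and not np.allclose(diff, 0):
            # constant nonzero difference: degenerate paired t (d_z -> inf)
            dz = float(np.sign(diff.mean()) * np.inf)
            rating = "large"
            t_stat, p_raw, half = dz, 0.0, 0.0
        else:
            t_stat, p_raw = sps.ttest_rel(x, y)
            half = sps.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
            dz, rating = cohens_d_paired(x, y)
        out.append(
            PostHocComparison(
                level_a=a,
                level_b=b,
                mean_diff=float(diff.mean()),
                ci_low=float(diff.mean() - half),
                ci_high=float(diff.mean() + half),
                t=float(t_stat),
                p_raw=float(p_raw),
                p_bonferroni=float(bonferroni_adjust([p_raw], m)[0]),
                cohens_dz=dz,
                cohens_d_av=cohens_d_av(x, y),
                rating=rating,
            )
        )
    return out


def posthoc_frame(comparisons: Sequence[PostHocComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
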