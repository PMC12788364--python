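import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from runload import (
    bonferroni_adjust,
    cohens_d_paired,
    condition_slopes,
    greenhouse_geisser_epsilon,
    mauchly_sphericity,
    partial_eta_squared,
    rm_anova_3way,
    shapiro_wilk,
)
from runload.stats import (
    _project,
    pairwise_posthoc,
    rate_cohens_d,
    rate_partial_eta_sq,
)

FACTORS = ("f_a", "f_b", "f_s")
LEVELS = {"f_a": (50, 1000, 2300), "f_b": ("v1", "v2", "v3"), "f_s": ("R", "T")}


def make_table(n_subjects, rng, effect=None):
    """Balanced subject x 3 x 3 x 2 table of N(0,1) + subject effect."""
    rows = []
    subj_eff = rng.normal(0, 1.0, n_subjects)
    for s in range(n_subjects):
        for a in LEVELS["f_a"]:
            for b in LEVELS["f_b"]:
                for c in LEVELS["f_s"]:
                    y = subj_eff[s] + rng.normal()
                    if effect:
                        y += effect(a, b, c)
                    rows.append((f"S{s}", a, b, c, y))
    return pd.DataFrame(rows, columns=["subject", *FACTORS, "y"])


class TestRmAnova:
    def test_seven_effects(self, rng):
        effects = rm_anova_3way(make_table(8, rng), "y", factors=FACTORS)
        assert len(effects) == 7
        names = {e.effect for e in effects}
        assert "f_a" in names and "f_a x f_b x f_s" in names

    def test_two_level_factor_equals_squared_paired_t(self, rng):
        table = make_table(9, rng)
        effects = {e.effect: e for e in rm_anova_3way(table, "y", factors=FACTORS)}
        wide = table.groupby(["subject", "f_s"])["y"].mean().unstack()
        t_stat, p = sps.ttest_rel(wide["R"], wide["T"])
        assert effects["f_s"].F == pytest.approx(t_stat**2, rel=1e-9)
        assert effects["f_s"].p_uncorrected == pytest.approx(p, rel=1e-9)
        assert effects["f_s"].gg_epsilon == 1.0  # two levels are always spherical

    def test_rejects_unbalanced_design(self, rng):
        table = make_table(6, rng).iloc[:-1]
        with pytest.raises(ValueError, match="S5"):
            rm_anova_3way(table, "y", factors=FACTORS)

    def test_rejects_too_few_subjects(self, rng):
        with pytest.raises(ValueError, match="nsufficient"):
            rm_anova_3way(make_table(2, rng), "y", factors=FACTORS)

    def test_gg_never_more_significant(self, rng):
        # the correction raises p in the significance region; far from it
        # (large p, F near or below 1) shrinking both dfs can lower p, but
        # never enough to flip a non-significant effect to significant
        for _ in range(10):
            for e in rm_anova_3way(make_table(7, rng), "y", factors=FACTORS):
                if e.p_uncorrected < 0.1:
                    assert e.p_gg >= e.p_uncorrected - 1e-12
                if e.p_gg < 0.05:
                    assert e.p_uncorrected < 0.05
                assert 1.0 / max(e.df_num, 1) <= e.gg_epsilon <= 1.0 + 1e-12

    def test_partial_eta_bounds_and_F_nonnegative(self, rng):
        for e in rm_anova_3way(make_table(8, rng), "y", factors=FACTORS):
            assert e.F >= 0
            assert 0 <= e.partial_eta_sq <= 1

    def test_detects_programmed_main_effect(self, rng):
        eff = lambda a, b, c: {"v1": -2.0, "v2": 0.0, "v3": 2.0}[b]
        effects = {
            e.effect: e
            for e in rm_anova_3way(make_table(10, rng, eff), "y", factors=FACTORS)
        }
        assert effects["f_b"].p < 0.001
        assert effects["f_b"].partial_eta_sq > 0.5

    def test_sum_of_squares_partition(self, rng):
        table = make_table(6, rng)
        cube = (
            table.pivot_table(
                index="subject", columns=list(FACTORS), values="y"
            )
            .to_numpy()
            .reshape(6, 3, 3, 2)
        )
        total = np.sum((cube - cube.mean()) ** 2)
        from itertools import combinations

        parts = 0.0
        for r in range(1, 5):
            for subset in combinations(range(4), r):
                parts += np.sum(_project(cube, subset) ** 2)
        assert parts == pytest.approx(total, rel=1e-10)

    def test_agreement_with_reference_implementation(self, rng):
        """F and p match statsmodels AnovaRM to 6 significant digits."""
        from statsmodels.stats.anova import AnovaRM

        name_map = {
            "f_a": "f_a",
            "f_b": "f_b",
            "f_s": "f_s",
            "f_a x f_b": "f_a:f_b",
            "f_a x f_s": "f_a:f_s",
            "f_b x f_s": "f_b:f_s",
            "f_a x f_b x f_s": "f_a:f_b:f_s",
        }
        for rep in range(20):
            table = make_table(6, rng)
            ours = rm_anova_3way(table, "y", factors=FACTORS)
            ref = AnovaRM(
                table, "y", "subject", within=list(FACTORS)
            ).fit().anova_table
            for e in ours:
                row = ref.loc[name_map[e.effect]]
                assert e.F == pytest.approx(row["F Value"], rel=1e-6)
                assert e.p_uncorrected == pytest.approx(row["Pr > F"], rel=1e-6, abs=1e-12)
                assert e.df_num == row["Num DF"]
                assert e.df_den == row["Den DF"]


class TestSphericity:
    def test_two_levels_epsilon_one(self):
        assert greenhouse_geisser_epsilon(np.array([[1.0, 0.2], [0.2, 1.5]])) == 1.0

    def test_identity_covariance_spherical(self):
        assert greenhouse_geisser_epsilon(np.eye(3)) == pytest.approx(1.0)

    def test_compound_symmetry_spherical(self):
        cov = 0.5 * np.ones((4, 4)) + 1.0 * np.eye(4)
        assert greenhouse_geisser_epsilon(cov) == pytest.approx(1.0)

    def test_rank_one_lower_bound(self):
        v = np.array([1.0, -0.3, 0.6])
        cov = np.outer(v, v)
        assert greenhouse_geisser_epsilon(cov) == pytest.approx(0.5)  # 1/(k-1)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            greenhouse_geisser_epsilon(np.ones((1, 1)))
        with pytest.raises(ValueError):
            greenhouse_geisser_epsilon(np.zeros((3, 3)))

    def test_mauchly_two_levels_degenerate(self, rng):
        table = make_table(8, rng)
        w, p = mauchly_sphericity(table, "f_s", "y")
        assert (w, p) == (1.0, 1.0)

    def test_mauchly_null_rejection_rate(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            scores = rng.normal(size=(10, 3))
            rows = [
                (f"S{s}", lvl, "x", "x", scores[s, j])
                for s in range(10)
                for j, lvl in enumerate("abc")
            ]
            df = pd.DataFrame(rows, columns=["subject", "f", "g", "h", "y"])
            _, p = mauchly_sphericity(df, "f", "y")
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_mauchly_power_on_nonspherical_data(self):
        rng = np.random.default_rng(8)
        scale = np.array([3.0, 1.0, 0.15])
        rejections = 0
        reps = 200
        for _ in range(reps):
            scores = rng.normal(size=(10, 3)) * scale
            rows = [
                (f"S{s}", lvl, scores[s, j])
                for s in range(10)
                for j, lvl in enumerate("abc")
            ]
            df = pd.DataFrame(rows, columns=["subject", "f", "y"])
            _, p = mauchly_sphericity(df, "f", "y")
            rejections += p < 0.05
        assert rejections / reps > 0.8


class TestShapiro:
    def test_null_rejection_rate(self):
        rng = np.random.default_rng(3)
        rej = sum(
            shapiro_wilk(rng.normal(size=30))[1] < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rej / 1000 <= 0.07

    def test_skewed_rejection(self):
        rng = np.random.default_rng(4)
        rej = sum(
            shapiro_wilk(rng.exponential(size=50))[1] < 0.05 for _ in range(200)
        )
        assert rej / 200 > 0.9

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([2.0] * 10)


class TestEffectSizes:
    def test_bonferroni_examples(self):
        assert bonferroni_adjust([0.01], 6)[0] == pytest.approx(0.06)
        assert bonferroni_adjust([0.5], 3)[0] == 1.0
        assert np.array_equal(bonferroni_adjust([0.2, 0.04], 1), [0.2, 0.04])

    def test_bonferroni_order_preserving(self, rng):
        p = np.sort(rng.uniform(0, 0.2, 10))
        adj = bonferroni_adjust(p, 5)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)

    def test_cohens_d_identical(self):
        d, rating = cohens_d_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and rating == "negligible"

    def test_cohens_d_hand_value(self):
        # differences (1, 2, 3): mean 2, sd 1 -> d = 2
        d, rating = cohens_d_paired([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert d == pytest.approx(2.0)
        assert rating == "large"

    def test_band_boundaries(self):
        assert rate_cohens_d(0.79) == "medium"
        assert rate_cohens_d(0.80) == "large"
        assert rate_cohens_d(0.19) == "negligible"
        assert rate_cohens_d(0.5) == "medium"

    def test_cohens_d_zero_variance_nonzero_diff(self):
        with pytest.raises(ValueError):
            cohens_d_paired([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_partial_eta_examples(self):
        assert partial_eta_squared(0.0, 5.0) == (0.0, "negligible")
        assert partial_eta_squared(5.0, 0.0) == (1.0, "large")
        v, rating = partial_eta_squared(3.0, 7.0)
        assert v == pytest.approx(0.30)
        assert rating == "large"

    def test_eta_band_boundaries(self):
        assert rate_partial_eta_sq(0.139) == "medium"
        assert rate_partial_eta_sq(0.14) == "large"
        assert rate_partial_eta_sq(0.005) == "negligible"


class TestConditionSlopes:
    def test_published_cadence_slope(self):
        slope = condition_slopes([160, 166, 172], [9.4, 12.7, 14.9])
        assert round(slope, 1) == 2.2

    def test_constant_means(self):
        assert condition_slopes([5, 5, 5], [1, 2, 3]) == pytest.approx(0.0)

    def test_two_points(self):
        assert condition_slopes([0, 5], [0, 1]) == pytest.approx(5.0)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            condition_slopes([1.0], [1.0])
        with pytest.raises(ValueError):
            condition_slopes([1, 2], [3, 3])


class TestPosthoc:
    def test_family_size_and_caps(self, rng):
        eff = lambda a, b, c: {"v1": -1.0, "v2": 0.0, "v3": 1.0}[b]
        table = make_table(10, rng, eff)
        comps = pairwise_posthoc(table, "y", "f_b")
        assert len(comps) == 3
        for c in comps:
            assert c.p_bonferroni >= c.p_raw
            assert c.p_bonferroni <= 1.0
            assert c.ci_low <= c.mean_diff <= c.ci_high

    def test_detects_programmed_difference(self, rng):
        eff = lambda a, b, c: {"v1": -2.0, "v2": 0.0, "v3": 2.0}[b]
        table = make_table(10, rng, eff)
        comps = {(c.level_a, c.level_b): c for c in pairwise_posthoc(table, "y", "f_b")}
        c = comps[("v1", "v3")]
        assert c.p_bonferroni < 0.01
        assert c.mean_diff == pytest.approx(-4.0, abs=1.0)
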