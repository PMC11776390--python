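"""Mixed 2x2 ANOVA against independent oracles, effect sizes, KS, Tukey."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dixonseg.errors import DesignError, StatsError
from dixonseg.phantom import CohortSpec
from dixonseg.stats import (
    MixedAnova2x2,
    classify_effect_size,
    interaction_power,
    ks_normality,
    mixed_anova_2x2,
    partial_eta_squared,
    partial_eta_squared_from_f,
    tukey_hsd,
)


def random_table(rng, n=9, effects=None):
    effects = effects or {}
    rows = []
    for gi, group in enumerate(("IG", "CG")):
        for i in range(n):
            subj_eff = rng.normal(0, 1)
            for ti, time in enumerate(("pre", "post")):
                y = (
                    10.0
                    + subj_eff
                    + effects.get("group", 0.0) * gi
                    + effects.get("time", 0.0) * ti
                    + effects.get("interaction", 0.0) * gi * ti
                    + rng.normal(0, 0.5)
                )
                rows.append(
                    {"subject_id": f"{group}{i:02d}", "group": group,
                     "time": time, "outcome_cm3": y}
                )
    return pd.DataFrame(rows)


def projection_oracle(table, outcome="outcome_cm3"):
    """Independent least-squares route: sums of squares from RSS drops of
    nested linear models fitted with lstsq."""
    df = table.copy()
    groups = ["IG", "CG"] if set(df.group) == {"IG", "CG"} else sorted(set(df.group))
    times = ["pre", "post"] if set(df.time) == {"pre", "post"} else sorted(set(df.time))
    y = df[outcome].to_numpy(dtype=float)
    n_obs = len(y)
    subjects = sorted(df.subject_id.unique())

    def dummies(cols):
        mats = [np.ones((n_obs, 1))]
        if "group" in cols:
            mats.append((df.group == groups[1]).to_numpy(float)[:, None])
        if "subject" in cols:
            mats.append(np.column_stack([(df.subject_id == s).to_numpy(float)
                                         for s in subjects[:-1]]))
        if "time" in cols:
            mats.append((df.time == times[1]).to_numpy(float)[:, None])
        if "interaction" in cols:
            g = (df.group == groups[1]).to_numpy(float)
            t = (df.time == times[1]).to_numpy(float)
            mats.append((g * t)[:, None])
        return np.column_stack(mats)

    def rss(cols):
        X = dummies(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ss_group = rss([]) - rss(["group"])
    ss_subj = rss(["group"]) - rss(["subject"])
    ss_time = rss(["subject"]) - rss(["subject", "time"])
    ss_inter = rss(["subject", "time"]) - rss(["subject", "time", "interaction"])
    ss_err = rss(["subject", "time", "interaction"])
    n = len(subjects) // 2
    out = {}
    for name, ss_e, df1, ss_er, df2 in (
        ("GROUP", ss_group, 1, ss_subj, 2 * (n - 1)),
        ("TIME", ss_time, 1, ss_err, 2 * (n - 1)),
        ("TIME×GROUP", ss_inter, 1, ss_err, 2 * (n - 1)),
    ):
        F = (ss_e / df1) / (ss_er / df2)
        out[name] = {
            "ss": ss_e, "ss_err": ss_er, "F": F,
            "p": float(sps.f.sf(F, df1, df2)),
        }
    return out


class TestMixedAnova:
    def test_constant_outcome_gives_zero_ss(self):
        rng = np.random.default_rng(0)
        table = random_table(rng)
        table["outcome_cm3"] = 42.0
        res = mixed_anova_2x2(table)
        for eff in res.effects.values():
            assert eff.ss_effect == pytest.approx(0.0, abs=1e-18)
            assert eff.F == 0.0 and eff.p == 1.0

    def test_df_are_1_and_16_for_nine_per_group(self):
        rng = np.random.default_rng(1)
        res = mixed_anova_2x2(random_table(rng, n=9))
        for eff in res.effects.values():
            assert (eff.df_num, eff.df_den) == (1, 16)

    def test_matches_projection_oracle_on_100_random_tables(self):
        rng = np.random.default_rng(2)
        for rep in range(100):
            effects = {
                "group": rng.normal(0, 2),
                "time": rng.normal(0, 2),
                "interaction": rng.normal(0, 2),
            }
            table = random_table(rng, n=9, effects=effects)
            res = mixed_anova_2x2(table)
            ref = projection_oracle(table)
            for name, eff in res.effects.items():
                r = ref[name]
                assert eff.ss_effect == pytest.approx(r["ss"], rel=1e-8, abs=1e-10)
                assert eff.ss_error == pytest.approx(r["ss_err"], rel=1e-8)
                assert eff.F == pytest.approx(r["F"], rel=1e-8)
                assert eff.p == pytest.approx(r["p"], rel=1e-8, abs=1e-12)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        table = random_table(rng, n=9, effects={"interaction": 1.5, "time": 0.7})
        res = mixed_anova_2x2(table)
        ref = pg.mixed_anova(data=table, dv="outcome_cm3", within="time",
                             between="group", subject="subject_id")
        ref = ref.set_index("Source")
        assert res.effects["GROUP"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res.effects["TIME"].F == pytest.approx(ref.loc["time", "F"], rel=1e-9)
        assert res.effects["TIME×GROUP"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert res.effects["TIME×GROUP"].partial_eta_sq == pytest.approx(
            ref.loc["Interaction", "np2"], rel=1e-9
        )

    def test_ss_decomposition_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            res = mixed_anova_2x2(random_table(rng, n=5))
            total = (
                res.ss["group"] + res.ss["subjects_within_group"] + res.ss["time"]
                + res.ss["interaction"] + res.ss["error_within"]
            )
            assert total == pytest.approx(res.ss["total"], rel=1e-10)

    def test_unbalanced_designs_rejected(self):
        rng = np.random.default_rng(5)
        table = random_table(rng)
        with pytest.raises(DesignError):
            mixed_anova_2x2(table.iloc[:-1])  # missing one cell
        extra = table.copy()
        extra.loc[extra.index[-1], "group"] = "IG"  # subject in two groups
        with pytest.raises(DesignError):
            mixed_anova_2x2(extra)

    def test_model_results_summary_contains_effects(self):
        rng = np.random.default_rng(6)
        res = MixedAnova2x2(random_table(rng), outcome="outcome_cm3").fit()
        text = res.summary()
        for token in ("GROUP", "TIME×GROUP", "eta_p^2"):
            assert token in text


class TestEffectSizes:
    def test_partial_eta_sq_from_ss(self):
        assert partial_eta_squared(4.0, 4.0) == 0.5
        assert partial_eta_squared(0.0, 5.0) == 0.0
        with pytest.raises(StatsError):
            partial_eta_squared(0.0, 0.0)

    def test_f_form_equivalence(self):
        """eta_p^2 from SS equals F*df1/(F*df1+df2) when F is built from the
        same SS and dfs."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            ss_e, ss_err = rng.uniform(0.01, 10, 2)
            df1, df2 = 1, 16
            f = (ss_e / df1) / (ss_err / df2)
            assert partial_eta_squared(ss_e, ss_err) == pytest.approx(
                partial_eta_squared_from_f(f, df1, df2), rel=1e-12
            )

    def test_interaction_effect_size_from_reported_f(self):
        assert partial_eta_squared_from_f(12.80, 1, 16) == pytest.approx(0.44, abs=0.005)

    def test_classification_thresholds(self):
        assert classify_effect_size(0.44) == "large"
        assert classify_effect_size(0.14) == "large"
        assert classify_effect_size(0.06) == "medium"
        assert classify_effect_size(0.01) == "low"
        assert classify_effect_size(0.005) == "below_low"
        with pytest.raises(StatsError):
            classify_effect_size(1.5)

    def test_classification_monotone(self):
        order = {"below_low": 0, "low": 1, "medium": 2, "large": 3}
        grid = np.linspace(0, 1, 101)
        ranks = [order[classify_effect_size(v)] for v in grid]
        assert ranks == sorted(ranks)


class TestKSNormality:
    def test_probability_integral_points_give_tiny_statistic(self):
        """Points placed at the fitted normal's quantile grid make the KS
        statistic at most 1/(2n) by construction (plus estimation slack)."""
        n = 20
        q = (np.arange(n) + 0.5) / n
        x = sps.norm.ppf(q)  # sample mean ~0, sd ~1 by symmetry
        stat, _ = ks_normality(x)
        assert stat <= 1 / (2 * n) + 0.02

    def test_constant_sample_rejected(self):
        with pytest.raises(StatsError):
            ks_normality(np.ones(10))
        with pytest.raises(StatsError):
            ks_normality([1.0, 2.0])

    def test_rejection_rate_near_nominal_with_lilliefors(self):
        """At n=9, the Lilliefors-corrected variant rejects true normals at
        about the nominal 5% rate; the plain variant is conservative."""
        rng = np.random.default_rng(8)
        plain = corrected = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=9)
            if ks_normality(x)[1] < 0.05:
                plain += 1
            if ks_normality(x, lilliefors=True)[1] < 0.05:
                corrected += 1
        se3 = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert corrected / reps == pytest.approx(0.05, abs=se3 + 0.01)
        assert plain / reps < 0.05  # conservative by construction


class TestTukey:
    def test_equal_cell_means_give_p_one(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, n=6)
        # force all four cell means equal while keeping residual noise
        for g in ("IG", "CG"):
            for t in ("pre", "post"):
                sel = (table.group == g) & (table.time == t)
                table.loc[sel, "outcome_cm3"] -= table.loc[sel, "outcome_cm3"].mean()
        res = mixed_anova_2x2(table)
        assert (tukey_hsd(table, res).p_adj > 1 - 1e-9).all()

    def test_identical_groups_have_symmetric_pre_post_p(self):
        rng = np.random.default_rng(10)
        half = random_table(rng, n=5)
        ig = half[half.group == "IG"].copy()
        cg = ig.copy()
        cg["group"] = "CG"
        cg["subject_id"] = cg["subject_id"].str.replace("IG", "CG")
        table = pd.concat([ig, cg], ignore_index=True)
        tk = mixed_anova_2x2(table).tukey().set_index(["cell_a", "cell_b"])
        p_ig = tk.loc[("IG_pre", "IG_post"), "p_adj"]
        p_cg = tk.loc[("CG_pre", "CG_post"), "p_adj"]
        assert p_ig == pytest.approx(p_cg, rel=1e-12)

    def test_adjusted_p_matches_studentized_range_cdf(self):
        """Direct evaluation of the studentized-range survival function on a
        constructed table reproduces each adjusted p."""
        rng = np.random.default_rng(11)
        table = random_table(rng, n=4, effects={"interaction": 2.0, "group": 1.0})
        res = mixed_anova_2x2(table)
        ms_err = res.ss["error_within"] / res.dfs["error_within"]
        tk = res.tukey()
        for _, row in tk.iterrows():
            q = abs(row.mean_diff) / np.sqrt(ms_err / res.n_per_group)
            expected = sps.studentized_range.sf(q, 4, res.dfs["error_within"])
            assert row.p_adj == pytest.approx(min(expected, 1.0), rel=1e-9)


class TestInteractionPower:
    def test_type_one_error_near_alpha_under_null(self):
        cs = CohortSpec(
            ig_muscle_effect_pct=0.0, cg_muscle_effect_pct=0.0,
            time_sat_effect_pct=0.0, within_subject_noise_pct=1.0,
        )
        rate = interaction_power(cs, alpha=0.05, n_reps=400, seed=1)
        se3 = 3 * np.sqrt(0.05 * 0.95 / 400)
        assert rate == pytest.approx(0.05, abs=se3)

    def test_power_one_for_huge_effect(self):
        cs = CohortSpec(
            ig_muscle_effect_pct=50.0, cg_muscle_effect_pct=0.0,
            within_subject_noise_pct=0.1,
        )
        assert interaction_power(cs, n_reps=100, seed=2) == 1.0
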