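"""Pre/post two-group statistics: normality screen, 2x2 mixed ANOVA,
partial eta-squared effect sizes, Tukey HSD follow-ups, and a Monte-Carlo
power harness.

The design is a split-plot: GROUP (intervention vs. control) is a
between-subject factor, TIME (pre vs. post) a within-subject factor.  The
sum-of-squares decomposition is

    SS_total = SS_group + SS_subjects(group) + SS_time + SS_timexgroup + SS_error

with GROUP tested against subjects-within-group (df = a(n-1)) and TIME and
the interaction tested against the subject-by-time residual
(df = a(n-1)(t-1)); for 9 subjects per group both error strata have 16 df.
Partial eta-squared pairs each effect with the error stratum it is tested
against: eta_p^2 = SS_effect / (SS_effect + SS_error), equivalently
F*df1 / (F*df1 + df2).  Effect sizes are classified against Cohen's
benchmarks (0.01 low, 0.06 medium, 0.14 large), treated as inclusive lower
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, StatsError

EFFECT_NAMES = ("GROUP", "TIME", "TIME×GROUP")
SIZE_CLASSES = ("below_low", "low", "medium", "large")


# ---------------------------------------------------------------------------
# small helpers


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """eta_p^2 = SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise StatsError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise StatsError("partial eta squared undefined when both SS are zero")
    return ss_effect / (ss_effect + ss_error)


def partial_eta_squared_from_f(f: float, df_num: int, df_den: int) -> float:
    """Equivalent form from the F statistic: F*df1 / (F*df1 + df2)."""
    if f < 0:
        raise StatsError("F must be non-negative")
    return f * df_num / (f * df_num + df_den)


def classify_effect_size(eta_p2: float) -> str:
    """Cohen benchmarks as inclusive lower bounds."""
    if not 0.0 <= eta_p2 <= 1.0:
        raise StatsError(f"partial eta squared must be in [0,1], got {eta_p2}")
    if eta_p2 >= 0.14:
        return "large"
    if eta_p2 >= 0.06:
        return "medium"
    if eta_p2 >= 0.01:
        return "low"
    return "below_low"


def ks_normality(values, lilliefors: bool = False) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a normal with the sample's
    mean and SD.

    With ``lilliefors=False`` (default) the plain KS p-value is returned;
    because the reference parameters are estimated from the same sample it
    is conservative (the Lilliefors caveat).  ``lilliefors=True`` uses the
    Lilliefors-corrected distribution instead.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 3:
        raise StatsError(f"KS normality test needs n >= 3, got n={x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("sample is constant; normality test undefined")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return float(stat), float(p)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# 2x2 mixed (split-plot) ANOVA


@dataclass
class EffectResult:
    effect: str
    ss_effect: float
    ss_error: float
    df_num: int
    df_den: int
    F: float
    p: float
    partial_eta_sq: float
    size_class: str


def _order_levels(levels, preferred):
    levels = list(dict.fromkeys(levels))
    if set(levels) == set(preferred):
        return list(preferred)
    return sorted(levels)


def _table_to_array(table: pd.DataFrame, outcome: str, subject: str,
                    group: str, time: str):
    """Validate the balanced 2x2 design and reshape to y[group, subject, time]."""
    for col in (subject, group, time, outcome):
        if col not in table.columns:
            raise DesignError(f"cohort table is missing column {col!r}")
    groups = _order_levels(table[group], ("IG", "CG"))
    times = _order_levels(table[time], ("pre", "post"))
    if len(groups) != 2:
        raise DesignError(f"need exactly 2 groups, got {groups}")
    if len(times) != 2:
        raise DesignError(f"need exactly 2 time points, got {times}")
    subj_group = table.groupby(subject)[group].nunique()
    if (subj_group > 1).any():
        bad = subj_group[subj_group > 1].index.tolist()
        raise DesignError(f"subjects assigned to more than one group: {bad}")
    counts = table.groupby([subject, time]).size()
    if (counts != 1).any():
        raise DesignError("each subject needs exactly one row per time point")
    per_subject = table.groupby(subject)[time].nunique()
    if (per_subject != 2).any():
        bad = per_subject[per_subject != 2].index.tolist()
        raise DesignError(f"subjects missing a time point: {bad}")
    ns = [table[table[group] == g][subject].nunique() for g in groups]
    if ns[0] != ns[1]:
        raise DesignError(f"unbalanced design: {ns[0]} vs {ns[1]} subjects per group")
    n = ns[0]
    if n < 2:
        raise DesignError("need at least 2 subjects per group")
    y = np.empty((2, n, 2), dtype=float)
    subject_ids = []
    for gi, g in enumerate(groups):
        sub = table[table[group] == g]
        sids = sorted(sub[subject].unique())
        subject_ids.append(sids)
        for si, sid in enumerate(sids):
            for ti, t in enumerate(times):
                val = sub[(sub[subject] == sid) & (sub[time] == t)][outcome]
                y[gi, si, ti] = float(val.iloc[0])
    if not np.all(np.isfinite(y)):
        raise DesignError("outcome contains non-finite values")
    return y, groups, times, subject_ids


def _f_and_p(ss_effect, df_num, ss_error, df_den):
    if ss_error <= 0:
        if ss_effect <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_effect / df_num) / (ss_error / df_den)
    return float(f), float(sps.f.sf(f, df_num, df_den))


class MixedAnova2x2:
    """2 (GROUP) x 2 (TIME, repeated) analysis of variance.

    Parameters
    ----------
    data : DataFrame with one row per subject x time.
    outcome : name of the outcome column (e.g. ``"muscle_cm3"``).
    subject, group, time : column names of the design factors.
    """

    def __init__(self, data: pd.DataFrame, outcome: str,
                 subject: str = "subject_id", group: str = "group",
                 time: str = "time"):
        self.data = data
        self.outcome = outcome
        self._y, self.groups, self.times, self.subject_ids = _table_to_array(
            data, outcome, subject, group, time
        )

    @classmethod
    def from_dataframe(cls, data, outcome, **kwargs):
        return cls(data, outcome, **kwargs)

    def fit(self) -> "MixedAnovaResults":
        y = self._y
        a, n, t = y.shape  # (2, n, 2)
        grand = y.mean()
        ss_total = float(((y - grand) ** 2).sum())
        group_means = y.mean(axis=(1, 2))
        subj_means = y.mean(axis=2)
        time_means = y.mean(axis=(0, 1))
        cell_means = y.mean(axis=1)

        ss_group = float(n * t * ((group_means - grand) ** 2).sum())
        ss_subj = float(t * ((subj_means - group_means[:, None]) ** 2).sum())
        ss_time = float(a * n * ((time_means - grand) ** 2).sum())
        ss_cells = float(n * ((cell_means - grand) ** 2).sum())
        ss_inter = max(ss_cells - ss_group - ss_time, 0.0)
        ss_error = max(ss_total - ss_group - ss_subj - ss_time - ss_inter, 0.0)

        df_group, df_subj = a - 1, a * (n - 1)
        df_time = t - 1
        df_inter = (a - 1) * (t - 1)
        df_error = a * (n - 1) * (t - 1)

        effects = {}
        for name, ss_e, df1, ss_err, df2 in (
            ("GROUP", ss_group, df_group, ss_subj, df_subj),
            ("TIME", ss_time, df_time, ss_error, df_error),
            ("TIME×GROUP", ss_inter, df_inter, ss_error, df_error),
        ):
            f, p = _f_and_p(ss_e, df1, ss_err, df2)
            if ss_e == 0 and ss_err == 0:
                eta = 0.0
            else:
                eta = partial_eta_squared(ss_e, ss_err)
            effects[name] = EffectResult(
                effect=name,
                ss_effect=ss_e,
                ss_error=ss_err,
                df_num=df1,
                df_den=df2,
                F=f,
                p=p,
                partial_eta_sq=eta,
                size_class=classify_effect_size(eta),
            )
        ss = {
            "group": ss_group,
            "subjects_within_group": ss_subj,
            "time": ss_time,
            "interaction": ss_inter,
            "error_within": ss_error,
            "total": ss_total,
        }
        dfs = {
            "group": df_group,
            "subjects_within_group": df_subj,
            "time": df_time,
            "interaction": df_inter,
            "error_within": df_error,
        }
        return MixedAnovaResults(
            model=self, effects=effects, ss=ss, dfs=dfs,
            cell_means=cell_means, n_per_group=n,
        )


@dataclass
class MixedAnovaResults:
    """Fitted decomposition with effect sizes and Tukey follow-ups."""

    model: MixedAnova2x2
    effects: dict[str, EffectResult]
    ss: dict[str, float]
    dfs: dict[str, int]
    cell_means: np.ndarray  # (group, time)
    n_per_group: int

    @property
    def anova_table(self) -> pd.DataFrame:
        rows = []
        for name in EFFECT_NAMES:
            e = self.effects[name]
            rows.append(
                {
                    "effect": e.effect,
                    "SS": e.ss_effect,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "F": e.F,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "size_class": e.size_class,
                }
            )
        return pd.DataFrame(rows)

    def tukey(self) -> pd.DataFrame:
        """All pairwise comparisons of the four GROUP x TIME cell means via
        the studentized range, using the within-subject error stratum."""
        groups, times = self.model.groups, self.model.times
        cells = [(g, t) for g in range(2) for t in range(2)]
        names = [f"{groups[g]}_{times[t]}" for g, t in cells]
        ms_err = self.ss["error_within"] / self.dfs["error_within"]
        df = self.dfs["error_within"]
        n = self.n_per_group
        rows = []
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                gi, ti = cells[i]
                gj, tj = cells[j]
                diff = float(self.cell_means[gi, ti] - self.cell_means[gj, tj])
                if ms_err > 0:
                    q = abs(diff) / np.sqrt(ms_err / n)
                    p_adj = float(sps.studentized_range.sf(q, len(cells), df))
                else:
                    q = 0.0 if diff == 0 else float("inf")
                    p_adj = 1.0 if diff == 0 else 0.0
                rows.append(
                    {
                        "cell_a": names[i],
                        "cell_b": names[j],
                        "mean_diff": diff,
                        "q": float(q),
                        "p_adj": min(p_adj, 1.0),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"2 (GROUP) x 2 (TIME) mixed ANOVA on {self.model.outcome!r}",
            f"subjects per group: {self.n_per_group}",
            "",
            f"{'effect':<12}{'SS':>12}{'df':>9}{'F':>10}{'p':>9}"
            f"{'eta_p^2':>9}  size",
        ]
        for name in EFFECT_NAMES:
            e = self.effects[name]
            lines.append(
                f"{e.effect:<12}{e.ss_effect:>12.4g}"
                f"{f'({e.df_num},{e.df_den})':>9}{e.F:>10.3f}{e.p:>9.4f}"
                f"{e.partial_eta_sq:>9.3f}  {e.size_class}"
            )
        lines.append("")
        lines.append(
            "SS decomposition: "
            + ", ".join(f"{k}={v:.4g}" for k, v in self.ss.items())
        )
        return "\n".join(lines)


def mixed_anova_2x2(table: pd.DataFrame, outcome: str = "outcome_cm3",
                    **kwargs) -> MixedAnovaResults:
    """Functional wrapper around :class:`MixedAnova2x2`."""
    return MixedAnova2x2(table, outcome, **kwargs).fit()


def tukey_hsd(table: pd.DataFrame, anova: MixedAnovaResults) -> pd.DataFrame:
    """Post-hoc cell-mean comparisons for a fitted ANOVA."""
    if anova is None:
        raise StatsError("tukey_hsd requires a fitted ANOVA result")
    return anova.tukey()


# ---------------------------------------------------------------------------
# Monte-Carlo power / calibration harness


def interaction_power(cspec, alpha: float = 0.05, n_reps: int = 1000,
                      seed: int = 0, outcome: str = "muscle_cm3") -> float:
    """Fraction of simulated cohorts whose TIME x GROUP interaction is
    significant at ``alpha``; under zero effects this estimates the type-I
    error rate."""
    from .phantom import simulate_cohort

    if n_reps < 100:
        raise StatsError("n_reps must be >= 100 for a stable estimate")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    hits = 0
    for s in child_seeds:
        table = simulate_cohort(replace(cspec, seed=int(s)))
        res = mixed_anova_2x2(table, outcome=outcome)
        if res.effects["TIME×GROUP"].p < alpha:
            hits += 1
    return hits / n_reps
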