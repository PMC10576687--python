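"""The group-comparison battery: two-way ANOVA interaction per feature
family, Bonferroni post-hoc two-sample t-tests, Pearson chi-square on 2x2
demographic tables (no continuity correction), pooled-variance t from raw
data or summary statistics, and Kruskal-Wallis topography comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .microstates import MicrostateModel, spatial_correlation


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p: float
    alpha: float = 0.05
    correction: str = "none"
    n_comparisons: int = 1
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p value {self.p} outside [0, 1]")
        threshold = self.alpha / self.n_comparisons
        expected = bool(self.p < threshold)
        if self.significant is None:
            object.__setattr__(self, "significant", expected)
        elif self.significant != expected:
            raise ValueError("significance flag inconsistent with p and alpha")


def anova_interaction(
    values: np.ndarray | pd.DataFrame, group_labels: np.ndarray | pd.Series
) -> StatResult:
    """Group x state interaction of a two-way fixed-effects ANOVA.

    ``values`` is subjects x levels for one feature family (4 states, or
    12 transition cells); each subject contributes one observation per
    level in long format.
    """
    vals = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    if vals.ndim != 2 or vals.shape[0] != groups.size:
        raise ValueError("values must be subjects x levels, one group per subject")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(vals) == 0.0:
        raise ValueError("ANOVA undefined: all observations are equal")
    n_subj, n_lev = vals.shape
    long = pd.DataFrame(
        {
            "value": vals.ravel(),
            "group": np.repeat(groups, n_lev),
            "state": np.tile(np.arange(n_lev), n_subj),
        }
    )
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fit = smf.ols("value ~ C(group) * C(state)", data=long).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(group):C(state)"]
    f_stat = float(row["F"])
    if not np.isfinite(f_stat):
        raise ValueError("ANOVA F undefined (zero residual variance)")
    return StatResult(
        test="two-way ANOVA interaction",
        statistic=f_stat,
        df=(float(row["df"]), float(table.loc["Residual", "df"])),
        p=float(row["PR(>F)"]),
    )


def posthoc_t_tests(
    feature_table: pd.DataFrame,
    group_labels: pd.Series,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Pooled-variance two-sample t per feature column, Bonferroni-flagged."""
    groups = pd.Series(group_labels).reindex(feature_table.index)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("post-hoc t-tests require exactly two groups")
    if n_comparisons is None:
        n_comparisons = feature_table.shape[1]
    a = feature_table[groups == levels[0]]
    b = feature_table[groups == levels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least two subjects per group")
    rows = []
    for col in feature_table.columns:
        x, y = a[col].to_numpy(), b[col].to_numpy()
        if np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
            raise ValueError(f"zero pooled variance for feature {col!r}")
        t, p = sst.ttest_ind(x, y, equal_var=True)
        rows.append(
            {
                "feature": col,
                "t": float(t),
                "df": len(x) + len(y) - 2,
                "p": float(p),
                "significant": bool(p < alpha / n_comparisons),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def chi_square_2x2(table: np.ndarray) -> StatResult:
    """Pearson chi-square on a 2x2 count table, df = 1, no Yates correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("all marginals must be positive")
    stat, p, df, _ = sst.chi2_contingency(tab, correction=False)
    return StatResult(test="Pearson chi-square", statistic=float(stat), df=(float(df),), p=float(p))


def two_sample_t(
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    *,
    summary: tuple[tuple[float, float, int], tuple[float, float, int]] | None = None,
) -> StatResult:
    """Pooled-variance Student t, from raw vectors or (mean, sd, n) summaries."""
    if summary is not None:
        (m1, s1, n1), (m2, s2, n2) = summary
        if min(n1, n2) < 2 or s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
            raise ValueError("invalid summary statistics")
        t, p = sst.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        df = n1 + n2 - 2
    else:
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        if min(x.size, y.size) < 2:
            raise ValueError("need at least two observations per group")
        if np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
            raise ValueError("zero variance in both groups")
        t, p = sst.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    return StatResult(
        test="two-sample t (pooled)", statistic=float(t), df=(float(df),), p=float(p)
    )


def subject_map_similarities(
    individual_models: list[MicrostateModel], grand_mean: MicrostateModel
) -> pd.DataFrame:
    """Per subject and state: |spatial correlation| between the subject's
    best-matching individual map and the grand-mean map of that state.

    This is the scalar the topography comparison ranks: how closely each
    subject's own maps resemble the shared A-D maps.
    """
    if grand_mean.labels is None:
        raise ValueError("grand-mean model must carry A-D labels")
    rows = []
    for model in individual_models:
        row = {}
        for label in grand_mean.labels:
            ref = grand_mean.map_by_label(label)
            row[label] = max(
                spatial_correlation(m, ref) for m in model.maps
            )
        rows.append(row)
    return pd.DataFrame(rows)


def kruskal_wallis_topography(
    similarities: pd.DataFrame, group_labels: np.ndarray | pd.Series
) -> dict[str, StatResult]:
    """Tie-corrected Kruskal-Wallis H per state column across two groups."""
    groups = np.asarray(group_labels)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for state in similarities.columns:
        samples = [
            similarities[state].to_numpy()[groups == g] for g in levels
        ]
        h, p = sst.kruskal(*samples)
        out[str(state)] = StatResult(
            test="Kruskal-Wallis", statistic=float(h), df=(float(len(levels) - 1),), p=float(p)
        )
    return out
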