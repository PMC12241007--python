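"""Group-comparison statistics: 3-sigma outlier exclusion, Mann-Whitney U
(exact at small n), Cliff's delta, Cohen's d, and additive two-way ANOVA.

Tests are two-sided throughout. Outlier exclusion is a single (non-iterated)
pass dropping values outside mean +/- 3 SD. The Mann-Whitney test uses full
enumeration of group assignments when both samples have n <= 8 and the
tie-corrected normal approximation otherwise. The two-way ANOVA is additive
(group + bin, no interaction by default) with Type II sums of squares and
reports the group main-effect F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    effect_size: float
    effect_size_name: str
    n_a: int
    n_b: int
    descriptives: dict = field(default_factory=dict)
    df: tuple = ()
    degenerate: bool = False


def exclude_outliers_3sigma(values) -> np.ndarray:
    """Single-pass exclusion of values outside mean +/- 3 SD (SD with n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return x.copy()
    m = x.mean()
    return x[(x >= m - 3 * sd) & (x <= m + 3 * sd)]


def cliffs_delta(x, y) -> float:
    """(#{x_i > y_j} - #{x_i < y_j}) / (n * m), in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (x.size * y.size))


def cohens_d(x, y) -> float:
    """Mean difference over pooled SD (n-1 weights)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group assignments of the pooled
    data (handles ties; feasible for n, m <= 8)."""
    pooled = np.concatenate([x, y])
    n, total = x.size, pooled.size
    nm = x.size * y.size
    u_obs = _u_statistic(x, y)
    dev_obs = abs(u_obs - nm / 2.0)
    count = 0
    idx = np.arange(total)
    for c in combinations(idx, n):
        sel = np.zeros(total, dtype=bool)
        sel[list(c)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - nm / 2.0) >= dev_obs - 1e-12:
            count += 1
    return count / comb(total, n)


def _descriptives(x: np.ndarray, y: np.ndarray, kind: str) -> dict:
    out = {}
    for name, v in (("a", x), ("b", y)):
        if kind == "median_iqr":
            q1, q3 = np.percentile(v, [25, 75])
            out[name] = {"median": float(np.median(v)), "iqr": float(q3 - q1)}
        else:
            out[name] = {
                "mean": float(np.mean(v)),
                "sem": float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan,
            }
    return out


def mann_whitney(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U with Cliff's delta effect size.

    Exact enumeration when both groups have n <= 8, tie-corrected normal
    approximation otherwise. Descriptives are median and IQR per group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if x.size <= 8 and y.size <= 8:
        p = _exact_mw_p(x, y)
    else:
        p = float(
            sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    return GroupComparison(
        test="mann_whitney",
        statistic=u,
        p_value=min(p, 1.0),
        effect_size=cliffs_delta(x, y),
        effect_size_name="cliffs_delta",
        n_a=int(x.size),
        n_b=int(y.size),
        descriptives=_descriptives(x, y, "median_iqr"),
    )


def anova2(values, factor_group, factor_bin, interaction: bool = False) -> GroupComparison:
    """Additive two-way ANOVA; reports the group main-effect F and p.

    Type II sums of squares (robust to unbalanced cells). A zero residual
    sum of squares is flagged as degenerate (F unbounded).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "group": np.asarray(factor_group).astype(str),
            "bin": np.asarray(factor_bin).astype(str),
        }
    )
    for fac in ("group", "bin"):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")

    formula = "value ~ C(group) + C(bin)"
    if interaction:
        formula += " + C(group):C(bin)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_resid = float(table.loc["Residual", "df"])
    degenerate = ss_resid <= 1e-12 * max(float(np.sum(df["value"] ** 2)), 1.0)
    f = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    if degenerate:
        f, p = np.inf, 0.0

    groups = sorted(df["group"].unique())
    a = df.loc[df["group"] == groups[0], "value"].to_numpy()
    b = df.loc[df["group"] == groups[1], "value"].to_numpy() if len(groups) > 1 else a
    try:
        effect = cohens_d(a, b)
    except ValueError:
        effect = np.nan
    return GroupComparison(
        test="anova2",
        statistic=f,
        p_value=p,
        effect_size=effect,
        effect_size_name="cohens_d",
        n_a=int(a.size),
        n_b=int(b.size),
        descriptives=_descriptives(a, b, "mean_sem"),
        df=(float(table.loc["C(group)", "df"]), df_resid),
        degenerate=degenerate,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; no correction is applied by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out
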