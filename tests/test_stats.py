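import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from popnoise.stats import (
    anova2,
    benjamini_hochberg,
    cliffs_delta,
    cohens_d,
    exclude_outliers_3sigma,
    mann_whitney,
)
from popnoise.unit_metrics import roc_snr


def test_3sigma_removes_gross_outlier():
    values = [1.0] * 20 + [100.0]
    kept = exclude_outliers_3sigma(values)
    assert 100.0 not in kept
    assert kept.size == 20


def test_3sigma_all_equal_unchanged():
    kept = exclude_outliers_3sigma([2.0] * 5)
    assert list(kept) == [2.0] * 5


def test_3sigma_normal_tail_fraction():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(10_000)
    kept = exclude_outliers_3sigma(x)
    frac = 1 - kept.size / x.size
    assert 0.001 < frac < 0.006  # ~0.27% expected


def test_3sigma_single_pass_not_iterated():
    x = np.array([0.0] * 30 + [10.0, 12.0])
    once = exclude_outliers_3sigma(x)
    twice = exclude_outliers_3sigma(once)
    # the second pass removes more; the function must do only one
    assert once.size >= twice.size
    assert once.size == 30 or once.size == 31 or once.size == 32


def test_mann_whitney_identical_groups():
    cmp = mann_whitney([1, 2, 3], [1, 2, 3])
    assert cmp.p_value == pytest.approx(1.0, abs=0.05)


def test_mann_whitney_exact_enumeration_example():
    cmp = mann_whitney([1, 2, 3], [4, 5, 6])
    assert cmp.statistic == 0.0
    assert cmp.p_value == pytest.approx(0.1)


def test_mann_whitney_exact_matches_scipy_no_ties():
    rng = np.random.default_rng(1)
    for _ in range(10):
        perm = rng.permutation(1000).astype(float)  # disjoint values: no ties
        x, y = perm[:6], perm[6:13]
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_mann_whitney_descriptives_median_iqr():
    cmp = mann_whitney([1, 2, 3, 4], [10, 20, 30, 40])
    assert cmp.descriptives["a"]["median"] == 2.5
    assert cmp.descriptives["b"]["median"] == 25.0
    assert cmp.descriptives["b"]["iqr"] == pytest.approx(15.0)


def test_mann_whitney_monotone_transform_invariance():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
    p1 = mann_whitney(x, y).p_value
    p2 = mann_whitney(np.exp(x), np.exp(y)).p_value
    assert p1 == pytest.approx(p2)


def test_cliffs_delta_examples():
    assert cliffs_delta([5, 6], [1, 2]) == 1.0
    assert cliffs_delta([1, 2], [1, 2]) == 0.0
    assert cliffs_delta([1, 2], [2, 3]) == pytest.approx(-0.75)


@settings(max_examples=60, deadline=None)
@given(
    x=st.lists(st.integers(0, 10), min_size=1, max_size=15),
    y=st.lists(st.integers(0, 10), min_size=1, max_size=15),
)
def test_cliffs_antisymmetry_and_auc_identity(x, y):
    d = cliffs_delta(x, y)
    assert d == pytest.approx(-cliffs_delta(y, x))
    assert -1.0 <= d <= 1.0
    # cross-module identity: delta = 2*AUC - 1
    assert d == pytest.approx(2 * roc_snr(x, y).auc - 1, abs=1e-12)


def test_cohens_d_examples():
    rng = np.random.default_rng(3)
    assert cohens_d([0, 1, 2], [0, 1, 2]) == 0.0
    assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)
    with pytest.raises(ValueError):
        cohens_d([1, 1, 1], [1, 1, 1])


def test_cohens_d_unit_difference():
    rng = np.random.default_rng(4)
    x = rng.normal(1.0, 1.0, 20_000)
    y = rng.normal(0.0, 1.0, 20_000)
    assert cohens_d(x, y) == pytest.approx(1.0, abs=0.05)


def anova_ss_oracle(values, group, bins):
    """From-scratch Type II sums of squares for the additive model."""
    import pandas as pd

    df = pd.DataFrame({"y": values, "g": group, "b": bins})
    grand = df["y"].mean()

    def rss(factors):
        # least squares fit of additive model with given factors
        import numpy as np

        x_cols = [np.ones(len(df))]
        for f in factors:
            levels = sorted(df[f].unique())[1:]
            for lv in levels:
                x_cols.append((df[f] == lv).astype(float).to_numpy())
        x = np.column_stack(x_cols)
        beta, *_ = np.linalg.lstsq(x, df["y"].to_numpy(), rcond=None)
        resid = df["y"].to_numpy() - x @ beta
        return float(resid @ resid)

    ss_g = rss(["b"]) - rss(["g", "b"])   # Type II: group after bin
    ss_res = rss(["g", "b"])
    df_g = df["g"].nunique() - 1
    df_res = len(df) - 1 - df_g - (df["b"].nunique() - 1)
    return (ss_g / df_g) / (ss_res / df_res)


def test_anova2_matches_ss_oracle():
    rng = np.random.default_rng(5)
    n = 20
    groups = np.repeat(["a", "b"], 3 * n)
    bins = np.tile(np.repeat(["x", "y", "z"], n), 2)
    values = rng.normal(0, 1, 6 * n) + (groups == "b") * 1.0
    cmp = anova2(values, groups, bins)
    f_oracle = anova_ss_oracle(values, groups, bins)
    assert cmp.statistic == pytest.approx(f_oracle, abs=1e-10)
    assert cmp.df[0] == 1.0


def test_anova2_null_effect():
    rng = np.random.default_rng(6)
    groups = np.repeat(["a", "b"], 60)
    bins = np.tile(np.repeat(["x", "y", "z"], 20), 2)
    base = rng.normal(0, 1, 60)
    values = np.concatenate([base, base])  # identical cell data per group
    cmp = anova2(values, groups, bins)
    assert cmp.statistic == pytest.approx(0.0, abs=1e-20)
    assert cmp.p_value == pytest.approx(1.0)


def test_anova2_degenerate_zero_residual():
    groups = np.repeat(["a", "b"], 6)
    bins = np.tile(np.repeat(["x", "y", "z"], 2), 2)
    values = (groups == "b") * 1.0 + (bins == "y") * 0.5  # exact additive fit
    cmp = anova2(values, groups, bins)
    assert cmp.degenerate
    assert np.isinf(cmp.statistic)


def test_anova2_single_level_raises():
    with pytest.raises(ValueError):
        anova2([1, 2, 3], ["a", "a", "a"], ["x", "y", "x"])


def test_benjamini_hochberg_monotone():
    p = np.array([0.001, 0.02, 0.03, 0.5])
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
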