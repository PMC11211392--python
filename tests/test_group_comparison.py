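import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shgtex import (
    PARAMETER_NAMES,
    compare_parameter_tables,
    dagostino_pearson,
    significance_tier,
    students_t,
)


def permutation_p_value(a, b):
    """Exact two-sided permutation p for the pooled-t statistic."""
    pooled = np.concatenate([a, b])
    t_obs = abs(students_t(a, b)[0])
    n_a = len(a)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        t_perm = abs(students_t(pooled[sel], pooled[~sel])[0])
        count += t_perm >= t_obs - 1e-12
        total += 1
    return count / total


def make_table(rng, n, shift=0.0):
    data = {"source_id": [f"img{i}" for i in range(n)]}
    for k, name in enumerate(PARAMETER_NAMES):
        data[name] = rng.normal(k + shift, 1.0, size=n)
    return pd.DataFrame(data)


def test_hand_computed_pooled_t():
    t, p, df = students_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
    assert t == pytest.approx(-1.0)
    assert df == 8
    assert p == pytest.approx(0.3466, abs=5e-4)


def test_identical_groups_give_t_zero_p_one(rng):
    x = rng.normal(size=10)
    t, p, _ = students_t(x, x)
    assert t == 0.0
    assert p == 1.0


def test_swap_flips_sign_keeps_p(rng):
    a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
    t1, p1, df1 = students_t(a, b)
    t2, p2, df2 = students_t(b, a)
    assert t2 == pytest.approx(-t1)
    assert p2 == pytest.approx(p1)
    assert df1 == df2 == 25


@pytest.mark.parametrize("seed", range(3))
def test_agrees_with_exact_permutation_test(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=6)
    b = rng.normal(0.8, 1.0, size=6)
    _, p_t, _ = students_t(a, b)
    p_perm = permutation_p_value(a, b)
    assert p_t == pytest.approx(p_perm, abs=0.06)


def test_zero_variance_handling():
    t, p, _ = students_t([3.0, 3.0, 3.0], [3.0, 3.0])
    assert (t, p) == (0.0, 1.0)
    with pytest.raises(ValueError, match="zero pooled variance"):
        students_t([3.0, 3.0], [4.0, 4.0])


def test_normality_test_size_under_the_null():
    # rejection rate near the nominal 5%, within binomial tolerance for 200 reps
    rng = np.random.default_rng(42)
    rejections = sum(
        dagostino_pearson(rng.normal(size=10_000))[1] <= 0.05 for _ in range(200)
    )
    assert abs(rejections / 200 - 0.05) <= 0.03


def test_normality_test_power_against_heavy_skew(rng):
    _, p = dagostino_pearson(rng.exponential(size=200))
    assert p < 0.01


def test_symmetric_sample_kills_skewness_term(rng):
    half = rng.normal(size=500)
    x = np.concatenate([half, -half])  # exactly mirror-symmetric
    k2, _ = dagostino_pearson(x)
    z_skew = stats.skewtest(x).statistic
    z_kurt = stats.kurtosistest(x).statistic
    assert z_skew == pytest.approx(0.0, abs=1e-10)
    assert k2 == pytest.approx(z_kurt**2, abs=1e-8)


def test_normality_test_input_validation():
    with pytest.raises(ValueError, match="insufficient"):
        dagostino_pearson(np.arange(10))
    with pytest.raises(ValueError, match="variance"):
        dagostino_pearson(np.full(25, 1.0))


def test_tier_mapping_matches_star_legend():
    assert significance_tier(0.2) == "ns"
    assert significance_tier(0.049) == "*"
    assert significance_tier(0.009) == "**"
    assert significance_tier(0.0009) == "***"
    assert significance_tier(0.00009) == "****"
    assert significance_tier(0.05) == "ns"  # strict inequality at the cutpoint


def test_table_compared_to_itself_yields_nothing_significant(rng):
    table = make_table(rng, 30)
    res = compare_parameter_tables(table, table.copy())
    assert res.n_significant == 0
    np.testing.assert_allclose(res.rows["p_value"].to_numpy(), 1.0)
    assert (res.rows["tier"] == "ns").all()


def test_overwhelming_shift_makes_all_parameters_significant(rng):
    a = make_table(rng, 30)
    b = make_table(rng, 30, shift=5.0)  # 5 pooled SDs
    res = compare_parameter_tables(a, b)
    assert res.n_significant == 12
    assert (res.rows["tier"] == "****").all()


def test_undefined_sentinels_dropped_and_sparse_rows_flagged(rng):
    a = make_table(rng, 30)
    b = make_table(rng, 30)
    a.loc[0:2, "skewness"] = np.nan  # a few undefined tiles
    b.loc[:, "correlation"] = np.nan
    b.loc[0, "correlation"] = 1.0  # only one defined value
    res = compare_parameter_tables(a, b)
    skew_row = res.rows.set_index("parameter").loc["skewness"]
    assert skew_row["n1"] == 27
    corr_row = res.rows.set_index("parameter").loc["correlation"]
    assert corr_row["tier"] == "insufficient data"
    assert res.n_evaluated == 11


def test_null_rejection_rate_of_full_comparison(rng):
    hits = np.zeros(len(PARAMETER_NAMES))
    reps = 150
    for _ in range(reps):
        res = compare_parameter_tables(make_table(rng, 15), make_table(rng, 15))
        hits += (res.rows["p_value"] < 0.05).to_numpy()
    assert (np.abs(hits / reps - 0.05) <= 0.05).all()


def test_holm_correction_is_monotone_and_conservative(rng):
    a = make_table(rng, 25)
    b = make_table(rng, 25, shift=0.5)
    plain = compare_parameter_tables(a, b)
    holm = compare_parameter_tables(a, b, correction="holm")
    bonf = compare_parameter_tables(a, b, correction="bonferroni")
    assert holm.n_significant <= plain.n_significant
    assert bonf.n_significant <= holm.n_significant
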