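import math

import numpy as np
import pytest

from footsga import (
    compare_two_groups,
    hedges_g,
    lilliefors,
    pearson_bootstrap,
    select_subgroup,
    two_way_anova,
)

from _oracles import anova_ss_oracle


# ---------------------------------------------------------------------------
# Hedges' g


def test_hedges_g_hand_computed_example():
    """x={0,2}, y={1,3}: quotient -1/sqrt(2); J = 1 - 3/7 = 4/7."""
    raw = hedges_g([0, 2], [1, 3], correct=False)
    assert raw.g == pytest.approx(-1 / math.sqrt(2))
    corrected = hedges_g([0, 2], [1, 3])
    assert corrected.g == pytest.approx((-1 / math.sqrt(2)) * (4 / 7))
    assert corrected.g == pytest.approx(-0.404, abs=0.001)
    assert corrected.correction_applied and not raw.correction_applied


def test_hedges_g_zero_for_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    assert hedges_g(x, list(x)).g == 0.0


def test_hedges_g_antisymmetry_and_affine_invariance(rng):
    x = rng.normal(0, 1, 15)
    y = rng.normal(0.5, 1.2, 12)
    assert hedges_g(x, y).g == pytest.approx(-hedges_g(y, x).g)
    a, c = 3.7, -2.2
    assert hedges_g(a * x + c, a * y + c).g == pytest.approx(hedges_g(x, y).g)


def test_correction_always_shrinks():
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.normal(0, 1, int(rng.integers(2, 25)))
        y = rng.normal(1, 1, int(rng.integers(2, 25)))
        assert abs(hedges_g(x, y).g) < abs(hedges_g(x, y, correct=False).g)


def test_hedges_g_zero_pooled_sd_rejected():
    with pytest.raises(ValueError):
        hedges_g([1.0, 1.0], [1.0, 1.0])


# ---------------------------------------------------------------------------
# Lilliefors


def test_lilliefors_statistic_matches_statsmodels(rng):
    """Statistic agrees with the independent table-based implementation."""
    from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

    for n in (10, 25, 60):
        x = rng.normal(3.0, 2.0, n)
        ours = lilliefors(x, n_sims=2000, seed=1)
        d_sm, p_sm = sm_lilliefors(x, dist="norm")
        assert ours.statistic == pytest.approx(d_sm, abs=1e-12)
        assert ours.p_value == pytest.approx(min(p_sm, 0.999), abs=0.08)


def test_lilliefors_location_scale_invariance(rng):
    x = rng.normal(0, 1, 30)
    a = lilliefors(x, n_sims=500, seed=0)
    b = lilliefors(5.0 * x - 3.0, n_sims=500, seed=0)
    assert a.statistic == pytest.approx(b.statistic)
    assert a.p_value == b.p_value


def test_lilliefors_rejects_uniform(rng):
    x = rng.uniform(0, 1, 1000)
    assert lilliefors(x, n_sims=2000, seed=0).p_value < 0.01


def test_lilliefors_degenerate_inputs():
    with pytest.raises(ValueError):
        lilliefors([1.0, 1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        lilliefors([1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# two-group comparison


def test_identical_groups_show_no_difference(rng):
    x = rng.normal(0, 1, 20)
    res = compare_two_groups(x, x.copy(), n_sims=500)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_three_sd_shift_is_detected(rng):
    x = rng.normal(0, 1, 20)
    y = rng.normal(3, 1, 20)
    res = compare_two_groups(x, y, n_sims=500)
    assert res.p_value < 0.001
    assert res.method == "t"


def test_heavy_tailed_sample_switches_to_rank_test(rng):
    x = rng.standard_cauchy(60)
    y = rng.normal(0, 1, 60)
    res = compare_two_groups(x, y, n_sims=2000)
    assert res.method == "mann-whitney"


def test_small_samples_rejected():
    with pytest.raises(ValueError):
        compare_two_groups([1, 2, 3], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# two-way ANOVA


def _toy_2x2x5(rng):
    vals, grp, side = [], [], []
    means = {("A", "L"): 1.0, ("A", "R"): 2.0, ("B", "L"): 4.0, ("B", "R"): 3.5}
    for (g, s), m in means.items():
        for _ in range(5):
            vals.append(m + rng.normal(0, 0.8))
            grp.append(g)
            side.append(s)
    return np.array(vals), grp, side


def test_anova_sums_of_squares_match_cell_means_oracle(rng):
    vals, grp, side = _toy_2x2x5(rng)
    res = two_way_anova(vals, grp, side)
    oracle = anova_ss_oracle(vals, grp, side)
    assert res.table.loc["C(group)", "sum_sq"] == pytest.approx(oracle["group"])
    assert res.table.loc["C(side)", "sum_sq"] == pytest.approx(oracle["side"])
    assert res.table.loc["C(group):C(side)", "sum_sq"] == pytest.approx(
        oracle["interaction"]
    )
    assert res.table.loc["Residual", "sum_sq"] == pytest.approx(oracle["error"])


def test_anova_ss_decomposition_on_random_balanced_data(rng):
    vals = rng.normal(0, 1, 40)
    grp = ["A"] * 20 + ["B"] * 20
    side = (["L"] * 10 + ["R"] * 10) * 2
    res = two_way_anova(vals, grp, side)
    oracle = anova_ss_oracle(vals, grp, side)
    parts = (
        res.table.loc["C(group)", "sum_sq"]
        + res.table.loc["C(side)", "sum_sq"]
        + res.table.loc["C(group):C(side)", "sum_sq"]
        + res.table.loc["Residual", "sum_sq"]
    )
    assert parts == pytest.approx(oracle["total"], rel=1e-9)


def test_pure_group_effect_design(rng):
    vals = np.concatenate([rng.normal(10, 1, 20), rng.normal(0, 1, 20)])
    grp = ["A"] * 20 + ["B"] * 20
    side = (["L"] * 10 + ["R"] * 10) * 2
    res = two_way_anova(vals, grp, side)
    assert res.p_group < 1e-6
    assert res.p_side > 0.01
    assert not res.tukey.empty


def test_identical_values_give_no_effect_output():
    res = two_way_anova([1.0] * 20, ["A"] * 10 + ["B"] * 10, ["L", "R"] * 10)
    assert res.degenerate
    assert res.p_group == 1.0 and res.f_group == 0.0


def test_empty_cell_rejected():
    with pytest.raises(ValueError):
        two_way_anova([1, 2, 3, 4], ["A", "A", "B", "B"], ["L", "L", "L", "L"])


# ---------------------------------------------------------------------------
# subgroup selection


def test_subgroup_threshold_hand_arithmetic():
    """Controls {5,10,15}: mean 10 + sample SD 5 -> threshold 15 (strict)."""
    res = select_subgroup([15.0, 15.01, 20.0], [5.0, 10.0, 15.0])
    assert res.threshold == pytest.approx(15.0)
    assert res.mask.tolist() == [False, True, True]
    assert res.n_selected == 2


def test_subgroup_can_be_empty():
    res = select_subgroup([1.0, 2.0], [5.0, 10.0, 15.0])
    assert res.n_selected == 0


def test_subgroup_requires_controls():
    with pytest.raises(ValueError):
        select_subgroup([1.0], [5.0])


# ---------------------------------------------------------------------------
# bootstrap correlation


def test_collinear_data_give_degenerate_ci():
    x = np.arange(10.0)
    res = pearson_bootstrap(x, 2 * x + 1, seed=0)
    assert res.r == pytest.approx(1.0)
    assert (res.ci_low, res.ci_high) == (1.0, 1.0)


def test_correlation_antisymmetry(rng):
    x = rng.normal(0, 1, 25)
    y = x + rng.normal(0, 0.5, 25)
    a = pearson_bootstrap(x, y, seed=3)
    b = pearson_bootstrap(x, -y, seed=3)
    assert a.r == pytest.approx(-b.r)


def test_bootstrap_is_seed_reproducible(rng):
    x = rng.normal(0, 1, 20)
    y = 0.5 * x + rng.normal(0, 1, 20)
    a = pearson_bootstrap(x, y, seed=11)
    b = pearson_bootstrap(x, y, seed=11)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    c = pearson_bootstrap(x, y, seed=12)
    assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)


def test_percentile_ci_contains_point_estimate(rng):
    x = rng.normal(0, 1, 30)
    y = 0.6 * x + rng.normal(0, 0.8, 30)
    res = pearson_bootstrap(x, y, seed=1, ci_type="percentile")
    assert res.ci_low <= res.r <= res.ci_high
    assert -1.0 <= res.ci_low <= res.ci_high <= 1.0


def test_zero_variance_rejected():
    with pytest.raises(ValueError):
        pearson_bootstrap([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
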