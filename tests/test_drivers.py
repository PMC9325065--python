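"""Mixed-model driver statistics: grouping, contrasts, stratified fits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import shootflux as sf
from shootflux.drivers import compact_letter_display


# --- period assignment ------------------------------------------------------


def test_first_date_is_period_one_and_boundary_is_half_open():
    dates = pd.to_datetime(["2020-03-06", "2020-03-19", "2020-03-20"])
    labels = sf.assign_periods(dates, 14)
    assert list(labels) == [1, 1, 2]


def test_periods_match_calendar_loop_oracle():
    rng = np.random.default_rng(1)
    first = pd.Timestamp("2020-03-06")
    dates = [first + pd.Timedelta(days=int(d)) for d in rng.integers(0, 90, 100)]
    dates[0] = first  # anchor
    labels = sf.assign_periods(dates, 14)
    oracle = [((d - first).days // 14) + 1 for d in dates]
    assert list(labels) == oracle


# --- mixed model ------------------------------------------------------------


def _sim_table(n_per_tree=50, n_trees=4, slope=0.5, ri_sd=0.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 10, n_per_tree)
    rows = []
    for t in range(n_trees):
        u = rng.normal(0, ri_sd) if ri_sd else 0.0
        y = 1.0 + slope * x + u + rng.normal(0, noise, n_per_tree)
        rows.append(pd.DataFrame({"tree_id": f"T{t}", "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


def test_zero_random_intercept_matches_ols_slope():
    table = _sim_table(ri_sd=0.0, seed=3)
    lmm = sf.fit_lmm(table, "y", ["x"])
    ols = sm.OLS(table["y"], sm.add_constant(table["x"])).fit()
    assert lmm.coef("x") == pytest.approx(float(ols.params.iloc[1]), abs=1e-6)


def test_single_group_reduces_to_ols_exactly():
    table = _sim_table(n_trees=1, ri_sd=0.0, seed=4)
    lmm = sf.fit_lmm(table, "y", ["x"])
    ols = sm.OLS(table["y"], sm.add_constant(table["x"])).fit()
    assert lmm.flags.get("ols_fallback")
    assert lmm.coef("x") == pytest.approx(float(ols.params.iloc[1]), rel=1e-12)


def test_constant_response_gives_zero_slope_and_spread():
    table = _sim_table(slope=0.0, noise=0.0, seed=5)
    table["y"] = 2.0
    lmm = sf.fit_lmm(table, "y", ["x"])
    assert lmm.coef("x") == 0.0
    assert lmm.residual_sd == 0.0


def test_slope_coverage_with_random_intercepts():
    """The fixed-slope CI covers the simulated truth at close to nominal
    rate in the presence of tree-level intercepts."""
    hits, reps = 0, 100
    for i in range(reps):
        table = _sim_table(n_per_tree=50, n_trees=4, slope=0.5, ri_sd=1.0, seed=100 + i)
        lmm = sf.fit_lmm(table, "y", ["x"])
        hits += abs(lmm.coef("x") - 0.5) <= 2 * lmm.se("x")
    assert hits / reps >= 0.88


def test_too_few_rows_rejected():
    table = _sim_table(n_per_tree=2, n_trees=2)
    with pytest.raises(ValueError):
        sf.fit_lmm(table.head(6), "y", ["x"])


# --- period comparisons and CLD ---------------------------------------------


def _period_table(shift=0.0, n=40, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for period, mu in ((1, 0.0), (2, shift)):
        for t in range(4):
            y = mu + rng.normal(0, 1.0, n // 4)
            rows.append(
                pd.DataFrame({"tree_id": f"T{t}", "period": period, "ch4_dw_flux": y})
            )
    return pd.concat(rows, ignore_index=True)


def test_single_period_gets_single_letter():
    table = _period_table().query("period == 1")
    out = sf.compare_period_means(table)
    assert out["letters"] == {1: "a"}


def test_identical_periods_share_a_letter():
    out = sf.compare_period_means(_period_table(shift=0.0, seed=8))
    letters = out["letters"]
    assert set(letters[1]) & set(letters[2])


def test_strongly_shifted_period_gets_distinct_letter():
    out = sf.compare_period_means(_period_table(shift=10.0, seed=9))
    letters = out["letters"]
    assert not (set(letters[1]) & set(letters[2]))


def test_sparse_period_excluded_with_note():
    table = _period_table(seed=10)
    extra = table.iloc[[0]].copy()
    extra["period"] = 9
    out = sf.compare_period_means(pd.concat([table, extra], ignore_index=True))
    assert out["excluded_periods"] == [9]


def test_cld_letters_encode_difference_structure():
    # a != c, everything else undistinguished: a and c must not share
    different = {(1, 2): False, (1, 3): True, (2, 3): False}
    letters = compact_letter_display([1, 2, 3], different)
    assert set(letters[1]) & set(letters[2])
    assert set(letters[2]) & set(letters[3])
    assert not (set(letters[1]) & set(letters[3]))


# --- t-tests against the blank chamber --------------------------------------


def test_identical_samples_give_p_one():
    x = np.arange(10.0)
    out = sf.ttest_vs_empty({"s1": x}, x)
    assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc[0, "p"] == pytest.approx(1.0)


def test_ten_sigma_shift_is_detected():
    rng = np.random.default_rng(11)
    empty = rng.normal(10, 2, 30)
    shoot = rng.normal(10 + 10 * 2, 2, 30)
    out = sf.ttest_vs_empty({"s1": shoot}, empty)
    assert out.loc[0, "p"] < 0.001


def test_insufficient_n_flagged_not_raised():
    out = sf.ttest_vs_empty({"s1": [1.0, 2.0]}, np.arange(10.0))
    assert out.loc[0, "insufficient_n"]
    assert np.isnan(out.loc[0, "p"])


def test_welch_decision_matches_permutation_oracle():
    """Accept/reject at alpha=0.05 agrees with a permutation test on the
    mean difference in >= 95% of simulated shoots."""
    rng = np.random.default_rng(12)
    agree, reps = 0, 100
    for i in range(reps):
        shift = rng.choice([0.0, 1.5])
        empty = rng.normal(10, 2, 25)
        shoot = rng.normal(10 + shift, 3, 25)
        p_welch = sf.ttest_vs_empty({"s": shoot}, empty).loc[0, "p"]
        pooled = np.concatenate([shoot, empty])
        obs = abs(shoot.mean() - empty.mean())
        perm = np.array(
            [
                abs(np.mean(z[:25]) - np.mean(z[25:]))
                for z in (rng.permutation(pooled) for _ in range(400))
            ]
        )
        p_perm = (1 + np.sum(perm >= obs)) / 401
        agree += (p_welch < 0.05) == (p_perm < 0.05)
    assert agree / reps >= 0.95


# --- PAR split --------------------------------------------------------------


def _driver_table(beta_low=0.0, beta_high=0.0, n=240, seed=0, ri_sd=0.5):
    rng = np.random.default_rng(seed)
    par = rng.uniform(0, 1500, n)
    temp = rng.uniform(0, 20, n)
    tree = rng.integers(0, 4, n)
    u = rng.normal(0, ri_sd, 4)
    beta = np.where(par >= 500, beta_high, beta_low)
    y = 1.0 + beta * temp + u[tree] + rng.normal(0, 1.0, n)
    return pd.DataFrame(
        {"tree_id": [f"T{t}" for t in tree], "par": par, "air_temp": temp,
         "ch4_dw_flux": y}
    )


def test_high_par_only_temperature_effect_detected():
    table = _driver_table(beta_low=0.0, beta_high=0.4, seed=13)
    out = sf.par_split_regression(table)
    assert out["high"]["p"] < 0.05
    assert out["low"]["p"] > 0.05


def test_threshold_above_all_par_flags_empty_stratum():
    table = _driver_table(seed=14)
    out = sf.par_split_regression(table, threshold=10000.0)
    assert out["high"]["empty"]
    assert not out["low"]["empty"]


def test_null_temperature_effect_within_two_ses():
    table = _driver_table(beta_low=0.0, beta_high=0.0, seed=15)
    out = sf.par_split_regression(table)
    for stratum in ("low", "high"):
        assert abs(out[stratum]["slope"]) <= 2.5 * out[stratum]["se"]


def test_boundary_rows_appear_in_both_strata():
    table = _driver_table(seed=16)
    table.loc[0, "par"] = 500.0
    out = sf.par_split_regression(table)
    assert out["low"]["n"] + out["high"]["n"] == len(table) + 1


# --- temperature-bin interaction --------------------------------------------


def test_helmert_matrix_is_orthogonal_and_centred():
    H = sf.helmert_matrix(4)
    assert H.shape == (4, 3)
    assert np.allclose(H.sum(axis=0), 0.0)
    gram = H.T @ H
    assert np.allclose(gram - np.diag(np.diag(gram)), 0.0)


def _interaction_table(slopes, n=400, seed=0):
    rng = np.random.default_rng(seed)
    par = rng.uniform(0, 1500, n)
    temp = rng.uniform(0, 20, n)
    tree = rng.integers(0, 4, n)
    u = rng.normal(0, 0.5, 4)
    bin_idx = np.minimum((temp // 5).astype(int), 3)
    y = 1.0 + np.asarray(slopes)[bin_idx] * par + u[tree] + rng.normal(0, 1.0, n)
    return pd.DataFrame(
        {"tree_id": [f"T{t}" for t in tree], "par": par, "air_temp": temp,
         "ch4_dw_flux": y}
    )


def test_increasing_par_slopes_detected_by_helmert_contrasts():
    table = _interaction_table([0.002, 0.004, 0.006, 0.008], seed=17)
    out = sf.temp_bin_interaction(table)
    slopes = [b["par_slope"] for b in out["per_bin"]]
    assert slopes == sorted(slopes)
    for c in out["helmert_contrasts"]:
        assert c["p"] < 0.05
        assert c["estimate"] > 0


def test_estimated_bin_slopes_near_truth():
    truth = [0.002, 0.004, 0.006, 0.008]
    table = _interaction_table(truth, n=800, seed=18)
    out = sf.temp_bin_interaction(table)
    for b, true_slope in zip(out["per_bin"], truth):
        assert b["par_slope"] == pytest.approx(true_slope, abs=3 * b["se"] + 1e-4)


def test_sparse_bin_merged_into_neighbour():
    table = _interaction_table([0.002, 0.004, 0.006, 0.008], n=300, seed=19)
    table = table[(table["air_temp"] < 14.0) | (table["air_temp"] > 19.7)]
    out = sf.temp_bin_interaction(table)
    if out["merged_bins"]:
        assert all(abs(a - b) >= 1 for a, b in out["merged_bins"])


def test_single_bin_rejected():
    table = _interaction_table([0.002] * 4, seed=20)
    table["air_temp"] = 2.0
    with pytest.raises(ValueError):
        sf.temp_bin_interaction(table)


# --- residual disentangling -------------------------------------------------


def _coupled_drivers(n=400, seed=0, rho=0.7):
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1, n)
    par = 700 + 400 * (rho * z + np.sqrt(1 - rho**2) * rng.normal(0, 1, n))
    temp = 10 + 5 * (rho * z + np.sqrt(1 - rho**2) * rng.normal(0, 1, n))
    return par, temp


def test_par_driven_flux_disentangled_from_correlated_temperature():
    par, temp = _coupled_drivers(seed=21)
    rng = np.random.default_rng(22)
    flux = 0.004 * par + rng.normal(0, 0.4, len(par))
    table = pd.DataFrame({"par": par, "air_temp": temp, "ch4_dw_flux": flux})
    out = sf.residual_disentangle(table)
    assert out["temp_resid_on_par"]["p"] < 0.05  # PAR explains what T cannot
    assert out["par_resid_on_temp"]["p"] > 0.05  # T adds nothing beyond PAR


def test_independent_drivers_both_detected():
    rng = np.random.default_rng(23)
    par = rng.uniform(0, 1500, 400)
    temp = rng.uniform(0, 20, 400)
    flux = 0.004 * par + 0.2 * temp + rng.normal(0, 0.5, 400)
    table = pd.DataFrame({"par": par, "air_temp": temp, "ch4_dw_flux": flux})
    out = sf.residual_disentangle(table)
    assert out["temp_resid_on_par"]["p"] < 0.05
    assert out["par_resid_on_temp"]["p"] < 0.05


def test_pure_noise_rarely_significant():
    rng = np.random.default_rng(24)
    hits = 0
    for i in range(40):
        par = rng.uniform(0, 1500, 100)
        temp = rng.uniform(0, 20, 100)
        flux = rng.normal(0, 1, 100)
        table = pd.DataFrame({"par": par, "air_temp": temp, "ch4_dw_flux": flux})
        out = sf.residual_disentangle(table)
        hits += out["temp_resid_on_par"]["p"] < 0.05
    assert hits / 40 <= 0.15
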