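import numpy as np
import pandas as pd
import pytest

from apctrend import (
    HorizonError,
    build_design,
    extend_effects,
    observed_yearly_means,
    project_cell_means,
    trend_series,
    yearly_mean_series,
)
from apctrend import validation as V


@pytest.fixture(scope="module")
def tiny_design():
    return build_design(9, 10, 2000, 2004)


def _deterministic_draws(design, pi_tail=(3.0, 5.0), tau=0.0):
    pi = np.array([0.0, 1.0, 1.0, *pi_tail])
    gamma = np.linspace(-1.0, 1.0, design.n_cohorts)
    return V.constant_draws(design, alpha=np.array([100.0, 104.0]), pi=pi,
                            gamma=gamma, tau_pi=tau, tau_gamma=tau)


def test_zero_tau_extension_is_exact_linear_continuation(tiny_design):
    draws = _deterministic_draws(tiny_design)
    ext = extend_effects(draws, horizon=3, seed=0)
    np.testing.assert_array_equal(
        ext.extensions["period"][0, 0], np.array([7.0, 9.0, 11.0])
    )
    # constant tail stays constant
    flat = V.constant_draws(tiny_design, np.zeros(2), np.full(5, 2.5),
                            np.zeros(tiny_design.n_cohorts))
    ext2 = extend_effects(flat, horizon=4, seed=0)
    np.testing.assert_array_equal(ext2.extensions["period"],
                                  np.full_like(ext2.extensions["period"], 2.5))


def test_horizon_zero_is_noop_and_negative_rejected(tiny_design):
    draws = _deterministic_draws(tiny_design)
    ext = extend_effects(draws, horizon=0, seed=0)
    assert ext.extensions == {}
    assert ext.base is draws
    with pytest.raises(ValueError):
        extend_effects(draws, horizon=-1, seed=0)


def test_stochastic_extension_mean_and_growing_variance(tiny_design):
    draws = _deterministic_draws(tiny_design, tau=1.0)
    draws = V.constant_draws(tiny_design, np.zeros(2),
                             np.array([0.0, 1.0, 1.0, 3.0, 5.0]),
                             np.zeros(tiny_design.n_cohorts),
                             tau_pi=1.0, tau_gamma=1.0, n_chains=2, n_kept=4000)
    ext = extend_effects(draws, horizon=5, seed=3)
    flat = ext.extensions["period"].reshape(-1, 5)
    linear = 5.0 + 2.0 * np.arange(1, 6)
    se = flat.std(axis=0, ddof=1) / np.sqrt(flat.shape[0])
    assert np.all(np.abs(flat.mean(axis=0) - linear) < 3 * se)
    v = flat.var(axis=0)
    assert np.all(np.diff(v) > 0)  # step-h variance grows with h


def test_cri_width_nondecreasing_in_forecast_step():
    res = V.cri_width_monotonicity(horizon=8, tau=0.5, seed=2)
    assert res["monotone"]


def test_projection_requires_cohort_coverage(tiny_design):
    draws = _deterministic_draws(tiny_design)
    ext = extend_effects(draws, horizon=2, seed=0)
    # period 2007 at age 9 needs cohort 1998 = 3 steps beyond 1995
    with pytest.raises(HorizonError, match="extension length 3"):
        project_cell_means(ext, periods=np.array([2005, 2007]),
                           ages=np.array([9]))


def test_required_cohort_extension_matches_horizon():
    """Projecting the surveillance design 10 years ahead needs exactly the
    10th cohort extension for the youngest age."""
    design = build_design(9, 18, 1999, 2014)
    pi = np.zeros(design.n_periods)
    draws = V.constant_draws(design, np.zeros(design.n_ages), pi,
                             np.zeros(design.n_cohorts), n_kept=5)
    ext = extend_effects(draws, horizon=10, seed=0)
    assert ext.future_grids["period"][-1] == 2024
    assert ext.future_grids["cohort"][-1] == 2015  # = 2024 - 9
    cells = project_cell_means(ext)  # must not raise
    assert cells.periods.tolist() == list(range(2015, 2025))


def test_deterministic_projection_is_additive_sum(tiny_design):
    draws = _deterministic_draws(tiny_design)
    ext = extend_effects(draws, horizon=2, seed=0)
    cells = project_cell_means(ext, periods=np.array([2005]), ages=np.array([10]))
    # alpha=104, pi(2005)=7 (linear continuation), gamma(1995)=1
    assert cells.draws[0, 0, 0, 0] == pytest.approx(104.0 + 7.0 + 1.0)


def test_projection_at_observed_final_period_reproduces_fit(fitted_draws):
    ext = extend_effects(fitted_draws, horizon=3, seed=5)
    d = fitted_draws.design
    last = int(d.periods[-1])
    cells = project_cell_means(ext, periods=np.array([last]))
    direct = fitted_draws.cell_mean_draws(d.ages, np.full(d.n_ages, last))
    np.testing.assert_array_equal(cells.draws[:, :, :, 0], direct)


def test_yearly_mean_series_weights(tiny_design):
    draws = V.constant_draws(tiny_design, np.array([10.0, 14.0]), np.zeros(5),
                             np.zeros(tiny_design.n_cohorts))
    ext = extend_effects(draws, horizon=0, seed=0)
    cells = project_cell_means(ext, periods=tiny_design.periods)
    equal = yearly_mean_series(cells)
    assert np.allclose(equal["mean"], 12.0)
    single = project_cell_means(ext, periods=tiny_design.periods,
                                ages=np.array([10]))
    one = yearly_mean_series(single)
    assert np.allclose(one["mean"], 14.0)
    weighted = yearly_mean_series(cells, age_weights=np.array([3.0, 1.0]))
    assert np.allclose(weighted["mean"], 11.0)


def test_projected_series_slope_tracks_rising_period_truth(tiny_design):
    """A posterior whose period effects rise linearly must project a rising
    yearly series."""
    pi = np.arange(5, dtype=float)
    draws = V.constant_draws(tiny_design, np.array([100.0, 100.0]), pi,
                             np.zeros(tiny_design.n_cohorts))
    ext = extend_effects(draws, horizon=5, seed=1)
    series = trend_series(ext)
    proj = series[series["kind"] == "projected"]["mean"].to_numpy()
    assert np.all(np.diff(proj) > 0)


def test_observed_yearly_means_raw_and_missing_age(tiny_design):
    table = pd.DataFrame({
        "sex": "male", "age": [9, 10, 9], "period": [2000, 2000, 2001],
        "n": 5, "mean": [10.0, 14.0, 11.0],
    })
    obs = observed_yearly_means(table[table["period"] == 2000], tiny_design)
    assert obs["mean"].iloc[0] == 12.0
    with pytest.raises(ValueError, match="missing ages"):
        observed_yearly_means(table, tiny_design)
    part = observed_yearly_means(table, tiny_design, partial_years=True)
    assert part.set_index("year").loc[2001, "mean"] == 11.0
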