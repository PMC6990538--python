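import warnings

import numpy as np
import pandas as pd
import pytest

from apctrend import (
    FitConfig,
    IdentifiabilityError,
    build_design,
    build_design_matrix,
    compare_models,
    default_constraints,
    dic,
    fit_apc,
    penalized_fit,
    rhat,
    summarize,
    truth_to_cell_means,
)
from apctrend import validation as V
from apctrend.apcmodel import PosteriorDraws, _split_rhat_1d, second_difference_matrix


def _full_table(design, value=100.0, n=50):
    rows = [("male", int(a), int(p), int(p - a), "", n, value, 1.0)
            for a in design.ages for p in design.periods]
    return pd.DataFrame(rows, columns=["sex", "age", "period", "cohort_index",
                                       "cohort_label", "n", "mean", "sd"])


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def test_full_bp_design_matrix_rank():
    design = build_design(9, 18, 1999, 2014)
    X, blocks = build_design_matrix(_full_table(design), design)
    assert X.shape == (160, 48)  # 10 age + 14 period + 24 cohort columns
    assert np.linalg.matrix_rank(X) == 48


def test_single_cell_design_single_age_column():
    design = build_design(5, 5, 2000, 2000)
    X, blocks = build_design_matrix(_full_table(design), design)
    assert X.shape == (1, 1)
    assert blocks[0].name == "age"


def test_removing_period_constraints_gives_rank_deficit_two():
    design = build_design(9, 13, 2000, 2005)
    table = _full_table(design)
    cons = default_constraints(design, ("age", "period", "cohort"))
    cons = {**cons, "period": ()}
    with pytest.raises(IdentifiabilityError, match="deficit 2"):
        build_design_matrix(table, design, constraints=cons)


def test_constraint_columns_absent():
    design = build_design(9, 13, 2000, 2005)
    _, blocks = build_design_matrix(_full_table(design), design)
    per = next(b for b in blocks if b.name == "period")
    assert set(per.constrained) == {design.ref_period_low, design.ref_period_high}
    coh = next(b for b in blocks if b.name == "cohort")
    assert set(coh.constrained) == {design.ref_cohort}


# ---------------------------------------------------------------------------
# penalized (closed-form) fit
# ---------------------------------------------------------------------------

def test_penalized_fit_recovers_noise_free_cell_means(small_design, small_truth):
    oracle = truth_to_cell_means(small_truth, small_design)
    params = penalized_fit(oracle, small_design)  # tau = inf: no smoothing
    mu = params.cell_mean(oracle["age"].to_numpy(), oracle["period"].to_numpy(),
                          small_design)
    np.testing.assert_allclose(mu, oracle["mean"].to_numpy(), atol=1e-8)
    # constraints hold exactly
    P = small_design
    assert params.pi[np.searchsorted(P.periods, P.ref_period_low)] == 0.0
    assert params.pi[np.searchsorted(P.periods, P.ref_period_high)] == 0.0
    assert params.gamma[np.searchsorted(P.cohorts, P.ref_cohort)] == 0.0


def test_tau_to_zero_forces_linear_period_effects(small_design):
    """The RW2 penalty null space is linear functions: tau -> 0 collapses the
    period effects onto the line through the two zero references, i.e. zero."""
    table = _full_table(small_design)
    rng = np.random.default_rng(3)
    table["mean"] = 100 + rng.normal(0, 1, len(table))
    params = penalized_fit(table, small_design, tau_pi=1e-8)
    d2 = second_difference_matrix(small_design.n_periods) @ params.pi
    np.testing.assert_allclose(d2, 0.0, atol=1e-6)
    np.testing.assert_allclose(params.pi, 0.0, atol=1e-6)


def test_penalized_fit_rejects_nonpositive_hyperparameters(small_design):
    table = _full_table(small_design)
    with pytest.raises(ValueError):
        penalized_fit(table, small_design, tau_pi=0.0)
    with pytest.raises(ValueError):
        penalized_fit(table, small_design, sigma=-1.0)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def test_fit_is_deterministic_given_seed(small_table, small_design):
    cfg = FitConfig(chains=2, iterations=60, seed=5, max_doublings=0,
                    rhat_threshold=np.inf)
    a = fit_apc(small_table, small_design, cfg)
    b = fit_apc(small_table, small_design, cfg)
    for name in a.effects:
        np.testing.assert_array_equal(a.effects[name], b.effects[name])
    np.testing.assert_array_equal(a.sigma, b.sigma)


def test_constraints_hold_on_every_draw(fitted_draws):
    d = fitted_draws.design
    pi = fitted_draws.effects["period"]
    gamma = fitted_draws.effects["cohort"]
    assert np.all(pi[:, :, np.searchsorted(d.periods, d.ref_period_low)] == 0.0)
    assert np.all(pi[:, :, np.searchsorted(d.periods, d.ref_period_high)] == 0.0)
    assert np.all(gamma[:, :, np.searchsorted(d.cohorts, d.ref_cohort)] == 0.0)
    assert np.all(fitted_draws.sigma > 0)
    for arr in fitted_draws.taus.values():
        assert np.all(arr > 0)


def test_gibbs_posterior_mean_matches_penalized_mode(small_table, small_design):
    """With fixed hyperparameters the effect update samples the exact Gaussian
    posterior, so the Gibbs mean must match the closed-form mode within
    Monte-Carlo error."""
    res = V.oracle_equivalence_study(seed=3, iterations=1500, chains=2)
    assert res["max_abs_z"] < 3.0


def test_cell_means_invariant_to_constraint_choice(small_table, small_design):
    """Different valid corner constraints reparameterize the same fit: the
    fitted cell means must agree within Monte-Carlo error."""
    ages = small_table["age"].to_numpy()
    periods = small_table["period"].to_numpy()
    base = dict(chains=2, iterations=1500, max_doublings=0,
                fixed_sigma=0.4,
                fixed_taus={"age": 5.0, "period": 5.0, "cohort": 5.0})
    alt_cons = {
        "age": (),
        "period": (int(small_design.periods[0]), int(small_design.periods[-1])),
        "cohort": (int(small_design.cohorts[2]),),
    }
    a = fit_apc(small_table, small_design, FitConfig(seed=21, **base))
    b = fit_apc(small_table, small_design,
                FitConfig(seed=22, constraints=alt_cons, **base))
    mu_a = a.cell_mean_draws(ages, periods).reshape(-1, len(ages))
    mu_b = b.cell_mean_draws(ages, periods).reshape(-1, len(ages))
    diff = mu_a.mean(0) - mu_b.mean(0)
    se = np.sqrt(mu_a.var(0) / mu_a.shape[0] + mu_b.var(0) / mu_b.shape[0])
    assert np.max(np.abs(diff) / se) < 4.0


def test_unconverged_run_is_flagged_not_silent(small_table, small_design):
    cfg = FitConfig(chains=2, iterations=24, seed=1, max_doublings=0,
                    rhat_threshold=1.0001)
    with pytest.warns(UserWarning, match="not converged"):
        draws = fit_apc(small_table, small_design, cfg)
    assert not draws.converged
    assert draws.rhat_max > 1.0001


# ---------------------------------------------------------------------------
# R-hat
# ---------------------------------------------------------------------------

def test_rhat_identical_constant_chains_is_one():
    x = np.ones((3, 40))
    assert _split_rhat_1d(x) == 1.0


def test_rhat_separated_constant_chains_is_large():
    x = np.vstack([np.zeros(40), np.ones(40)])
    with pytest.warns(UserWarning):
        assert _split_rhat_1d(x) > 1.1


def test_rhat_iid_normal_draws_near_one():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((5, 500))
    assert _split_rhat_1d(x) < 1.05


def test_rhat_matches_arviz_split_method(fitted_draws):
    az = pytest.importorskip("arviz")
    ours = rhat(fitted_draws)
    theirs = float(az.rhat(fitted_draws.sigma, method="split"))
    assert abs(ours["sigma"] - theirs) < 1e-10
    j = int(np.searchsorted(fitted_draws.design.ages, 11))
    theirs_age = float(az.rhat(fitted_draws.effects["age"][:, :, j], method="split"))
    assert abs(ours["age[11]"] - theirs_age) < 1e-10


# ---------------------------------------------------------------------------
# summaries and DIC
# ---------------------------------------------------------------------------

def test_summarize_constant_and_constrained_positions(small_design):
    alpha = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    draws = V.constant_draws(small_design, alpha, np.zeros(6), np.zeros(10))
    s = summarize(draws).set_index("parameter")
    row = s.loc["age[9]"]
    assert row["mean"] == row["lower"] == row["upper"] == 1.0
    con = s.loc[f"period[{small_design.ref_period_low}]"]
    assert con["mean"] == 0.0 and con["lower"] == 0.0 and con["upper"] == 0.0


def test_summarize_quantiles_on_normal_draws(small_design):
    rng = np.random.default_rng(1)
    draws = V.constant_draws(small_design, np.zeros(5), np.zeros(6), np.zeros(10),
                             n_chains=2, n_kept=5000)
    draws.effects["age"][:, :, 0] = rng.standard_normal((2, 5000))
    s = summarize(draws).set_index("parameter")
    row = s.loc["age[9]"]
    assert abs(row["lower"] + 1.96) < 0.08 and abs(row["upper"] - 1.96) < 0.08
    assert abs(row["mean"]) < 0.05
    assert (s["lower"] <= s["mean"] + 1e-12).all()
    assert (s["mean"] <= s["upper"] + 1e-12).all()


def test_dic_degenerate_posterior_has_zero_pd(small_design, small_table):
    alpha = np.full(5, float(small_table["mean"].mean()))
    draws = V.constant_draws(small_design, alpha, np.zeros(6), np.zeros(10),
                             sigma=1.0)
    d = dic(draws, small_table, small_design)
    assert abs(d.pD) < 1e-8
    assert abs(d.DIC - d.Dbar) < 1e-8


def test_dic_prefers_period_model_when_period_signal_present(small_design,
                                                             small_truth):
    rng = np.random.default_rng(12)
    table = V.simulate_cell_means(small_truth, small_design, 200, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp = compare_models(table, small_design, models=("A", "AP"),
                             config=FitConfig(chains=2, iterations=400, seed=9,
                                              max_doublings=1))
    out = cmp.set_index("model")
    assert out.loc["AP", "DIC"] < out.loc["A", "DIC"]
    assert out.loc["AP", "best"]


def test_compare_models_single_model_single_row(small_table, small_design):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp = compare_models(small_table, small_design, models=("APC",),
                             config=FitConfig(chains=2, iterations=200, seed=2,
                                              max_doublings=0))
    assert len(cmp) == 1 and cmp["best"].iloc[0]
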