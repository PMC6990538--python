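"""Desk-scale validation studies for the APC pipeline.

The registry behind the published trend analysis is restricted, so the
pipeline is validated by (a) design bookkeeping and worked examples on
the published aggregate series, and (b) property/replicate studies on
model-generated data: sampler-vs-closed-form equivalence, credible
interval coverage, DIC model selection, curvature invariance, RW2
projection limits and joinpoint behaviour.  Every study is deterministic
given its seed and sized to run on one CPU in minutes.

Replicate studies simulate at the stratum level: a cell mean of n
independent Normal(mu, sd^2) outcomes is exactly Normal(mu, sd^2/n), so
cell means are drawn directly instead of materializing individual
records (the record-level path is exercised separately against the
noise-free oracle).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import datasets
from .apcmodel import (
    FitConfig,
    PosteriorDraws,
    dic,
    fit_apc,
    penalized_fit,
)
from .changepoints import joinpoint_fit
from .forecast import extend_effects
from .synthgen import APCTruth
from .tabulate import APCDesign, STRATUM_COLUMNS, build_design, cohort_label, design_summary


# ---------------------------------------------------------------------------
# small shared fixtures
# ---------------------------------------------------------------------------

def small_design() -> APCDesign:
    """The scaled-down 5-age x 6-period design used by the replicate studies."""
    return build_design(9, 13, 2000, 2005)


def small_truth(residual_sd: float = 5.0) -> APCTruth:
    """A curved, BP-like truth on :func:`small_design` (all effects informative)."""
    d = small_design()
    age_curve = {int(a): 100.0 + 1.5 * (a - 9) + 0.3 * (a - 9) ** 2 for a in d.ages}
    mid = int(d.periods[len(d.periods) // 2])
    period_curve = {int(p): 0.8 * abs(int(p) - mid) - 1.0 for p in d.periods}
    cohort_curve = {int(k): 0.25 * (int(k) - int(d.cohorts[0])) ** 2 * 0.1 for k in d.cohorts}
    return APCTruth(age_curve, period_curve, cohort_curve, residual_sd)


def simulate_cell_means(
    truth: APCTruth,
    design: APCDesign,
    n_per_cell: int,
    rng: np.random.Generator,
    sex: str = "male",
) -> pd.DataFrame:
    """Stratum table with cell means drawn Normal(mu, residual_sd^2 / n)."""
    rows = []
    se = truth.residual_sd / np.sqrt(n_per_cell)
    for p in design.periods:
        for a in design.ages:
            mu = truth.cell_mean(int(a), int(p))
            rows.append((sex, int(a), int(p), int(p - a), cohort_label(a, p),
                         n_per_cell, mu + rng.normal(0.0, se), truth.residual_sd))
    return pd.DataFrame(rows, columns=STRATUM_COLUMNS)


def constant_draws(
    design: APCDesign,
    alpha: np.ndarray,
    pi: np.ndarray,
    gamma: np.ndarray,
    tau_pi: float = 0.0,
    tau_gamma: float = 0.0,
    sigma: float = 1.0,
    n_chains: int = 2,
    n_kept: int = 50,
) -> PosteriorDraws:
    """A degenerate posterior whose every draw equals the given parameters.

    Useful for exercising projection and curvature code on exactly known
    effect vectors (e.g. the tau = 0 linear-continuation limit).
    """
    shape = (n_chains, n_kept)
    return PosteriorDraws(
        design=design,
        model=("age", "period", "cohort"),
        effects={
            "age": np.broadcast_to(np.asarray(alpha, float), shape + (len(alpha),)).copy(),
            "period": np.broadcast_to(np.asarray(pi, float), shape + (len(pi),)).copy(),
            "cohort": np.broadcast_to(np.asarray(gamma, float), shape + (len(gamma),)).copy(),
        },
        sigma=np.full(shape, sigma),
        taus={
            "period": np.full(shape, tau_pi),
            "cohort": np.full(shape, tau_gamma),
        },
        burn_in=0, iterations=n_kept, seed=0, converged=True, rhat_max=1.0,
    )


# ---------------------------------------------------------------------------
# bookkeeping and worked examples
# ---------------------------------------------------------------------------

def design_bookkeeping() -> dict:
    """Strata/parameter/cohort counts and per-stratum averages for both designs."""
    bp = build_design(9, 18, 1999, 2014)
    bmi = build_design(6, 18, 1996, 2014)
    bp_sum = design_summary(bp, 196_299)
    bp_sum_g = design_summary(bp, 205_741)
    bmi_sum = design_summary(bmi, 957_577)
    bmi_sum_g = design_summary(bmi, 941_239)
    return {
        "bp_strata": bp_sum["strata"],
        "bp_parameters": bp_sum["parameters"],
        "bp_cohorts": bp_sum["cohorts"],
        "bp_mean_n_boys": bp_sum["mean_n_per_stratum"],
        "bp_mean_n_girls": bp_sum_g["mean_n_per_stratum"],
        "bmi_strata": bmi_sum["strata"],
        "bmi_parameters": bmi_sum["parameters"],
        "bmi_cohorts": bmi_sum["cohorts"],
        "bmi_mean_n_boys": bmi_sum["mean_n_per_stratum"],
        "bmi_mean_n_girls": bmi_sum_g["mean_n_per_stratum"],
    }


def observed_extrema() -> dict:
    """Turning points of the published boys' childhood SBP and BMI series."""
    sbp = datasets.series_extrema(datasets.observed_series("sbp", "male", "9-11"))
    bmi = datasets.series_extrema(datasets.observed_series("bmi", "male", "9-11"))
    return {
        "sbp_boys_child_min_mmHg": sbp["min_value"],
        "sbp_boys_child_min_year": sbp["min_year"],
        "bmi_boys_child_max_kgm2": bmi["max_value"],
        "bmi_boys_child_max_year": bmi["max_year"],
    }


# ---------------------------------------------------------------------------
# sampler studies
# ---------------------------------------------------------------------------

def oracle_equivalence_study(
    seed: int = 0,
    iterations: int = 2000,
    chains: int = 2,
) -> dict:
    """Gibbs posterior mean vs closed-form mode at fixed hyperparameters.

    With sigma and all taus fixed, the effect block update is an exact
    draw from the Gaussian posterior, so the draws are iid and the
    Monte-Carlo SE of each posterior mean is sd/sqrt(n).  Reports the
    maximum |z| over the free effect coordinates.
    """
    rng = np.random.default_rng([seed, 11])
    design = small_design()
    truth = small_truth()
    table = simulate_cell_means(truth, design, n_per_cell=200, rng=rng)
    sigma0, tau0 = 0.5, 2.0
    mode = penalized_fit(table, design, tau_alpha=tau0, tau_pi=tau0,
                         tau_gamma=tau0, sigma=sigma0)
    cfg = FitConfig(
        chains=chains, iterations=iterations, seed=seed,
        fixed_sigma=sigma0,
        fixed_taus={"age": tau0, "period": tau0, "cohort": tau0},
    )
    draws = fit_apc(table, design, cfg)
    zs = []
    mode_full = {"age": mode.alpha, "period": mode.pi, "cohort": mode.gamma}
    for name, arr in draws.effects.items():
        flat = arr.reshape(-1, arr.shape[-1])
        cons = set(draws.constraints.get(name, ()))
        grid = {"age": design.ages, "period": design.periods, "cohort": design.cohorts}[name]
        for j, g in enumerate(grid):
            if int(g) in cons:
                continue
            se = flat[:, j].std(ddof=1) / np.sqrt(flat.shape[0])
            zs.append(abs(flat[:, j].mean() - mode_full[name][j]) / se)
    return {"max_abs_z": float(max(zs)), "n_parameters": len(zs),
            "n_draws": draws.n_draws}


def coverage_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_per_cell: int = 200,
    iterations: int = 400,
    chains: int = 2,
) -> dict:
    """95% CrI coverage of identifiable cell means on model-generated data.

    Per replicate, cell means are simulated from the curved truth on the
    small design, the full APC model is fitted, and each cell's 95% CrI
    is checked against the true cell mean; the coverage fraction pools
    all cells over all replicates.
    """
    design = small_design()
    truth = small_truth(residual_sd=5.0)
    ages = np.repeat(design.ages, design.n_periods)
    periods = np.tile(design.periods, design.n_ages)
    mu_true = np.array([truth.cell_mean(int(a), int(p)) for a, p in zip(ages, periods)])
    hits = total = 0
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, 17, r])
        table = simulate_cell_means(truth, design, n_per_cell, rng)
        cfg = FitConfig(chains=chains, iterations=iterations, seed=seed * 100003 + r,
                        max_doublings=1)
        draws = fit_apc(table, design, cfg)
        cells = draws.cell_mean_draws(ages, periods).reshape(-1, mu_true.size)
        lo = np.quantile(cells, 0.025, axis=0)
        hi = np.quantile(cells, 0.975, axis=0)
        hits += int(np.sum((lo <= mu_true) & (mu_true <= hi)))
        total += mu_true.size
    return {"coverage": hits / total, "n_replicates": n_replicates,
            "n_cells": total}


def dic_selection_study(
    n_replicates: int = 20,
    seed: int = 0,
    iterations: int = 1000,
    chains: int = 2,
    n_per_cell: int = 1226,
    residual_sd: float = 8.0,
) -> dict:
    """How often DIC picks the generating sub-model in an A vs APC contrast.

    Data are generated from an age-only truth (flat period and cohort
    curves) on the full surveillance-sized design (10 ages x 16 periods,
    the published stratum count and average stratum size, individual SD 8
    mmHg); per replicate both the age-only and the full APC model are
    fitted and the smaller DIC recorded.  The full-size design matters
    here: DIC's ability to reject spurious period/cohort structure grows
    with the cells-per-parameter ratio (3.3 at full size), whereas on the
    5x6 toy design the contrast is near-uninformative.
    """
    design = build_design(9, 18, 1999, 2014)
    age_curve = {int(a): 100.0 + 1.1 * (a - 9) + 0.25 * (a - 9) ** 2 for a in design.ages}
    truth = APCTruth(
        age_curve,
        {int(p): 0.0 for p in design.periods},
        {int(k): 0.0 for k in design.cohorts},
        residual_sd=residual_sd,
    )
    correct = 0
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, 23, r])
        table = simulate_cell_means(truth, design, n_per_cell=n_per_cell, rng=rng)
        dics = {}
        for i, model in enumerate(("A", "APC")):
            cfg = FitConfig(chains=chains, iterations=iterations, model=model,
                            seed=seed * 100003 + 2 * r + i, max_doublings=1)
            draws = fit_apc(table, design, cfg)
            dics[model] = dic(draws, table, design).DIC
        if dics["A"] < dics["APC"]:
            correct += 1
    return {"fraction_correct": correct / n_replicates, "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# projection and changepoint studies
# ---------------------------------------------------------------------------

def rw2_linear_limit(horizon: int = 10) -> dict:
    """Max |error| of tau=0 extensions vs exact linear continuation.

    Uses a degenerate posterior whose period effects end (3, 5): the
    noise-free RW2 extension must continue 7, 9, 11, ...
    """
    design = build_design(9, 10, 2000, 2004)
    pi = np.array([0.0, 1.0, 1.0, 3.0, 5.0])
    draws = constant_draws(design, alpha=np.zeros(2), pi=pi,
                           gamma=np.zeros(design.n_cohorts))
    ext = extend_effects(draws, horizon=horizon, seed=1)
    expected = 5.0 + 2.0 * np.arange(1, horizon + 1)
    err = np.abs(ext.extensions["period"] - expected).max()
    return {"max_abs_error": float(err), "horizon": horizon}


def cri_width_monotonicity(
    horizon: int = 10, tau: float = 1.0, n_kept: int = 4000, seed: int = 0
) -> dict:
    """CrI widths of RW2 extensions must not shrink with forecast step."""
    design = build_design(9, 10, 2000, 2004)
    draws = constant_draws(design, alpha=np.zeros(2), pi=np.zeros(5),
                           gamma=np.zeros(design.n_cohorts),
                           tau_pi=tau, tau_gamma=tau, n_chains=2, n_kept=n_kept)
    ext = extend_effects(draws, horizon=horizon, seed=seed)
    flat = ext.extensions["period"].reshape(-1, horizon)
    widths = np.quantile(flat, 0.975, axis=0) - np.quantile(flat, 0.025, axis=0)
    return {
        "widths": widths.tolist(),
        "monotone": bool(np.all(np.diff(widths) >= 0)),
        "min_step": float(np.diff(widths).min()),
    }


def joinpoint_v_recovery(vertex: int = 2004, arm: int = 8) -> dict:
    """Noiseless V series: the selected model must put one joinpoint at the vertex."""
    years = np.arange(vertex - arm, vertex + arm + 1)
    values = np.abs(years - vertex).astype(float)
    fit = joinpoint_fit(years, values, max_joinpoints=2)
    return {
        "n_joinpoints": fit.n_joinpoints,
        "joinpoint_year": fit.joinpoints[0] if fit.joinpoints else None,
        "sse": fit.sse,
    }


def joinpoint_noise_study(n_replicates: int = 50, seed: int = 0, n_years: int = 16) -> dict:
    """Fraction of pure-noise series on which MBIC selects zero joinpoints."""
    zero = 0
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, 31, r])
        years = np.arange(1999, 1999 + n_years)
        values = rng.normal(0.0, 1.0, size=n_years)
        fit = joinpoint_fit(years, values, max_joinpoints=2)
        if fit.n_joinpoints == 0:
            zero += 1
    return {"fraction_zero": zero / n_replicates, "n_replicates": n_replicates}


def curvature_invariance(seed: int = 0, n_trials: int = 20) -> dict:
    """Max change in second differences under added affine trends (should be ~0)."""
    from .changepoints import curvature

    rng = np.random.default_rng([seed, 37])
    worst = 0.0
    for _ in range(n_trials):
        m = int(rng.integers(5, 30))
        theta = rng.normal(0, 5, size=m)
        a, b = rng.normal(0, 10, size=2)
        base = curvature(theta).mean
        shifted = curvature(theta + a + b * np.arange(m)).mean
        worst = max(worst, float(np.abs(base - shifted).max()))
    return {"max_abs_change": worst, "n_trials": n_trials}
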