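"""Bayesian age-period-cohort linear regression with RW2 smoothing priors.

The observation unit is a stratum (sex-by-age-by-period cell) mean:

    ybar_i ~ Normal(alpha[a_i] + pi[p_i] + gamma[p_i - a_i], sigma^2 / w_i)

with w_i = 1 by default (cell means modelled directly) or w_i = n_i when
``weighting="n"``.  Because cohort = period - age, the three effect sets
share an exact linear dependency; identifiability is obtained by pinning
the second and penultimate periods and the central cohort to zero, with
no constraint on age (the age effects carry the absolute level).  Only
second-order features of the effect curves (curvature, inflection
points) are free of this constraint choice.

Each effect vector carries a second-order random-walk (RW2) prior: flat
on its first two elements and Normal(2*theta[j-1] - theta[j-2], tau^2)
forward from there, i.e. a Gaussian penalty on second differences whose
null space is exactly the (non-identified) linear trends.  The residual
SD sigma and the three innovation SDs tau carry uniform(0, U) priors.

Sampling is blocked Gibbs: the full effect coefficient vector is
conditionally Gaussian and drawn jointly; sigma and the taus are updated
by stepping-out/shrinkage slice sampling.  Multiple chains from
dispersed starts feed the split-chain R-hat diagnostic; model fit is
compared by DIC.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.stats import norm, rankdata

from .tabulate import APCDesign

BLOCK_ORDER = ("age", "period", "cohort")

#: shorthand model names -> effect blocks
MODEL_SETS: dict[str, tuple[str, ...]] = {
    "A": ("age",),
    "AP": ("age", "period"),
    "AC": ("age", "cohort"),
    "APC": ("age", "period", "cohort"),
}

_TINY = 1e-12


class IdentifiabilityError(ValueError):
    """The constrained design matrix is rank deficient."""


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# design matrix and penalties
# ---------------------------------------------------------------------------

def second_difference_matrix(m: int) -> np.ndarray:
    """(m-2) x m matrix of second differences; empty for m < 3."""
    if m < 3:
        return np.zeros((0, m))
    D = np.zeros((m - 2, m))
    for j in range(m - 2):
        D[j, j : j + 3] = (1.0, -2.0, 1.0)
    return D


@dataclass(frozen=True)
class EffectBlock:
    """One effect set (age, period or cohort) in the constrained model."""

    name: str
    grid: np.ndarray                 # full grid of years / cohort indices
    constrained: tuple[int, ...]     # grid values pinned to zero
    free: np.ndarray                 # grid values with a free coefficient
    cols: slice                      # this block's columns in X
    embed: np.ndarray                # (m, f): free coefficients -> full vector
    penalty_root: np.ndarray         # D2 @ embed; rows = number of 2nd differences

    @property
    def n_free(self) -> int:
        return self.free.size

    def full_vector(self, beta_block: np.ndarray) -> np.ndarray:
        """Expand free coefficients to the full grid (exact zeros at references)."""
        return self.embed @ beta_block


def _resolve_model(model: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(model, str):
        if model not in MODEL_SETS:
            raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_SETS)}")
        return MODEL_SETS[model]
    blocks = tuple(b for b in BLOCK_ORDER if b in model)
    if set(blocks) != set(model):
        raise ValueError(f"unknown effect blocks in {model!r}")
    return blocks


def default_constraints(design: APCDesign, blocks: Sequence[str]) -> dict[str, tuple[int, ...]]:
    """Reference constraints giving a full-rank design for the given blocks.

    The unconstrained indicator model has one level redundancy per block
    beyond the first, plus one trend redundancy when all three blocks are
    present.  Constraints are taken in priority order: second period,
    central cohort, penultimate period.
    """
    blocks = tuple(blocks)
    needed = max(len(blocks) - 1, 0) + (1 if len(blocks) == 3 else 0)
    pool = [
        ("period", design.ref_period_low),
        ("cohort", design.ref_cohort),
        ("period", design.ref_period_high),
    ]
    cons: dict[str, list[int]] = {b: [] for b in blocks}
    for name, pos in pool:
        if needed == 0:
            break
        if name in cons and pos not in cons[name]:
            cons[name].append(pos)
            needed -= 1
    return {b: tuple(v) for b, v in cons.items()}


def build_design_matrix(
    table: pd.DataFrame,
    design: APCDesign,
    model: str | Sequence[str] = "APC",
    constraints: Mapping[str, Sequence[int]] | None = None,
    check_rank: bool = True,
) -> tuple[np.ndarray, list[EffectBlock]]:
    """Indicator design matrix with reference constraints applied.

    One row per stratum; columns are the free coefficients of each effect
    block (A age + (P-2) period + (C-1) cohort columns for the full
    model under the default constraints).

    Raises
    ------
    IdentifiabilityError
        If the matrix is numerically rank deficient (wrong constraints,
        or too few occupied cells).
    """
    blocks_names = _resolve_model(model)
    if constraints is None:
        constraints = default_constraints(design, blocks_names)
    grids = {"age": design.ages, "period": design.periods, "cohort": design.cohorts}
    values = {
        "age": table["age"].to_numpy(int),
        "period": table["period"].to_numpy(int),
        "cohort": table["period"].to_numpy(int) - table["age"].to_numpy(int),
    }

    blocks: list[EffectBlock] = []
    col = 0
    for name in blocks_names:
        grid = grids[name]
        cons = tuple(int(c) for c in dict.fromkeys(constraints.get(name, ())))
        for c in cons:
            if c not in grid:
                raise ValueError(f"constraint {c} not on the {name} grid")
        free = np.array([g for g in grid if g not in cons], dtype=int)
        m, f = grid.size, free.size
        embed = np.zeros((m, f))
        pos = {int(g): i for i, g in enumerate(grid)}
        for j, g in enumerate(free):
            embed[pos[int(g)], j] = 1.0
        D2 = second_difference_matrix(m)
        blocks.append(
            EffectBlock(name, grid, cons, free, slice(col, col + f), embed, D2 @ embed)
        )
        col += f

    M = len(table)
    X = np.zeros((M, col))
    for blk in blocks:
        fpos = {int(g): j for j, g in enumerate(blk.free)}
        v = values[blk.name]
        for i in range(M):
            j = fpos.get(int(v[i]))
            if j is not None:
                X[i, blk.cols.start + j] = 1.0
    if check_rank:
        rank = np.linalg.matrix_rank(X)
        if rank < col:
            raise IdentifiabilityError(
                f"design matrix rank {rank} < {col} columns (deficit {col - rank}); "
                "check constraints and cell occupancy"
            )
    return X, blocks


# ---------------------------------------------------------------------------
# parameters and point estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APCParams:
    """One parameter configuration: full effect vectors plus scale parameters.

    Absent blocks (sub-models) are all-zero vectors; constrained
    positions are exact zeros.
    """

    alpha: np.ndarray
    pi: np.ndarray
    gamma: np.ndarray
    sigma: float
    tau_alpha: float
    tau_pi: float
    tau_gamma: float

    def cell_mean(self, age: np.ndarray, period: np.ndarray, design: APCDesign) -> np.ndarray:
        ai = np.searchsorted(design.ages, age)
        pi_ = np.searchsorted(design.periods, period)
        ki = np.searchsorted(design.cohorts, np.asarray(period) - np.asarray(age))
        return self.alpha[ai] + self.pi[pi_] + self.gamma[ki]


def _weights(table: pd.DataFrame, weighting: str) -> np.ndarray:
    if weighting == "unit":
        return np.ones(len(table))
    if weighting == "n":
        return table["n"].to_numpy(float)
    raise ValueError(f"weighting must be 'unit' or 'n', got {weighting!r}")


def _params_from_beta(
    beta: np.ndarray, blocks: list[EffectBlock], design: APCDesign,
    sigma: float, taus: Mapping[str, float],
) -> APCParams:
    full = {
        "age": np.zeros(design.n_ages),
        "period": np.zeros(design.n_periods),
        "cohort": np.zeros(design.n_cohorts),
    }
    for blk in blocks:
        full[blk.name] = blk.full_vector(beta[blk.cols])
    return APCParams(
        alpha=full["age"], pi=full["period"], gamma=full["cohort"], sigma=float(sigma),
        tau_alpha=float(taus.get("age", np.nan)),
        tau_pi=float(taus.get("period", np.nan)),
        tau_gamma=float(taus.get("cohort", np.nan)),
    )


def penalized_fit(
    table: pd.DataFrame,
    design: APCDesign,
    tau_alpha: float = np.inf,
    tau_pi: float = np.inf,
    tau_gamma: float = np.inf,
    sigma: float = 1.0,
    weighting: str = "unit",
    model: str | Sequence[str] = "APC",
    constraints: Mapping[str, Sequence[int]] | None = None,
) -> APCParams:
    """Exact Gaussian posterior mode at fixed hyperparameters.

    The generalized ridge solution of the constrained least-squares
    problem with RW2 penalty ``||D2 theta||^2 / tau^2`` per block;
    ``tau = inf`` removes a block's penalty, ``tau -> 0`` forces the
    block onto the RW2 null space (linear functions through its zero
    references).  Deterministic; used as the sampler oracle and
    initializer.
    """
    for name, t in (("tau_alpha", tau_alpha), ("tau_pi", tau_pi), ("tau_gamma", tau_gamma)):
        if not t > 0:
            raise ValueError(f"{name} must be > 0 (use np.inf for no smoothing)")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    X, blocks = build_design_matrix(table, design, model, constraints)
    y = table["mean"].to_numpy(float)
    w = _weights(table, weighting)
    taus = {"age": tau_alpha, "period": tau_pi, "cohort": tau_gamma}
    A = X.T @ (X * w[:, None]) / sigma**2
    for blk in blocks:
        if np.isfinite(taus[blk.name]) and blk.penalty_root.shape[0]:
            A[blk.cols, blk.cols] += (blk.penalty_root.T @ blk.penalty_root) / taus[blk.name] ** 2
    b = X.T @ (w * y) / sigma**2
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise IdentifiabilityError(f"singular penalized system: {e}") from e
    return _params_from_beta(beta, blocks, design, sigma, taus)


# ---------------------------------------------------------------------------
# slice sampling
# ---------------------------------------------------------------------------

def slice_sample(x0, logf, rng, lower, upper, width, max_steps=50):
    """Univariate stepping-out/shrinkage slice sampler on (lower, upper)."""
    logy = logf(x0) - rng.exponential()
    u = rng.uniform()
    L, R = x0 - width * u, x0 + width * (1.0 - u)
    for _ in range(max_steps):
        if L <= lower or logf(L) <= logy:
            break
        L -= width
    for _ in range(max_steps):
        if R >= upper or logf(R) <= logy:
            break
        R += width
    L, R = max(L, lower), min(R, upper)
    for _ in range(200):
        x1 = rng.uniform(L, R)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """MCMC settings for :func:`fit_apc`.

    ``iterations`` counts total iterations per chain before burn-in
    removal; the first ``burn_in_fraction`` of each chain is discarded.
    If the maximum split R-hat exceeds ``rhat_threshold`` the run is
    repeated with doubled iterations up to ``max_doublings`` times, then
    flagged (warning, never silent).  ``fixed_sigma``/``fixed_taus`` pin
    hyperparameters (used for oracle-equivalence checks).  ``prior_upper``
    is the U of the uniform(0, U) priors on sigma and the taus, in
    outcome units.
    """

    chains: int = 5
    iterations: int = 1000
    burn_in_fraction: float = 0.5
    seed: int = 0
    weighting: str = "unit"
    model: str | Sequence[str] = "APC"
    prior_upper: float = 100.0
    rhat_threshold: float = 1.05
    max_doublings: int = 2
    fixed_sigma: float | None = None
    fixed_taus: Mapping[str, float] = field(default_factory=dict)
    init_jitter: float = 0.5
    constraints: Mapping[str, Sequence[int]] | None = None


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC samples, by chain.

    ``effects[name]`` has shape (chains, kept, grid length) and holds the
    full effect vectors with exact zeros at the reference positions;
    ``sigma`` and ``taus[name]`` have shape (chains, kept).
    """

    design: APCDesign
    model: tuple[str, ...]
    effects: dict[str, np.ndarray]
    sigma: np.ndarray
    taus: dict[str, np.ndarray]
    burn_in: int
    iterations: int
    seed: int
    converged: bool
    rhat_max: float
    weighting: str = "unit"
    constraints: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_kept(self) -> int:
        return self.sigma.shape[1]

    @property
    def n_draws(self) -> int:
        return self.sigma.size

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one quantity flattened over chains: (n_draws, ...)."""
        if name == "sigma":
            return self.sigma.reshape(-1)
        if name.startswith("tau_"):
            return self.taus[name[4:]].reshape(-1)
        arr = self.effects[name]
        return arr.reshape(-1, arr.shape[-1])

    def cell_mean_draws(self, age: np.ndarray, period: np.ndarray) -> np.ndarray:
        """Fitted cell means per draw: (chains, kept, len(age))."""
        age = np.asarray(age, int)
        period = np.asarray(period, int)
        out = np.zeros(self.sigma.shape + (age.size,))
        idx = {
            "age": np.searchsorted(self.design.ages, age),
            "period": np.searchsorted(self.design.periods, period),
            "cohort": np.searchsorted(self.design.cohorts, period - age),
        }
        for name, arr in self.effects.items():
            out += arr[:, :, idx[name]]
        return out

    def posterior_mean_params(self) -> APCParams:
        d = self.design
        full = {
            "age": np.zeros(d.n_ages),
            "period": np.zeros(d.n_periods),
            "cohort": np.zeros(d.n_cohorts),
        }
        for name, arr in self.effects.items():
            full[name] = arr.mean(axis=(0, 1))
        taus = {n: float(a.mean()) for n, a in self.taus.items()}
        return APCParams(
            alpha=full["age"], pi=full["period"], gamma=full["cohort"],
            sigma=float(self.sigma.mean()),
            tau_alpha=taus.get("age", np.nan),
            tau_pi=taus.get("period", np.nan),
            tau_gamma=taus.get("cohort", np.nan),
        )


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------

def _run_chain(
    X: np.ndarray,
    blocks: list[EffectBlock],
    y: np.ndarray,
    w: np.ndarray,
    cfg: FitConfig,
    rng: np.random.Generator,
    beta_init: np.ndarray,
    sigma_init: float,
    n_iter: int,
):
    """One chain of the partially collapsed Gibbs sampler.

    sigma and each tau are slice-sampled on their collapsed conditionals
    with the effect vector integrated out analytically (the model is
    conditionally Gaussian, so the marginal is a Cholesky away); the
    effect vector is then redrawn jointly from its Gaussian full
    conditional.  Collapsing removes the funnel coupling between an
    effect block and its smoothing SD that makes the centered scheme mix
    slowly when the true block signal is weak.
    """
    M, q = X.shape
    XtWX = X.T @ (X * w[:, None])
    XtWy = X.T @ (w * y)
    yWy = float(y @ (w * y))
    U = cfg.prior_upper

    penalized = [blk for blk in blocks if blk.penalty_root.shape[0] > 0]
    grams = {blk.name: blk.penalty_root.T @ blk.penalty_root for blk in penalized}
    n_diff = {blk.name: blk.penalty_root.shape[0] for blk in penalized}

    def precision(sigma, taus):
        Q = XtWX / sigma**2
        for blk in penalized:
            t = taus[blk.name]
            if np.isfinite(t):
                Q[blk.cols, blk.cols] += grams[blk.name] / max(t, _TINY) ** 2
        return Q

    def chol(Q):
        try:
            return np.linalg.cholesky(Q)
        except np.linalg.LinAlgError:
            return np.linalg.cholesky(Q + np.eye(q) * 1e-10 * np.trace(Q) / q)

    def log_marginal(sigma, taus):
        """log p(y | sigma, taus) with beta integrated out, up to a constant."""
        L = chol(precision(sigma, taus))
        u = solve_triangular(L, XtWy / sigma**2, lower=True)
        val = (-M * np.log(sigma) - yWy / (2.0 * sigma**2)
               - float(np.log(np.diag(L)).sum()) + 0.5 * float(u @ u))
        for blk in penalized:
            val -= n_diff[blk.name] * np.log(taus[blk.name])
        return val

    sigma = (float(np.clip(sigma_init, 1e-3, U * 0.99))
             if cfg.fixed_sigma is None else cfg.fixed_sigma)
    taus = {blk.name: float(cfg.fixed_taus.get(blk.name, 1.0)) for blk in blocks}
    beta = beta_init.copy()

    out_beta = np.empty((n_iter, q))
    out_sigma = np.empty(n_iter)
    out_taus = {blk.name: np.empty(n_iter) for blk in blocks}

    for it in range(n_iter):
        # --- tau_b | y, sigma, tau_-b (effects collapsed)
        for blk in penalized:
            if blk.name in cfg.fixed_taus:
                continue
            def logf_tau(t, name=blk.name):
                return log_marginal(sigma, {**taus, name: t})
            taus[blk.name] = slice_sample(
                logf=logf_tau, x0=taus[blk.name], rng=rng, lower=1e-8, upper=U,
                width=max(0.5 * taus[blk.name], 1e-3),
            )

        # --- sigma | y, taus (effects collapsed)
        if cfg.fixed_sigma is None:
            sigma = slice_sample(
                logf=lambda s: log_marginal(s, taus), x0=sigma, rng=rng,
                lower=1e-8, upper=U, width=max(0.5 * sigma, 1e-3),
            )

        # --- effects | y, sigma, taus: joint Gaussian draw
        L = chol(precision(sigma, taus))
        mean = cho_solve((L, True), XtWy / sigma**2)
        z = rng.standard_normal(q)
        beta = mean + solve_triangular(L.T, z, lower=False)

        out_beta[it] = beta
        out_sigma[it] = sigma
        for name in out_taus:
            out_taus[name][it] = taus[name]

    return out_beta, out_sigma, out_taus


def fit_apc(table: pd.DataFrame, design: APCDesign, config: FitConfig | None = None) -> PosteriorDraws:
    """Fit the Bayesian APC model by blocked Gibbs sampling.

    Chains start from the penalized-fit mode plus chain-indexed Gaussian
    jitter (dispersed starts).  The first half of each chain is discarded
    as burn-in; if any split R-hat exceeds the threshold the whole run is
    repeated with doubled iterations, up to ``max_doublings`` times, and
    flagged with a :class:`ConvergenceWarning` if still above.
    Deterministic given ``config.seed``.
    """
    cfg = config or FitConfig()
    if cfg.chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    blocks_names = _resolve_model(cfg.model)
    X, blocks = build_design_matrix(table, design, blocks_names, cfg.constraints)
    y = table["mean"].to_numpy(float)
    w = _weights(table, cfg.weighting)

    # moderate-smoothing mode as the initialization centre
    init_params = penalized_fit(
        table, design, tau_alpha=1.0, tau_pi=1.0, tau_gamma=1.0,
        sigma=1.0, weighting=cfg.weighting, model=blocks_names,
        constraints=cfg.constraints,
    )
    beta0 = np.concatenate([
        {"age": init_params.alpha, "period": init_params.pi, "cohort": init_params.gamma}[
            blk.name
        ][[int(np.searchsorted(blk.grid, g)) for g in blk.free]]
        for blk in blocks
    ]) if blocks else np.zeros(0)
    resid0 = y - X @ beta0
    scale = max(float(np.std(y)), 1.0)
    sigma0 = max(float(np.sqrt(np.mean(w * resid0**2))), 1e-2)

    n_iter = cfg.iterations
    for attempt in range(cfg.max_doublings + 1):
        chain_betas, chain_sigmas, chain_taus = [], [], []
        burn = int(n_iter * cfg.burn_in_fraction)
        if n_iter - burn < 4:
            burn = max(n_iter - 4, 0)
        for c in range(cfg.chains):
            rng = np.random.default_rng([cfg.seed, attempt, c])
            jitter = rng.normal(0.0, cfg.init_jitter * scale * (1.0 + c), size=beta0.shape)
            s_init = sigma0 * float(np.exp(rng.normal(0.0, 0.3 * (1.0 + 0.2 * c))))
            ob, os_, ot = _run_chain(X, blocks, y, w, cfg, rng, beta0 + jitter, s_init, n_iter)
            chain_betas.append(ob[burn:])
            chain_sigmas.append(os_[burn:])
            chain_taus.append({k: v[burn:] for k, v in ot.items()})

        beta_arr = np.stack(chain_betas)           # (chains, kept, q)
        sigma_arr = np.stack(chain_sigmas)
        tau_arr = {
            blk.name: np.stack([ct[blk.name] for ct in chain_taus]) for blk in blocks
        }
        effects = {}
        for blk in blocks:
            effects[blk.name] = np.einsum("ckf,mf->ckm", beta_arr[:, :, blk.cols], blk.embed)

        draws = PosteriorDraws(
            design=design, model=tuple(blocks_names), effects=effects,
            sigma=sigma_arr, taus=tau_arr, burn_in=burn, iterations=n_iter,
            seed=cfg.seed, converged=True, rhat_max=np.nan,
            weighting=cfg.weighting,
            constraints={blk.name: blk.constrained for blk in blocks},
        )
        r = rhat(draws)
        rmax = float(np.nanmax(r.to_numpy())) if len(r) else 1.0
        draws.rhat_max = rmax
        if rmax <= cfg.rhat_threshold:
            return draws
        n_iter *= 2

    draws.converged = False
    warnings.warn(
        f"APC sampler not converged: max R-hat {rmax:.3f} > {cfg.rhat_threshold} "
        f"after {n_iter // 2} iterations per chain",
        ConvergenceWarning,
    )
    return draws


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def _split_rhat_1d(x: np.ndarray, rank_normalize: bool = False) -> float:
    """Split-chain potential scale reduction factor for one scalar quantity.

    ``x`` has shape (chains, draws); each chain is split in half, giving
    2*chains sequences.  Degenerate (zero within-chain variance)
    sequences return exactly 1.0 with a warning.
    """
    c, n = x.shape
    half = n // 2
    if half < 2:
        return float("nan")
    seqs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    if rank_normalize:
        r = rankdata(seqs, axis=None).reshape(seqs.shape)
        seqs = norm.ppf((r - 0.375) / (seqs.size + 0.25))
    within = seqs.var(axis=1, ddof=1)
    W = float(within.mean())
    B_over_n = float(seqs.mean(axis=1).var(ddof=1))
    tol = _TINY * max(float(np.abs(seqs).max()) ** 2, 1.0)
    if W <= tol:
        if B_over_n <= tol:
            return 1.0  # all chains constant and equal: converged by definition
        warnings.warn("zero within-chain variance but chains differ; R-hat infinite")
        return float("inf")
    var_plus = (half - 1) / half * W + B_over_n
    return float(np.sqrt(var_plus / W))


def rhat(draws: PosteriorDraws, rank_normalize: bool = False) -> pd.Series:
    """Split-chain R-hat per monitored scalar parameter.

    Constrained (exactly zero) effect positions are excluded; a fixed
    sigma or tau yields R-hat 1 by the degenerate-sequence rule.
    """
    if draws.n_chains < 2:
        raise ValueError("R-hat needs >= 2 chains")
    if draws.n_kept < 4:
        raise ValueError("R-hat needs >= 4 post-burn-in draws per chain")
    vals: dict[str, float] = {}
    for name, arr in draws.effects.items():
        cons = set(draws.constraints.get(name, ()))
        grid = {
            "age": draws.design.ages,
            "period": draws.design.periods,
            "cohort": draws.design.cohorts,
        }[name]
        for j, g in enumerate(grid):
            if int(g) in cons:
                continue
            vals[f"{name}[{int(g)}]"] = _split_rhat_1d(arr[:, :, j], rank_normalize)
    vals["sigma"] = _split_rhat_1d(draws.sigma, rank_normalize)
    for name, arr in draws.taus.items():
        vals[f"tau_{name}"] = _split_rhat_1d(arr, rank_normalize)
    return pd.Series(vals, name="rhat")


def summarize(draws: PosteriorDraws, interval: float = 0.95) -> pd.DataFrame:
    """Posterior mean, central credible interval and R-hat per parameter."""
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    r = rhat(draws)
    rows = []
    grids = {
        "age": draws.design.ages,
        "period": draws.design.periods,
        "cohort": draws.design.cohorts,
    }
    def _row(pname, flat):
        rows.append({
            "parameter": pname,
            "mean": float(flat.mean()),
            "lower": float(np.quantile(flat, lo_q)),
            "upper": float(np.quantile(flat, hi_q)),
            "rhat": float(r[pname]) if pname in r.index else 1.0,
        })
    for name, arr in draws.effects.items():
        flat = arr.reshape(-1, arr.shape[-1])
        for j, g in enumerate(grids[name]):
            _row(f"{name}[{int(g)}]", flat[:, j])
    _row("sigma", draws.sigma.reshape(-1))
    for name, arr in draws.taus.items():
        _row(f"tau_{name}", arr.reshape(-1))
    return pd.DataFrame(rows)


DICResult = namedtuple("DICResult", ["Dbar", "pD", "DIC"])


def _deviance(mu: np.ndarray, sigma, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """-2 log likelihood of cell means; broadcasts over leading draw axes."""
    sigma = np.asarray(sigma)[..., None]
    r2 = (y - mu) ** 2
    return np.sum(np.log(2 * np.pi * sigma**2 / w) + w * r2 / sigma**2, axis=-1)


def dic(draws: PosteriorDraws, table: pd.DataFrame, design: APCDesign) -> DICResult:
    """Deviance information criterion with the posterior-mean plug-in.

    Dbar is the posterior mean deviance; pD = Dbar - D(posterior mean of
    all parameters); DIC = Dbar + pD.  Smaller DIC implies better fit.
    """
    y = table["mean"].to_numpy(float)
    w = _weights(table, draws.weighting)
    age = table["age"].to_numpy(int)
    period = table["period"].to_numpy(int)
    mu = draws.cell_mean_draws(age, period)          # (chains, kept, M)
    D = _deviance(mu, draws.sigma, y, w)             # (chains, kept)
    Dbar = float(D.mean())
    mu_hat = mu.mean(axis=(0, 1))
    Dhat = float(_deviance(mu_hat, float(draws.sigma.mean()), y, w))
    pD = Dbar - Dhat
    return DICResult(Dbar, pD, Dbar + pD)


def compare_models(
    table: pd.DataFrame,
    design: APCDesign,
    models: Sequence[str] = ("A", "AP", "AC", "APC"),
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Fit each sub-model and tabulate DIC; smallest DIC flagged as best."""
    cfg = config or FitConfig()
    rows = []
    for i, name in enumerate(models):
        sub = replace(cfg, model=name, seed=cfg.seed + i, constraints=None)
        draws = fit_apc(table, design, sub)
        d = dic(draws, table, design)
        rows.append({
            "model": name, "Dbar": d.Dbar, "pD": d.pD, "DIC": d.DIC,
            "rhat_max": draws.rhat_max, "converged": draws.converged,
        })
    out = pd.DataFrame(rows)
    out["best"] = out["DIC"] == out["DIC"].min()
    return out
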