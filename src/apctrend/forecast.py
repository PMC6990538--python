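"""RW2 extrapolation of period and cohort effects and trend projection.

Projections continue the fitted model forward: for every posterior draw,
``H`` additional period and cohort effects are simulated from the RW2
predictive

    theta[J+h] = 2 theta[J+h-1] - theta[J+h-2] + Normal(0, tau^2)

using that draw's own innovation SD, so forecast uncertainty combines
parameter uncertainty with random-walk innovation.  With tau = 0 the
extension is the exact linear continuation of the last two effects.
Projected cell means are alpha[a] + pi[p] + gamma[p-a] per draw; yearly
series average the cell means over ages (equal weights by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .apcmodel import PosteriorDraws
from .tabulate import APCDesign, cohort_label


class HorizonError(ValueError):
    """A required effect lies beyond the extended grids."""


@dataclass
class ExtendedDraws:
    """Posterior draws augmented with H extrapolated period/cohort effects.

    ``extensions[name]`` has shape (chains, kept, H); ``future_grids``
    holds the corresponding years / cohort indices.
    """

    base: PosteriorDraws
    horizon: int
    seed: int
    extensions: dict[str, np.ndarray] = field(default_factory=dict)
    future_grids: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def design(self) -> APCDesign:
        return self.base.design

    def grid(self, name: str) -> np.ndarray:
        obs = {"age": self.design.ages, "period": self.design.periods,
               "cohort": self.design.cohorts}[name]
        fut = self.future_grids.get(name)
        return obs if fut is None or fut.size == 0 else np.concatenate([obs, fut])

    def effect_at(self, name: str, point: int) -> np.ndarray:
        """Draws of one effect level, observed or extrapolated: (chains, kept)."""
        obs = {"age": self.design.ages, "period": self.design.periods,
               "cohort": self.design.cohorts}[name]
        point = int(point)
        if obs[0] <= point <= obs[-1]:
            if name not in self.base.effects:
                return np.zeros_like(self.base.sigma)
            return self.base.effects[name][:, :, point - int(obs[0])]
        fut = self.future_grids.get(name, np.array([], dtype=int))
        if fut.size and fut[0] <= point <= fut[-1]:
            return self.extensions[name][:, :, point - int(fut[0])]
        needed = point - int(obs[-1])
        raise HorizonError(
            f"{name} effect at {point} not available: requires extension length "
            f"{needed}, have {self.horizon}"
        )


def extend_effects(draws: PosteriorDraws, horizon: int = 10, seed: int = 0) -> ExtendedDraws:
    """Extrapolate period and cohort effects ``horizon`` steps forward.

    Applied recursively in the forward direction per draw; age effects
    are left unchanged.  ``horizon = 0`` is a no-op wrapper around the
    fitted draws.  Deterministic given ``seed``.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    ext = ExtendedDraws(base=draws, horizon=int(horizon), seed=int(seed))
    if horizon == 0:
        return ext
    rng = np.random.default_rng([seed, horizon])
    grids = {"period": draws.design.periods, "cohort": draws.design.cohorts}
    for name in ("period", "cohort"):
        if name not in draws.effects:
            continue
        eff = draws.effects[name]
        if eff.shape[-1] < 2:
            raise ValueError(f"{name} effects need >= 2 levels to extrapolate")
        tau = draws.taus.get(name)
        if tau is None:
            raise ValueError(f"draws carry no tau for {name}")
        prev2 = eff[:, :, -2].copy()
        prev1 = eff[:, :, -1].copy()
        out = np.empty(eff.shape[:2] + (horizon,))
        for h in range(horizon):
            step = 2.0 * prev1 - prev2
            noise = rng.standard_normal(prev1.shape) * tau
            new = step + noise
            out[:, :, h] = new
            prev2, prev1 = prev1, new
        ext.extensions[name] = out
        last = int(grids[name][-1])
        ext.future_grids[name] = np.arange(last + 1, last + 1 + horizon)
    return ext


@dataclass
class ProjectionCells:
    """Per-draw projected cell means over an age x period grid."""

    ages: np.ndarray
    periods: np.ndarray
    draws: np.ndarray  # (chains, kept, n_ages, n_periods)

    def summary(self, interval: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - interval) / 2, 1 - (1 - interval) / 2
        flat = self.draws.reshape(-1, self.ages.size, self.periods.size)
        rows = []
        for i, a in enumerate(self.ages):
            for j, p in enumerate(self.periods):
                d = flat[:, i, j]
                rows.append({
                    "age": int(a), "period": int(p),
                    "cohort_label": cohort_label(int(a), int(p)),
                    "mean": float(d.mean()),
                    "lower": float(np.quantile(d, lo)),
                    "upper": float(np.quantile(d, hi)),
                })
        return pd.DataFrame(rows)


def project_cell_means(
    ext: ExtendedDraws,
    periods: np.ndarray | None = None,
    ages: np.ndarray | None = None,
) -> ProjectionCells:
    """Projected (or fitted) cell means per draw for the requested grid.

    Defaults to all future periods of the extension; observed periods may
    be requested too, in which case the fitted effects are used and the
    result reproduces the fit exactly.

    Raises
    ------
    HorizonError
        If a required cohort index ``p - a`` lies beyond the extension,
        stating the extension length needed.
    """
    design = ext.design
    if ages is None:
        ages = design.ages
    if periods is None:
        periods = ext.future_grids.get("period", np.array([], dtype=int))
    ages = np.asarray(ages, int)
    periods = np.asarray(periods, int)
    if periods.size == 0:
        raise ValueError("no periods requested (horizon 0 and no explicit periods)")

    out = np.zeros(ext.base.sigma.shape + (ages.size, periods.size))
    for i, a in enumerate(ages):
        alpha = ext.effect_at("age", int(a))
        for j, p in enumerate(periods):
            out[:, :, i, j] = (
                alpha + ext.effect_at("period", int(p)) + ext.effect_at("cohort", int(p) - int(a))
            )
    return ProjectionCells(ages=ages, periods=periods, draws=out)


def yearly_mean_series(
    cells: ProjectionCells,
    age_weights: np.ndarray | None = None,
    interval: float = 0.95,
) -> pd.DataFrame:
    """Per-year weighted mean over ages, summarized as mean and CrI.

    The average is taken per posterior draw and then summarized, so the
    credible interval reflects the joint posterior of all cell means.
    Equal age weights by default.
    """
    n_ages = cells.ages.size
    if age_weights is None:
        wts = np.full(n_ages, 1.0 / n_ages)
    else:
        wts = np.asarray(age_weights, float)
        if wts.size != n_ages or wts.sum() <= 0:
            raise ValueError("age_weights must match the age grid and sum to > 0")
        wts = wts / wts.sum()
    series = np.tensordot(cells.draws, wts, axes=([2], [0]))  # (chains, kept, P)
    flat = series.reshape(-1, cells.periods.size)
    lo, hi = (1 - interval) / 2, 1 - (1 - interval) / 2
    return pd.DataFrame({
        "year": cells.periods.astype(int),
        "mean": flat.mean(axis=0),
        "lower": np.quantile(flat, lo, axis=0),
        "upper": np.quantile(flat, hi, axis=0),
    })


def observed_yearly_means(
    table: pd.DataFrame,
    design: APCDesign,
    age_weights: np.ndarray | None = None,
    partial_years: bool = False,
) -> pd.DataFrame:
    """Raw observed per-year series: weighted mean over ages of cell means.

    Requires every design age in every reported year unless
    ``partial_years`` is set (weights are then renormalized over the
    ages present).
    """
    n_ages = design.n_ages
    if age_weights is None:
        wts = pd.Series(1.0, index=design.ages)
    else:
        wts = pd.Series(np.asarray(age_weights, float), index=design.ages)
    rows = []
    for year, grp in table.groupby("period"):
        present = grp.set_index("age")["mean"]
        missing = [int(a) for a in design.ages if a not in present.index]
        if missing and not partial_years:
            raise ValueError(f"year {year}: missing ages {missing} (set partial_years=True)")
        w = wts.loc[present.index]
        rows.append({"year": int(year), "mean": float((present * w).sum() / w.sum())})
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def trend_series(
    ext: ExtendedDraws,
    table: pd.DataFrame | None = None,
    age_weights: np.ndarray | None = None,
    observed: str = "fitted",
    interval: float = 0.95,
) -> pd.DataFrame:
    """Observed plus projected yearly series with a kind flag per row.

    ``observed="fitted"`` plots the model's fitted yearly means over the
    observed periods (with CrIs); ``observed="raw"`` uses the raw stratum
    means from ``table`` (no interval).  Future years always come from
    the RW2 projection.
    """
    design = ext.design
    if observed == "fitted":
        obs_cells = project_cell_means(ext, periods=design.periods)
        obs = yearly_mean_series(obs_cells, age_weights, interval)
    elif observed == "raw":
        if table is None:
            raise ValueError("observed='raw' requires the stratum table")
        obs = observed_yearly_means(table, design, age_weights)
        obs["lower"] = np.nan
        obs["upper"] = np.nan
    else:
        raise ValueError("observed must be 'fitted' or 'raw'")
    obs["kind"] = "observed"
    future = ext.future_grids.get("period", np.array([], dtype=int))
    parts = [obs]
    if future.size:
        proj = yearly_mean_series(project_cell_means(ext, periods=future), age_weights, interval)
        proj["kind"] = "projected"
        parts.append(proj)
    return pd.concat(parts, ignore_index=True)
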