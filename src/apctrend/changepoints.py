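"""Curvature (second-difference) analysis and joinpoint regression.

Because of the exact linear dependency cohort = period - age, only
second-order features of APC effect curves are identified: adding any
affine function of the index to an effect vector leaves its second
differences unchanged.  Curvature series therefore locate inflection
points free of the reference-constraint choice.

Joinpoint regression fits a continuous piecewise-linear trend with
breakpoints at observed years, selecting the number and placement of
joinpoints by a modified Bayesian information criterion

    MBIC(k) = n ln(SSE_k / n) + (2k + 2) ln(n)

via exhaustive grid search (deterministic; ties broken toward fewer
joinpoints, then earliest placement).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CurvatureSeries:
    """Second differences of an effect or trend series at interior positions.

    For posterior draws, ``mean``/``lower``/``upper`` summarize the
    per-draw curvature; for a plain series they all equal the point
    curvature.
    """

    positions: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    draws: np.ndarray | None = None  # (n_draws, len(positions)) when available

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions, "curvature": self.mean,
            "lower": self.lower, "upper": self.upper,
        })


def curvature(
    values: np.ndarray,
    positions: np.ndarray | None = None,
    interval: float = 0.95,
) -> CurvatureSeries:
    """Second differences d2[j] = x[j+1] - 2 x[j] + x[j-1] per interior point.

    ``values`` is either a 1-D series or a 2-D array of posterior draws
    (draws x length); draws are summarized by posterior mean and central
    credible interval.  Invariant under addition of any affine function
    of the index.
    """
    arr = np.asarray(values, float)
    if arr.ndim == 1:
        arr = arr[None, :]
        point = True
    elif arr.ndim == 2:
        point = False
    else:
        raise ValueError("values must be 1-D (series) or 2-D (draws x length)")
    m = arr.shape[1]
    if m < 3:
        raise ValueError(f"need a series of length >= 3, got {m}")
    if positions is None:
        positions = np.arange(m)
    positions = np.asarray(positions)
    if positions.size != m:
        raise ValueError("positions must match series length")
    d2 = arr[:, 2:] - 2.0 * arr[:, 1:-1] + arr[:, :-2]
    lo, hi = (1 - interval) / 2, 1 - (1 - interval) / 2
    if point:
        c = d2[0]
        return CurvatureSeries(positions[1:-1], c, c.copy(), c.copy(), None)
    return CurvatureSeries(
        positions[1:-1],
        d2.mean(axis=0),
        np.quantile(d2, lo, axis=0),
        np.quantile(d2, hi, axis=0),
        d2,
    )


def inflection_points(
    curv: CurvatureSeries,
    credible_level: float = 0.95,
    min_magnitude: float = 0.0,
) -> list[tuple[int, str]]:
    """Flag positions whose curvature CrI excludes zero.

    A position is flagged when the central ``credible_level`` interval of
    its curvature excludes 0 and the absolute posterior mean is at least
    ``min_magnitude``; the sign of the mean tags it upward (convex) or
    downward (concave).  Requires draw-based curvature.
    """
    if curv.draws is None:
        raise ValueError("inflection flagging needs curvature computed from draws")
    lo_q, hi_q = (1 - credible_level) / 2, 1 - (1 - credible_level) / 2
    lower = np.quantile(curv.draws, lo_q, axis=0)
    upper = np.quantile(curv.draws, hi_q, axis=0)
    out: list[tuple[int, str]] = []
    for pos, mu, lo, hi in zip(curv.positions, curv.mean, lower, upper):
        if (lo > 0 or hi < 0) and abs(mu) >= min_magnitude:
            out.append((int(pos), "upward" if mu > 0 else "downward"))
    return out


@dataclass
class JoinpointFit:
    """Selected continuous piecewise-linear trend model."""

    joinpoints: list[int]       # years, strictly increasing, interior
    slopes: list[float]         # one per segment (outcome units / year)
    intercept: float            # fitted value at the first year
    sse: float
    mbic: float
    fitted: np.ndarray
    candidates: pd.DataFrame    # per (k, placement): sse, mbic

    @property
    def n_joinpoints(self) -> int:
        return len(self.joinpoints)


def _hinge_design(x: np.ndarray, knots: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(x), x] + [np.maximum(x - c, 0.0) for c in knots]
    return np.column_stack(cols)


def mbic(sse: float, n: int, k: int, floor: float) -> float:
    """Modified BIC: n ln(SSE/n) + (2k+2) ln n, with SSE floored for exact fits."""
    return n * np.log(max(sse, floor) / n) + (2 * k + 2) * np.log(n)


def joinpoint_fit(
    years: np.ndarray,
    values: np.ndarray,
    max_joinpoints: int = 3,
) -> JoinpointFit:
    """Exhaustive-search joinpoint regression with MBIC model selection.

    Candidate joinpoints sit at observed years, with at least two
    observations strictly on each side of every joinpoint and strictly
    between consecutive joinpoints.  For each candidate placement a
    continuous piecewise-linear model is fitted by least squares; the
    (k, placement) minimizing MBIC wins, ties going to fewer joinpoints
    and then to the earliest placement.
    """
    years = np.asarray(years, float)
    values = np.asarray(values, float)
    if years.ndim != 1 or years.shape != values.shape:
        raise ValueError("years and values must be matching 1-D arrays")
    order = np.argsort(years)
    years, values = years[order], values[order]
    n = years.size
    k_max = int(max_joinpoints)
    if k_max < 0:
        raise ValueError("max_joinpoints must be >= 0")
    n_min = 2 * (k_max + 1) + k_max
    if n < n_min:
        raise ValueError(
            f"series of length {n} too short for {k_max} joinpoints (need >= {n_min})"
        )

    x = years - years[0]
    sse_floor = max(float(np.sum(values**2)) * 1e-14, 1e-300)
    best = None
    cand_rows = []
    for k in range(k_max + 1):
        # knot indices: >=2 points strictly before, between and after knots
        combos = (
            c for c in itertools.combinations(range(2, n - 2), k)
            if all(c[j + 1] - c[j] >= 3 for j in range(k - 1))
        ) if k else iter([()])
        for idx in combos:
            knots = tuple(x[list(idx)])
            Z = _hinge_design(x, knots)
            coef, _, _, _ = np.linalg.lstsq(Z, values, rcond=None)
            resid = values - Z @ coef
            sse = float(resid @ resid)
            crit = float(mbic(sse, n, k, sse_floor))
            key = (crit, k, idx)
            cand_rows.append({
                "k": k,
                "joinpoints": tuple(int(years[i]) for i in idx),
                "sse": sse,
                "mbic": crit,
            })
            if best is None or key < best[0]:
                best = (key, idx, coef, sse, crit, Z)

    (_, idx, coef, sse, crit, Z) = best
    slopes = list(np.cumsum(coef[1:]).astype(float))
    return JoinpointFit(
        joinpoints=[int(years[i]) for i in idx],
        slopes=slopes,
        intercept=float(coef[0]),
        sse=sse,
        mbic=crit,
        fitted=Z @ coef,
        candidates=pd.DataFrame(cand_rows),
    )
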