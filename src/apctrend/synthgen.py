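"""Synthetic school-health-record generator with known APC structure.

The real registry behind routine annual school health assessments is
restricted, so every downstream stage is exercised on populations
generated here.  Each synthetic child is assigned a birth year; their
annual check-up visits advance along the cohort diagonal (age and period
increase together), which reproduces the within-child structure that the
one-record-per-child sampling step removes.  Outcomes are drawn
independently around additive cell means

    y = age_curve[a] + period_curve[p] + cohort_curve[p - a] + Normal(0, sd)

The default truth curves qualitatively mimic paediatric blood-pressure
surveillance in a developed East-Asian city — an upward inflection of the
age curve around age 10 in boys / 9 in girls, a period minimum around
2005, cohort inflections around 1993 and 1998 — with no claim of
quantitative fidelity; every curve is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tabulate import APCDesign, STRATUM_COLUMNS, cohort_label

#: canonical individual-record columns
RECORD_COLUMNS = ["child_id", "sex", "age", "period", "outcome_kind", "outcome"]

#: sentinel stratum size marking noise-free oracle tables
ORACLE_N = -1


class TruthError(ValueError):
    """Truth curves do not cover the design grid."""


@dataclass(frozen=True)
class APCTruth:
    """Generating analogues of the age (level), period and cohort (offset) effects.

    ``age_curve`` carries the absolute outcome level per age; the period
    and cohort curves are additive offsets.  ``residual_sd`` is the
    individual-level residual standard deviation in outcome units.
    """

    age_curve: Mapping[int, float]
    period_curve: Mapping[int, float]
    cohort_curve: Mapping[int, float]
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.residual_sd >= 0:
            raise TruthError("residual_sd must be >= 0")

    def validate_covers(self, design: APCDesign) -> None:
        for name, curve, grid in (
            ("age_curve", self.age_curve, design.ages),
            ("period_curve", self.period_curve, design.periods),
            ("cohort_curve", self.cohort_curve, design.cohorts),
        ):
            for point in grid:
                if int(point) not in curve:
                    raise TruthError(f"{name} missing grid point {int(point)}")

    def cell_mean(self, age: int, period: int) -> float:
        return (
            self.age_curve[int(age)]
            + self.period_curve[int(period)]
            + self.cohort_curve[int(period) - int(age)]
        )


def _piecewise(grid: np.ndarray, knots: list[tuple[int, float]]) -> dict[int, float]:
    """Piecewise-linear curve through (year, value) knots, evaluated on grid."""
    xs, ys = zip(*sorted(knots))
    vals = np.interp(grid, xs, ys)
    return {int(g): float(v) for g, v in zip(grid, vals)}


def default_truth(design: APCDesign, sex: str = "male", residual_sd: float = 8.0) -> APCTruth:
    """A realistic systolic-BP-like truth on the given design.

    Age level rises through puberty with the upward inflection ~age 10
    for boys and ~9 for girls; the period offset is V-shaped with its
    minimum at 2005; the cohort offset has inflections around 1993
    (upward) and 1998 (downward).  Residual SD defaults to 8 mmHg,
    a typical individual-level spread for childhood systolic BP.
    """
    ages, periods, cohorts = design.ages, design.periods, design.cohorts
    bend = 10 if sex == "male" else 9
    a_lo, a_hi = int(ages[0]), int(ages[-1])
    age_knots = [(a_lo, 100.0), (min(max(bend, a_lo), a_hi), 102.0), (a_hi, 115.0)]
    age_curve = _piecewise(ages, list(dict(age_knots).items()))

    p_lo, p_hi = int(periods[0]), int(periods[-1])
    p_mid = min(max(2005, p_lo), p_hi)
    period_curve = _piecewise(periods, list(dict([(p_lo, 1.5), (p_mid, -1.0), (p_hi, 0.8)]).items()))

    c_lo, c_hi = int(cohorts[0]), int(cohorts[-1])
    c_knots = dict(
        [(c_lo, 0.0)]
        + [(y, v) for y, v in ((1993, -0.8), (1998, 0.6)) if c_lo < y < c_hi]
        + [(c_hi, 0.0)]
    )
    cohort_curve = _piecewise(cohorts, list(c_knots.items()))
    return APCTruth(age_curve, period_curve, cohort_curve, residual_sd)


def generate_population(
    truth: APCTruth,
    design: APCDesign,
    visits_per_child: int = 1,
    n_children_per_birth_year: int = 100,
    seed: int = 0,
    sex: str = "male",
    outcome_kind: str = "sbp",
) -> pd.DataFrame:
    """Simulate annual check-up records for cohorts of synthetic children.

    Each child carries a birth year (cohort index); their visits occupy up
    to ``visits_per_child`` consecutive (age, period) cells along the
    cohort diagonal, starting at a uniformly drawn in-design entry point.
    Outcomes are independent normal draws around the additive cell mean.
    Deterministic given ``seed``.
    """
    if visits_per_child < 1 or n_children_per_birth_year < 1:
        raise ValueError("visits_per_child and n_children_per_birth_year must be >= 1")
    truth.validate_covers(design)
    rng = np.random.default_rng(seed)

    rows: list[tuple] = []
    for k in design.cohorts:
        # ages at which cohort k is observable inside the grid
        ages_k = [int(a) for a in design.ages if design.contains(a, k + a)]
        if not ages_k:
            continue
        for child in range(n_children_per_birth_year):
            child_id = f"c{k}_{child}"
            start = rng.integers(0, len(ages_k))
            visit_ages = ages_k[start : start + visits_per_child]
            for a in visit_ages:
                p = k + a
                mu = truth.cell_mean(a, p)
                y = mu + rng.normal(0.0, truth.residual_sd) if truth.residual_sd > 0 else mu
                rows.append((child_id, sex, a, p, outcome_kind, y))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def select_one_record_per_child(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep exactly one uniformly chosen record per child.

    This mirrors the one-time-point-per-participant sampling used to
    remove within-child correlation before aggregation.  Deterministic
    given ``seed``; the output is a row subset of the input.
    """
    if records.empty:
        return records.copy()
    rng = np.random.default_rng(seed)
    # stable order so the draw depends only on (data, seed), not row order
    ordered = records.sort_values(["child_id", "age"], kind="mergesort")
    picks = []
    for _, idx in ordered.groupby("child_id", sort=True).indices.items():
        picks.append(ordered.index[idx[rng.integers(0, len(idx))]])
    return records.loc[sorted(picks)]


def truth_to_cell_means(
    truth: APCTruth, design: APCDesign, sex: str = "male"
) -> pd.DataFrame:
    """Noise-free stratum table: exact additive cell means on the full grid.

    Serves as the exact-recovery oracle for aggregation and fitting; the
    ``n`` column holds the sentinel ``ORACLE_N`` and ``sd`` is 0.
    """
    truth.validate_covers(design)
    rows = []
    for p in design.periods:
        for a in design.ages:
            rows.append(
                (sex, int(a), int(p), int(p - a), cohort_label(a, p), ORACLE_N,
                 truth.cell_mean(a, p), 0.0)
            )
    return pd.DataFrame(rows, columns=STRATUM_COLUMNS)
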