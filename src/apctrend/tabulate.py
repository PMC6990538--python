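"""Age-period-cohort design construction and stratum aggregation.

An APC design is a rectangular grid of integer ages (rows) by integer
calendar periods (columns).  Each cell belongs to the birth cohort
``k = period - age``; the ``A + P - 1`` cohort indices run along the
anti-diagonals of the grid.  Because a child of age ``a`` examined in
school year ``p`` can have been born in either of two adjacent calendar
years, cohorts are displayed with two-year labels ``"(k-1)-k"``.

Identifiability of the additive decomposition requires reference
constraints: here the second and penultimate periods and the central
birth cohort are pinned to zero, with no constraint on age (the age
effects absorb the overall level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical StratumTable columns
STRATUM_COLUMNS = ["sex", "age", "period", "cohort_index", "cohort_label", "n", "mean", "sd"]


class DesignError(ValueError):
    """Invalid APC design specification."""


@dataclass(frozen=True)
class APCDesign:
    """Rectangular age-by-period grid with induced cohorts and references.

    Attributes
    ----------
    ages, periods : np.ndarray
        Consecutive integer years; ``A`` and ``P`` levels.
    cohorts : np.ndarray
        Integer cohort indices ``period - age``; ``C = A + P - 1`` levels,
        spanning ``period_min - age_max`` .. ``period_max - age_min``.
    ref_period_low, ref_period_high : int
        The second and penultimate periods (zero references).
    ref_cohort : int
        The central cohort index (zero reference).
    """

    ages: np.ndarray
    periods: np.ndarray
    cohorts: np.ndarray = field(init=False)
    ref_period_low: int = field(init=False)
    ref_period_high: int = field(init=False)
    ref_cohort: int = field(init=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        periods = np.asarray(self.periods, dtype=int)
        if ages.size == 0 or periods.size == 0:
            raise DesignError("age and period grids must be non-empty")
        for name, grid in (("age", ages), ("period", periods)):
            if grid.size > 1 and not np.array_equal(grid, np.arange(grid[0], grid[-1] + 1)):
                raise DesignError(f"{name} grid must be consecutive integers")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "periods", periods)
        cohorts = np.arange(periods[0] - ages[-1], periods[-1] - ages[0] + 1)
        object.__setattr__(self, "cohorts", cohorts)
        # "second and penultimate" in 1-based grid order; degenerate grids
        # (P < 2) fall back to the only available positions.
        P = periods.size
        object.__setattr__(self, "ref_period_low", int(periods[min(1, P - 1)]))
        object.__setattr__(self, "ref_period_high", int(periods[max(P - 2, 0)]))
        # central cohort: position ceil(C/2) in 1-based order
        C = cohorts.size
        object.__setattr__(self, "ref_cohort", int(cohorts[(C + 1) // 2 - 1]))

    @property
    def n_ages(self) -> int:
        return self.ages.size

    @property
    def n_periods(self) -> int:
        return self.periods.size

    @property
    def n_cohorts(self) -> int:
        return self.cohorts.size

    def cohort_of(self, age: int, period: int) -> int:
        return int(period) - int(age)

    def contains(self, age: int, period: int) -> bool:
        return self.ages[0] <= age <= self.ages[-1] and self.periods[0] <= period <= self.periods[-1]


def build_design(age_min: int, age_max: int, period_min: int, period_max: int) -> APCDesign:
    """Build the APC design for consecutive integer age and period grids.

    Examples
    --------
    >>> d = build_design(9, 18, 1999, 2014)
    >>> d.n_ages, d.n_periods, d.n_cohorts
    (10, 16, 25)
    >>> d.ref_period_low, d.ref_period_high, d.ref_cohort
    (2000, 2013, 1993)
    """
    if age_min > age_max:
        raise DesignError(f"age_min ({age_min}) > age_max ({age_max})")
    if period_min > period_max:
        raise DesignError(f"period_min ({period_min}) > period_max ({period_max})")
    return APCDesign(
        ages=np.arange(age_min, age_max + 1),
        periods=np.arange(period_min, period_max + 1),
    )


def cohort_label(age: int, period: int) -> str:
    """Two-year birth-cohort label for a cell: ``"(k-1)-k"`` with k = period - age.

    A child of age ``a`` seen in school year ``p`` was born in ``p - a``
    or ``p - a - 1``, hence the two-year span, displayed by its earliest
    year in figures.

    >>> cohort_label(18, 1999)
    '1980–1981'
    >>> cohort_label(9, 2014)
    '2004–2005'
    """
    k = int(period) - int(age)
    return f"{k - 1}–{k}"


class EmptyTableError(ValueError):
    """No records fall inside the design grid."""


def aggregate(records: pd.DataFrame, design: APCDesign, min_n: int = 1) -> pd.DataFrame:
    """Aggregate individual records into a per-(sex, age, period) stratum table.

    Parameters
    ----------
    records : DataFrame
        Individual rows with columns ``sex, age, period, outcome`` (extra
        columns ignored).  Rows outside the design grid are dropped with a
        logged count.
    design : APCDesign
    min_n : int
        Cells with fewer retained records are dropped with a warning
        (the model fits cell means, so a floor of 1 is the default).

    Returns
    -------
    DataFrame with columns sex, age, period, cohort_index, cohort_label,
    n, mean, sd — one row per occupied cell; ``sum(n)`` equals the number
    of retained records.
    """
    req = {"sex", "age", "period", "outcome"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    in_range = (
        records["age"].between(design.ages[0], design.ages[-1])
        & records["period"].between(design.periods[0], design.periods[-1])
    )
    dropped = int((~in_range).sum())
    if dropped:
        logger.info("aggregate: dropped %d out-of-design records", dropped)
    kept = records.loc[in_range]
    if kept.empty:
        raise EmptyTableError("no records inside the design grid")

    grouped = kept.groupby(["sex", "age", "period"], observed=True)["outcome"]
    table = grouped.agg(n="size", mean="mean", sd="std").reset_index()
    below = table["n"] < min_n
    if below.any():
        logger.warning("aggregate: dropping %d cells with n < %d", int(below.sum()), min_n)
        table = table.loc[~below]
    table["cohort_index"] = table["period"].astype(int) - table["age"].astype(int)
    table["cohort_label"] = [cohort_label(a, p) for a, p in zip(table["age"], table["period"])]
    return table[STRATUM_COLUMNS].sort_values(["sex", "period", "age"]).reset_index(drop=True)


def design_summary(design: APCDesign, total_n: int) -> dict:
    """Design bookkeeping: strata count, parameter count and mean stratum size.

    The per-stratum average is truncated toward zero, matching the
    convention of reporting e.g. 196,299 boys over 160 strata as an
    average of 1226 per stratum.
    """
    if total_n < 0:
        raise ValueError("total_n must be >= 0")
    strata = design.n_ages * design.n_periods
    return {
        "strata": strata,
        "parameters": design.n_ages + design.n_periods + design.n_cohorts,
        "cohorts": design.n_cohorts,
        "mean_n_per_stratum": int(total_n // strata),
    }
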