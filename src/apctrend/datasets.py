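"""Bundled reference data.

``hk_observed_means.csv`` holds the published observed mean systolic BP,
diastolic BP (mmHg) and BMI (kg/m^2) series from annual school health
assessments in Hong Kong, by sex and broad age group (childhood 9-11
years, adolescence 12-18), over examination years 1999-2014 (BP) and
1996-2014 (BMI).  These printed aggregate series are the only part of
the restricted registry that is public; they anchor worked examples and
trend/changepoint checks.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def load_observed_means() -> pd.DataFrame:
    """Tidy observed-series table: outcome, age_group, sex, year, mean."""
    with resources.files(__package__).joinpath("data/hk_observed_means.csv").open() as f:
        return pd.read_csv(f)


def observed_series(outcome: str, sex: str, age_group: str = "9-11") -> pd.Series:
    """One yearly mean series, indexed by year.

    Parameters
    ----------
    outcome : {"sbp", "dbp", "bmi"}
    sex : {"male", "female"}
    age_group : {"9-11", "12-18"}
    """
    df = load_observed_means()
    sel = df[(df.outcome == outcome) & (df.sex == sex) & (df.age_group == age_group)]
    if sel.empty:
        raise KeyError(f"no series for ({outcome!r}, {sex!r}, {age_group!r})")
    s = sel.set_index("year")["mean"].sort_index()
    s.index = s.index.astype(int)
    s.index.name = "year"
    return s


def series_extrema(s: pd.Series) -> dict:
    """Minimum and maximum of a yearly series with the years they occur."""
    return {
        "min_year": int(s.idxmin()), "min_value": float(s.min()),
        "max_year": int(s.idxmax()), "max_value": float(s.max()),
    }
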