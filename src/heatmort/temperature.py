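"""Collapse the temperature grid to district daily series and static covariates."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import StudyConfig

__all__ = [
    "district_daily_temperature",
    "district_altitude",
    "summer_mean_temperature",
]


def district_daily_temperature(
    grid_temps: pd.DataFrame, cells: pd.DataFrame
) -> pd.DataFrame:
    """Population-weighted mean daily temperature per district.

    ``T_d(t) = sum_c w_cd * pop_c * T_c(t) / sum_c w_cd * pop_c`` over the
    member cells of each district.  Membership weights may be fractional
    (a cell straddling districts contributes to both).

    Parameters
    ----------
    grid_temps : DataFrame with columns ``cell_id, date, temperature``;
        every cell must cover every date.
    cells : DataFrame with columns ``cell_id, population, district_id, weight``.

    Returns
    -------
    DataFrame with columns ``district_id, date, mean_temp``, one row per
    district-day.
    """
    cells = cells.copy()
    cells["eff_weight"] = cells["weight"] * cells["population"]
    totals = cells.groupby("district_id")["eff_weight"].sum()
    zero = totals[totals <= 0.0]
    if not zero.empty:
        raise ValueError(
            "zero total weighted population for district(s): "
            + ", ".join(zero.index.astype(str))
        )

    n_dates = grid_temps.groupby("cell_id")["date"].nunique()
    if n_dates.nunique() > 1:
        raise ValueError("grid temperature table has missing cell-dates")
    missing = set(cells["cell_id"]) - set(n_dates.index)
    if missing:
        raise ValueError(f"no temperature series for cell(s): {sorted(missing)}")

    merged = grid_temps.merge(
        cells[["cell_id", "district_id", "eff_weight"]], on="cell_id"
    )
    merged["wt"] = merged["eff_weight"] * merged["temperature"]
    agg = merged.groupby(["district_id", "date"], sort=True)[["wt", "eff_weight"]].sum()
    out = (agg["wt"] / agg["eff_weight"]).rename("mean_temp").reset_index()
    return out


def district_altitude(cells: pd.DataFrame) -> pd.Series:
    """Unweighted mean altitude of member cells per district.

    Weights determine membership only (any cell with weight > 0 counts
    once); magnitude is deliberately ignored.
    """
    members = cells[cells["weight"] > 0]
    if members.empty:
        raise ValueError("no cells with positive membership weight")
    return members.groupby("district_id")["altitude"].mean()


def summer_mean_temperature(
    district_temps: pd.DataFrame, config: StudyConfig
) -> pd.Series:
    """Arithmetic mean temperature over all season days of the study period."""
    df = district_temps.copy()
    dates = pd.DatetimeIndex(df["date"])
    in_season = dates.month.isin(sorted(config.season_months)) & (
        (dates >= pd.Timestamp(config.start_date))
        & (dates <= pd.Timestamp(config.end_date))
    )
    season = df[np.asarray(in_season)]

    expected = pd.date_range(config.start_date, config.end_date, freq="D")
    expected = expected[expected.month.isin(sorted(config.season_months))]
    for did, grp in season.groupby("district_id"):
        missing = expected.difference(pd.DatetimeIndex(grp["date"]))
        if len(missing):
            raise ValueError(
                f"district {did} missing {len(missing)} season days, "
                f"first: {missing[0].date()}"
            )
    return season.groupby("district_id")["mean_temp"].mean()
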