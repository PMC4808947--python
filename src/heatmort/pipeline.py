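"""End-to-end orchestration of the analysis stages.

These helpers chain the stages on in-memory tables; the CLI exposes the
same steps on CSV files so each stage can also run independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import BaselineFit, BaselineSpec, fit_stratified_baseline
from .config import StudyConfig
from .ecology import oecd_criterion, ses_index
from .excess import (
    HotDayMask,
    MCBound,
    classify_districts,
    detect_hot_days,
    mc_null_bounds,
    mean_deviation_on_days,
    relative_deviations,
    _season_mask,
)
from .spells import (
    GroupDefinition,
    LagProfile,
    aggregate_group_series,
    assign_groups,
    cumulative_excess,
    detect_hot_spells,
    lag_profile,
    mc_lag_bounds,
    refit_group_baseline,
)
from .standardize import StandardPopulation, standardize_series
from .synthetic import SimScenario, simulate_all
from .temperature import district_altitude, summer_mean_temperature

log = logging.getLogger("heatmort")


@dataclass
class DistrictResults:
    config: StudyConfig
    rates: pd.DataFrame
    fit: BaselineFit
    deviations: pd.DataFrame
    hot_masks: dict[str, HotDayMask]
    dev_cvd: dict[str, float]
    bounds: dict[str, MCBound]
    classification: pd.DataFrame
    covariates: pd.DataFrame


@dataclass
class GroupResults:
    groups: list[GroupDefinition]
    group_rates: pd.DataFrame
    group_temps: pd.DataFrame
    fit: BaselineFit
    deviations: pd.DataFrame
    spells: dict[str, list]
    profiles: dict[str, LagProfile]
    cumulative: dict[str, dict]


def run_district_pipeline(
    data: dict[str, pd.DataFrame],
    config: StudyConfig,
    family: str = "quasipoisson",
) -> DistrictResults:
    """Standardize, fit the baseline, and score every district's DevCVD."""
    standard = StandardPopulation.from_frame(data["standard_population"])
    rates = standardize_series(data["mortality"], standard)
    spec = BaselineSpec.from_config(config, family=family)
    fit = fit_stratified_baseline(rates, spec)
    deviations = relative_deviations(fit.fitted)

    district_temps = data["district_temps"]
    dev_cvd: dict[str, float] = {}
    bounds: dict[str, MCBound] = {}
    hot_masks: dict[str, HotDayMask] = {}
    for i, (did, dtemps) in enumerate(district_temps.groupby("district_id")):
        mask = detect_hot_days(dtemps, config)
        hot_masks[did] = mask
        ddev = deviations[deviations["district_id"] == did]
        dev_cvd[did] = mean_deviation_on_days(ddev, mask.hot_dates)
        dates = pd.DatetimeIndex(ddev["date"])
        summer = ddev[np.asarray(_season_mask(dates, config))]
        bounds[did] = mc_null_bounds(
            summer["deviation"].to_numpy(),
            len(mask.hot_dates),
            config,
            seed=config.rng_seed + 1000 + i,
        )
    classification = classify_districts(dev_cvd, bounds)

    covariates = build_district_covariates(data, config, dev_cvd)
    return DistrictResults(
        config=config,
        rates=rates,
        fit=fit,
        deviations=deviations,
        hot_masks=hot_masks,
        dev_cvd=dev_cvd,
        bounds=bounds,
        classification=classification,
        covariates=covariates,
    )


def build_district_covariates(
    data: dict[str, pd.DataFrame],
    config: StudyConfig,
    dev_cvd: dict[str, float] | None = None,
    degenerate_ses: str = "error",
) -> pd.DataFrame:
    """Assemble the per-district covariate table for the ecological stage."""
    cov = data["covariates"].copy()
    ses = ses_index(cov, degenerate=degenerate_ses)
    oecd = oecd_criterion(data["municipalities"])
    summer_t = summer_mean_temperature(data["district_temps"], config)
    altitude = district_altitude(data["cells"])
    cov = cov.set_index("district_id")
    cov["ses"] = ses
    cov["oecd"] = oecd
    cov["summer_t"] = summer_t
    cov["altitude"] = altitude
    if dev_cvd is not None:
        cov["dev_cvd"] = pd.Series(dev_cvd)
    return cov.reset_index()


def run_group_pipeline(
    district_results: DistrictResults,
    data: dict[str, pd.DataFrame],
    config: StudyConfig,
    family: str = "quasipoisson",
    mc_cumulative: bool = True,
) -> GroupResults:
    """Group districts, refit the baseline per group, profile hot spells."""
    groups = [
        g
        for g in assign_groups(district_results.covariates, config)
        if g.members
    ]
    if not groups:
        raise ValueError("no district group has any members under the current cuts")
    group_rates, group_temps = aggregate_group_series(
        groups, district_results.rates, data["district_temps"]
    )
    spec = BaselineSpec.from_config(config, family=family)
    fit = refit_group_baseline(group_rates, spec)
    deviations = relative_deviations(fit.fitted)

    spells, profiles, cumulative = {}, {}, {}
    for i, g in enumerate(groups):
        gtemps = group_temps[group_temps["district_id"] == g.label]
        gspells = detect_hot_spells(gtemps, config)
        spells[g.label] = gspells
        if not gspells:
            log.warning("group %s has no hot spells", g.label)
            continue
        gdev = deviations[deviations["district_id"] == g.label]
        profile = lag_profile(gdev, gspells, config)
        cum_q = None
        if mc_cumulative:
            per_lag, cum_q = mc_lag_bounds(
                gdev, len(gspells), config, seed=config.rng_seed + 2000 + i
            )
            profile.bounds = per_lag
        profiles[g.label] = profile
        cumulative[g.label] = cumulative_excess(profile, cum_q)
    return GroupResults(
        groups=groups,
        group_rates=group_rates,
        group_temps=group_temps,
        fit=fit,
        deviations=deviations,
        spells=spells,
        profiles=profiles,
        cumulative=cumulative,
    )


def run_scenario(
    scenario: SimScenario,
    config: StudyConfig | None = None,
    with_groups: bool = False,
    family: str = "quasipoisson",
    mc_cumulative: bool = True,
):
    """Simulate a scenario and run the pipeline on it (tests, acceptance)."""
    config = config or scenario.study_config()
    data = simulate_all(scenario)
    district = run_district_pipeline(data, config, family=family)
    if not with_groups:
        return data, district, None
    group = run_group_pipeline(
        district, data, config, family=family, mc_cumulative=mc_cumulative
    )
    return data, district, group
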