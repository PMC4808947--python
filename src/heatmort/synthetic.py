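"""Synthetic inputs for the full pipeline.

Generates a gridded daily temperature field, a grid-to-district membership
table, district mortality counts by age band with a known acute heat effect
and an optional frail-pool depletion mechanism (mortality displacement),
plus census-like district covariates and a municipality table for the
rurality criterion.  Every output is a plain :class:`pandas.DataFrame`
reproducible from ``rng_seed`` alone.

Scenario presets
----------------
``null``
    no heat effect, no displacement — for coverage checks.
``acute_only``
    a step +20 % expected mortality on days above the district's own summer
    90th percentile, no displacement — for parameter recovery.
``urban_no_displacement``
    same acute effect, no frail pool.
``rural_displacement``
    acute effect drawn largely from a depletable frail pool, so hot spells
    are followed by a mortality deficit.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import StudyConfig

__all__ = [
    "SimScenario",
    "scenario_preset",
    "simulate_districts",
    "simulate_temperature_grid",
    "simulate_mortality",
    "expected_death_means",
    "default_standard_population",
    "simulate_all",
]

#: z-scored deprivation offsets and urbanization targets for the four
#: factorial quadrants districts cycle through (guarantees that each of the
#: SES/urbanization groups is populated once n_districts >= 4).
_QUADRANTS = (
    {"label": "high_ses_urban", "deprived": False, "urban": True},
    {"label": "high_ses_rural", "deprived": False, "urban": False},
    {"label": "low_ses_urban", "deprived": True, "urban": True},
    {"label": "low_ses_rural", "deprived": True, "urban": False},
)


@dataclass(frozen=True)
class SimScenario:
    """Knobs of the generative model.

    ``daily_sd`` is the innovation standard deviation of the shared AR(1)
    temperature anomaly; ``heat_log_rr_per_degree`` scales with degrees
    above the district's own summer ``heat_threshold_quantile`` while
    ``heat_step_log_rr`` is a flat log relative risk on exceedance days
    (used by presets that need an exactly known percentage effect).
    ``frail_pool_fraction`` routes that share of expected deaths through a
    depletable pool; zero disables displacement entirely.
    """

    n_districts: int = 8
    n_cells: int = 16
    years: int = 16
    start_year: int = 1994
    temp_mean_annual: float = 9.0
    temp_seasonal_amplitude: float = 10.0
    ar1_coefficient: float = 0.75
    daily_sd: float = 2.0
    cell_noise_sd: float = 0.3
    lapse_rate: float = 6.5
    age_bands: tuple[tuple[str, float], ...] = (
        ("0-64", 2.0e-6),
        ("65-79", 4.0e-5),
        ("80+", 3.0e-4),
    )
    band_shares: tuple[float, ...] = (0.85, 0.11, 0.04)
    district_population: float = 100_000.0
    dow_effects: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 0.97, 0.96)
    trend_slope: float = -0.01
    seasonal_mortality_amplitude: float = 0.12
    heat_threshold_quantile: float = 0.90
    heat_log_rr_per_degree: float = 0.0
    heat_step_log_rr: float = 0.0
    frail_pool_fraction: float = 0.0
    frail_replenish_rate: float = 0.15
    frail_pool_scale: float = 0.25
    identical_districts: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.n_districts < 4:
            raise ValueError("n_districts must be >= 4")
        if self.n_cells < self.n_districts:
            raise ValueError("n_cells must be >= n_districts (each district needs a cell)")
        for frac_name in (
            "ar1_coefficient",
            "heat_threshold_quantile",
            "frail_pool_fraction",
            "frail_replenish_rate",
        ):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must lie in [0, 1], got {v}")
        if self.ar1_coefficient >= 1.0:
            raise ValueError("ar1_coefficient must be < 1")
        if any(h <= 0 for _, h in self.age_bands):
            raise ValueError("age-band hazards must be positive")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries")

    @property
    def start_date(self) -> dt.date:
        return dt.date(self.start_year, 1, 1)

    @property
    def end_date(self) -> dt.date:
        return dt.date(self.start_year + self.years - 1, 12, 31)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, self.end_date, freq="D")

    def study_config(self, **overrides) -> StudyConfig:
        base = dict(
            start_date=self.start_date,
            end_date=self.end_date,
            hot_day_quantile=self.heat_threshold_quantile,
        )
        base.update(overrides)
        return StudyConfig(**base)


_PRESETS: Mapping[str, dict] = {
    "null": {},
    # recovery-oracle design: iid flat-summer climate spreads hot days
    # uniformly over June-August, minimizing how much of the injected step
    # the 7-df/yr baseline spline can absorb
    "acute_only": {
        "heat_step_log_rr": float(np.log(1.2)),
        "temp_seasonal_amplitude": 0.0,
        "ar1_coefficient": 0.0,
        "daily_sd": 4.0,
        "district_population": 400_000.0,
    },
    "urban_no_displacement": {
        "heat_step_log_rr": float(np.log(1.5)),
        "n_districts": 12,
        "n_cells": 24,
        "district_population": 1_200_000.0,
        "ar1_coefficient": 0.85,
    },
    "rural_displacement": {
        "heat_step_log_rr": float(np.log(1.5)),
        "n_districts": 12,
        "n_cells": 24,
        "district_population": 400_000.0,
        "frail_pool_fraction": 0.9,
        "frail_replenish_rate": 0.02,
        "frail_pool_scale": 0.1,
    },
}


def scenario_preset(name: str, **overrides) -> SimScenario:
    """Return a named scenario preset, optionally overriding fields."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return SimScenario(**{**_PRESETS[name], **overrides})


def _seeds(scenario: SimScenario, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(scenario.rng_seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def simulate_districts(
    scenario: SimScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the static geography: cells, municipalities, covariates.

    Returns ``(cells, municipalities, covariates)`` where ``cells`` has
    columns ``cell_id, altitude, population, district_id, weight`` (whole
    cells, weight 1), ``municipalities`` has ``district_id,
    municipality_id, municipality_pop, density`` and ``covariates`` carries
    the census/land-cover shares used by the ecological regression.
    """
    rng = _seeds(scenario, 3)[0]
    n_d, n_c = scenario.n_districts, scenario.n_cells

    districts = [f"D{i:03d}" for i in range(n_d)]
    quadrant = [_QUADRANTS[i % 4] for i in range(n_d)]

    cov_rows = []
    muni_rows = []
    cell_rows = []
    # round-robin cell assignment: every district gets at least one cell
    cell_district = [districts[i % n_d] for i in range(n_c)]

    for i, (did, quad) in enumerate(zip(districts, quadrant)):
        if scenario.identical_districts:
            urban, deprived = False, False
            altitude = 400.0
            pop = 90_000.0
            oecd_target = 30.0
            unemp, lowedu, singles = 9.0, 55.0, 25.0
            impervious = 5.0
            elderly = 16.0
        else:
            urban, deprived = quad["urban"], quad["deprived"]
            altitude = float(
                rng.uniform(150, 320) if urban else rng.uniform(420, 720)
            )
            pop = float(rng.uniform(110_000, 160_000) if urban else rng.uniform(55_000, 90_000))
            oecd_target = float(rng.uniform(5, 20) if urban else rng.uniform(45, 70))
            unemp = float(rng.uniform(11, 16) if deprived else rng.uniform(4, 7))
            lowedu = float(rng.uniform(60, 70) if deprived else rng.uniform(42, 52))
            singles = float(rng.uniform(28, 34) if deprived else rng.uniform(20, 26))
            impervious = float(rng.uniform(7, 14) if urban else rng.uniform(1.5, 4))
            elderly = float(rng.uniform(13, 19))

        cov_rows.append(
            dict(
                district_id=did,
                pct_elderly=elderly,
                pct_low_education=lowedu,
                pct_unemployed=unemp,
                pct_singles=singles,
                pct_impervious=impervious,
                deprived=deprived,
                urban=urban,
            )
        )
        # two municipality strata reproduce the target low-density share
        low_pop = pop * oecd_target / 100.0
        muni_rows.append(
            dict(
                district_id=did,
                municipality_id=f"{did}-L",
                municipality_pop=low_pop,
                density=float(rng.uniform(40, 130)),
            )
        )
        muni_rows.append(
            dict(
                district_id=did,
                municipality_id=f"{did}-H",
                municipality_pop=pop - low_pop,
                density=float(rng.uniform(300, 2500)),
            )
        )

        member_cells = [c for c, d in enumerate(cell_district) if d == did]
        cell_pops = rng.dirichlet(np.ones(len(member_cells))) * pop
        for c, cpop in zip(member_cells, cell_pops):
            cell_rows.append(
                dict(
                    cell_id=f"C{c:04d}",
                    altitude=float(altitude + rng.normal(0, 30)),
                    population=float(cpop),
                    district_id=did,
                    weight=1.0,
                )
            )

    cells = pd.DataFrame(cell_rows).sort_values("cell_id", ignore_index=True)
    municipalities = pd.DataFrame(muni_rows)
    covariates = pd.DataFrame(cov_rows)
    return cells, municipalities, covariates


def simulate_temperature_grid(
    scenario: SimScenario, cells: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Daily mean temperature per grid cell.

    One shared regional AR(1) anomaly rides on a summer-peaking sinusoid;
    each cell adds small independent noise and its altitude lapse, so
    district series are spatially coherent but not identical.
    """
    if cells is None:
        cells, _, _ = simulate_districts(scenario)
    rng = _seeds(scenario, 3)[1]
    dates = scenario.dates()
    n_t = len(dates)
    doy = dates.day_of_year.to_numpy()

    seasonal = scenario.temp_mean_annual + scenario.temp_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 196) / 365.25
    )
    phi, sd = scenario.ar1_coefficient, scenario.daily_sd
    innov = rng.normal(0.0, sd, size=n_t)
    anomaly = np.empty(n_t)
    prev = innov[0] / np.sqrt(1.0 - phi**2) if sd > 0 and phi > 0 else innov[0]
    for t in range(n_t):
        prev = phi * prev + innov[t]
        anomaly[t] = prev

    frames = []
    for row in cells.itertuples(index=False):
        noise = (
            rng.normal(0.0, scenario.cell_noise_sd, size=n_t)
            if scenario.cell_noise_sd > 0
            else 0.0
        )
        temp = seasonal + anomaly + noise - scenario.lapse_rate * row.altitude / 1000.0
        frames.append(
            pd.DataFrame(
                {"cell_id": row.cell_id, "date": dates, "temperature": temp}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _summer_threshold(temps: np.ndarray, months: np.ndarray, q: float) -> float:
    jja = temps[np.isin(months, (6, 7, 8))]
    return float(np.quantile(jja, q))  # linear interpolation of order statistics



def _district_expected_deaths(
    scenario: SimScenario,
    dates: pd.DatetimeIndex,
    temps: np.ndarray,
    deprived: bool,
    hazards: np.ndarray,
    band_pops: np.ndarray,
) -> np.ndarray:
    """Expected deaths per day x band before any frail-pool modulation."""
    months = dates.month.to_numpy()
    doy = dates.day_of_year.to_numpy()
    dow = dates.dayofweek.to_numpy()
    yrs = (dates - dates[0]).days.to_numpy() / 365.25

    thr = _summer_threshold(temps, months, scenario.heat_threshold_quantile)
    exceed = temps > thr
    heat = scenario.heat_log_rr_per_degree * np.maximum(
        0.0, temps - thr
    ) + scenario.heat_step_log_rr * exceed

    log_mod = (
        scenario.trend_slope * yrs
        + scenario.seasonal_mortality_amplitude
        * np.cos(2.0 * np.pi * (doy - 15) / 365.25)
        + np.log(np.asarray(scenario.dow_effects))[dow]
        + heat
    )
    # deprived districts carry a level shift so the district stratum in the
    # baseline model has real signal
    if deprived and not scenario.identical_districts:
        log_mod = log_mod + np.log(1.15)
    mu = hazards[None, :] * band_pops[None, :] * np.exp(log_mod)[:, None]
    assert np.all(mu > 0), "expected death rate must be positive"
    return mu


def expected_death_means(
    scenario: SimScenario, district_temps: pd.DataFrame
) -> pd.DataFrame:
    """Deterministic expected deaths per district-day-band (no frail pool).

    Companion to :func:`simulate_mortality` for checking Poisson totals.
    """
    _, _, covariates = simulate_districts(scenario)
    deprived = dict(zip(covariates.district_id, covariates.deprived))
    hazards = np.array([h for _, h in scenario.age_bands])
    shares = np.asarray(scenario.band_shares)
    band_labels = [b for b, _ in scenario.age_bands]
    out = []
    for did, grp in district_temps.groupby("district_id", sort=True):
        grp = grp.sort_values("date")
        dates = pd.DatetimeIndex(grp["date"])
        mu = _district_expected_deaths(
            scenario, dates, grp["mean_temp"].to_numpy(),
            deprived.get(did, False), hazards, shares * scenario.district_population,
        )
        for b, label in enumerate(band_labels):
            out.append(pd.DataFrame({
                "district_id": did, "date": dates, "age_band": label, "mu": mu[:, b],
            }))
    return pd.concat(out, ignore_index=True)


def simulate_mortality(
    scenario: SimScenario, district_temps: pd.DataFrame
) -> pd.DataFrame:
    """Poisson deaths by district, day and age band, with optional harvesting.

    The log expected rate per band stacks the band hazard, a linear yearly
    trend, a winter-peaking seasonal term, the day-of-week factor and the
    acute heat terms above the district's own summer threshold.  When
    ``frail_pool_fraction`` > 0 that share of expected deaths is drawn
    against a pool F(t) updated as
    ``F(t+1) = F(t) + replenish_rate * (F_star - F(t)) - frail_deaths(t)``,
    so heat-driven excess depletes the pool and depresses subsequent rates.
    """
    rng = _seeds(scenario, 3)[2]
    _, _, covariates = simulate_districts(scenario)
    deprived = dict(zip(covariates.district_id, covariates.deprived))

    band_labels = [b for b, _ in scenario.age_bands]
    hazards = np.array([h for _, h in scenario.age_bands])
    shares = np.asarray(scenario.band_shares)

    out = []
    for did, grp in district_temps.groupby("district_id", sort=True):
        grp = grp.sort_values("date")
        dates = pd.DatetimeIndex(grp["date"])
        band_pops = shares * scenario.district_population
        mu = _district_expected_deaths(
            scenario, dates, grp["mean_temp"].to_numpy(),
            deprived.get(did, False), hazards, band_pops,
        )
        n_t = len(dates)
        if scenario.frail_pool_fraction <= 0.0:
            deaths = rng.poisson(mu)
        else:
            # Pool normalization: frail deaths scale with F(t)/F_eq so the
            # heat-free equilibrium reproduces the intended rates exactly.
            # F_star = (1+c) * f*mu_bar / r gives equilibrium F_eq =
            # c * f*mu_bar / r; smaller frail_pool_scale c means a thinner
            # pool, hence stronger and longer-lasting harvesting.
            f = scenario.frail_pool_fraction
            r = scenario.frail_replenish_rate
            c = scenario.frail_pool_scale
            mu_day = mu.sum(axis=1)
            mu_bar = float(mu_day.mean())
            f_eq = max(c * f * mu_bar / max(r, 1e-9), 1e-9)
            f_star = (1.0 + c) * f * mu_bar / max(r, 1e-9)
            pool = f_eq
            deaths = np.zeros_like(mu, dtype=np.int64)
            band_frac = mu / mu_day[:, None]
            for t in range(n_t):
                e_frail = f * mu_day[t] * max(pool, 0.0) / f_eq
                e_robust = (1.0 - f) * mu_day[t]
                d_frail = rng.poisson(e_frail)
                d_robust = rng.poisson(e_robust)
                total = d_frail + d_robust
                deaths[t] = rng.multinomial(total, band_frac[t])
                pool = max(pool + r * (f_star - pool) - d_frail, 0.0)

        for b, label in enumerate(band_labels):
            out.append(
                pd.DataFrame(
                    {
                        "district_id": did,
                        "date": dates,
                        "age_band": label,
                        "deaths": deaths[:, b],
                        "midyear_pop": band_pops[b],
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


def default_standard_population(scenario: SimScenario | None = None) -> pd.DataFrame:
    """Three-band standard population (weights sum to 100 000)."""
    bands = [b for b, _ in (scenario or SimScenario()).age_bands]
    weights = [85_000.0, 11_000.0, 4_000.0][: len(bands)]
    return pd.DataFrame({"age_band": bands, "weight": weights})


def district_adjacency(districts: list[str]) -> pd.DataFrame:
    """Ring contiguity over the sorted district list (synthetic geography)."""
    districts = sorted(districts)
    n = len(districts)
    rows = [
        {"district_id_a": districts[i], "district_id_b": districts[(i + 1) % n]}
        for i in range(n)
    ]
    return pd.DataFrame(rows)


def simulate_all(scenario: SimScenario) -> dict[str, pd.DataFrame]:
    """Generate every pipeline input table for a scenario in one call."""
    cells, municipalities, covariates = simulate_districts(scenario)
    grid = simulate_temperature_grid(scenario, cells)
    from .temperature import district_daily_temperature

    district_temps = district_daily_temperature(grid, cells)
    mortality = simulate_mortality(scenario, district_temps)
    return {
        "cells": cells,
        "municipalities": municipalities,
        "covariates": covariates,
        "grid_temps": grid,
        "district_temps": district_temps,
        "mortality": mortality,
        "standard_population": default_standard_population(scenario),
        "adjacency": district_adjacency(list(covariates.district_id)),
    }
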