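"""Group-level hot-spell analysis: lag profiles and mortality displacement.

Districts are grouped by socioeconomic status (high/low at +/-0.5 SD of the
SES index) crossed with urbanization (OECD rurality below 25 % = urban,
above 37.5 % = rural); member series are averaged, the baseline refitted
with the groups as strata, and relative deviations profiled on days D-2 to
D+14 around hot-spell onsets.  Cumulative sums over D+0..D+3 (immediate
effect) and D+4..D+14 (lagged effect) quantify displacement; significance
comes from a Monte-Carlo null that redraws pseudo-onset dates from summer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import BaselineFit, BaselineSpec, fit_stratified_baseline
from .config import StudyConfig
from .excess import hot_day_threshold, _season_mask

__all__ = [
    "GROUP_LABELS",
    "GroupDefinition",
    "HotSpell",
    "LagProfile",
    "assign_groups",
    "aggregate_group_series",
    "refit_group_baseline",
    "detect_hot_spells",
    "lag_profile",
    "mc_lag_bounds",
    "cumulative_excess",
]

GROUP_LABELS = (
    "high SES-Urban",
    "high SES-Rural",
    "low SES-Urban",
    "low SES-Rural",
)

IMMEDIATE_WINDOW = (0, 3)
LAGGED_WINDOW = (4, 14)


@dataclass(frozen=True)
class GroupDefinition:
    label: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class HotSpell:
    group: str
    onset: pd.Timestamp
    length: int

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("hot spell must span at least 2 days")


@dataclass
class LagProfile:
    group: str
    lags: np.ndarray
    mean_dev: np.ndarray
    n_per_lag: np.ndarray
    n_spells: int
    bounds: pd.DataFrame | None = None  # per-lag lo95/lo90/hi90/hi95

    @property
    def cumulative_immediate(self) -> float:
        return self._window_sum(IMMEDIATE_WINDOW)

    @property
    def cumulative_lagged(self) -> float:
        return self._window_sum(LAGGED_WINDOW)

    @property
    def cumulative_total(self) -> float:
        return self._window_sum((IMMEDIATE_WINDOW[0], LAGGED_WINDOW[1]))

    def _window_sum(self, window: tuple[int, int]) -> float:
        lo, hi = window
        sel = (self.lags >= lo) & (self.lags <= hi)
        return float(self.mean_dev[sel].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"group": self.group, "lag": self.lags, "mean_dev": self.mean_dev,
             "n_spells": self.n_per_lag}
        )
        if self.bounds is not None:
            df = df.merge(self.bounds, on="lag")
        return df


def assign_groups(covariates: pd.DataFrame, config: StudyConfig) -> list[GroupDefinition]:
    """Split districts into the four SES x urbanization groups.

    Districts with intermediate SES (within +/- ``ses_cut`` standard
    deviations) or intermediate rurality (between ``urban_cut`` and
    ``rural_cut``) belong to no group.
    """
    for col in ("ses", "oecd"):
        if col not in covariates.columns:
            raise KeyError(f"covariates table lacks column {col!r}")
    ses = covariates["ses"].to_numpy(dtype=float)
    sd = float(np.std(ses, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("SES index is degenerate (zero variance across districts)")
    z = (ses - ses.mean()) / sd
    oecd = covariates["oecd"].to_numpy(dtype=float)

    high = z > config.ses_cut
    low = z < -config.ses_cut
    urban = oecd < config.urban_cut
    rural = oecd > config.rural_cut

    ids = covariates["district_id"].to_numpy()
    groups = [
        GroupDefinition("high SES-Urban", tuple(ids[high & urban])),
        GroupDefinition("high SES-Rural", tuple(ids[high & rural])),
        GroupDefinition("low SES-Urban", tuple(ids[low & urban])),
        GroupDefinition("low SES-Rural", tuple(ids[low & rural])),
    ]
    return groups


def aggregate_group_series(
    groups: list[GroupDefinition],
    rates: pd.DataFrame,
    district_temps: pd.DataFrame,
    weights: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average member rates and temperatures per day for each group.

    Unweighted arithmetic means by default; pass per-district ``weights``
    (e.g. populations) for a weighted variant.

    Returns ``(group_rates, group_temps)`` with ``district_id`` replaced by
    the group label.
    """
    rate_frames, temp_frames = [], []
    for g in groups:
        if not g.members:
            raise ValueError(f"group {g.label!r} has no member districts")
        r = rates[rates["district_id"].isin(g.members)]
        t = district_temps[district_temps["district_id"].isin(g.members)]
        if weights is None:
            gr = r.groupby("date")["rate"].mean()
            gt = t.groupby("date")["mean_temp"].mean()
        else:
            w = weights.reindex(g.members)

            def _wmean(df, col):
                ww = df["district_id"].map(w)
                return (df[col] * ww).groupby(df["date"]).sum() / ww.groupby(
                    df["date"]
                ).sum()

            gr = _wmean(r, "rate")
            gt = _wmean(t, "mean_temp")
        rate_frames.append(
            pd.DataFrame({"district_id": g.label, "date": gr.index, "rate": gr.values})
        )
        temp_frames.append(
            pd.DataFrame(
                {"district_id": g.label, "date": gt.index, "mean_temp": gt.values}
            )
        )
    return (
        pd.concat(rate_frames, ignore_index=True),
        pd.concat(temp_frames, ignore_index=True),
    )


def refit_group_baseline(group_rates: pd.DataFrame, spec: BaselineSpec) -> BaselineFit:
    """Same stratified model as districts, with the groups as strata."""
    return fit_stratified_baseline(group_rates, spec)


def detect_hot_spells(
    group_temps: pd.DataFrame, config: StudyConfig, threshold: float | None = None
) -> list[HotSpell]:
    """Maximal runs of >= ``min_spell_length`` consecutive hot days.

    A hot day strictly exceeds the group's season-quantile threshold; runs
    must be consecutive calendar days (a season boundary breaks a run).
    """
    (group,) = group_temps["district_id"].unique()
    gt = group_temps.sort_values("date")
    dates = pd.DatetimeIndex(gt["date"])
    temps = gt["mean_temp"].to_numpy(dtype=float)
    in_season = np.asarray(_season_mask(dates, config))
    if threshold is None:
        threshold = hot_day_threshold(temps[in_season], config.hot_day_quantile)
    hot = in_season & (temps > threshold)

    spells: list[HotSpell] = []
    i, n = 0, len(dates)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and hot[j + 1]
            and (dates[j + 1] - dates[j]) == pd.Timedelta(days=1)
        ):
            j += 1
        length = j - i + 1
        if length >= config.min_spell_length:
            spells.append(HotSpell(group=str(group), onset=dates[i], length=length))
        i = j + 1
    return spells


def _profile_from_onsets(
    dev: np.ndarray, onset_idx: np.ndarray, lags: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean deviation per lag over onsets; out-of-range lags are dropped."""
    pos = onset_idx[:, None] + lags[None, :]
    valid = (pos >= 0) & (pos < dev.size)
    vals = np.where(valid, dev[np.clip(pos, 0, dev.size - 1)], np.nan)
    n_per_lag = valid.sum(axis=0)
    if (n_per_lag == 0).any():
        raise ValueError("some lag has no in-period observation for any spell")
    with np.errstate(invalid="ignore"):
        return np.nanmean(vals, axis=0), n_per_lag


def lag_profile(
    group_deviations: pd.DataFrame, spells: list[HotSpell], config: StudyConfig
) -> LagProfile:
    """Average deviation at each lag D-2..D+14 over all hot-spell onsets.

    Lag windows of successive spells may overlap — each spell contributes
    independently at every lag; lags beyond the study period are dropped
    from that spell's contribution (per-lag counts are reported).
    """
    if not spells:
        raise ValueError("no hot spells supplied")
    gd = group_deviations.sort_values("date")
    dates = pd.DatetimeIndex(gd["date"])
    dev = gd["deviation"].to_numpy(dtype=float)
    date_pos = pd.Series(np.arange(len(dates)), index=dates)
    onset_idx = np.array([date_pos.loc[s.onset] for s in spells])
    lags = np.array(list(config.lags))
    mean_dev, n_per_lag = _profile_from_onsets(dev, onset_idx, lags)
    return LagProfile(
        group=spells[0].group,
        lags=lags,
        mean_dev=mean_dev,
        n_per_lag=n_per_lag,
        n_spells=len(spells),
    )


def mc_lag_bounds(
    group_deviations: pd.DataFrame,
    n_spells: int,
    config: StudyConfig,
    seed: int | None = None,
    n_replicates: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lag Monte-Carlo bounds at 90 % and 95 % plus cumulative-sum nulls.

    Each replicate draws ``n_spells`` pseudo-onset dates uniformly from the
    summer days (without replacement), rebuilds the lag profile, and
    records both the per-lag means and the cumulative window sums.

    Returns ``(per_lag_bounds, cumulative_quantiles)``: the former has
    columns ``lag, lo95, lo90, hi90, hi95``; the latter rows
    ``sum_0_3, sum_4_14, total`` with the same quantile columns.
    """
    if n_spells <= 0:
        raise ValueError("n_spells must be positive")
    gd = group_deviations.sort_values("date")
    dates = pd.DatetimeIndex(gd["date"])
    dev = gd["deviation"].to_numpy(dtype=float)
    season_idx = np.flatnonzero(np.asarray(_season_mask(dates, config)))
    if n_spells > season_idx.size:
        raise ValueError("n_spells exceeds number of summer days")

    seed = config.rng_seed if seed is None else seed
    n_rep = config.mc_replicates if n_replicates is None else n_replicates
    rng = np.random.default_rng(seed)
    lags = np.array(list(config.lags))

    keys = rng.random((n_rep, season_idx.size))
    subset = np.argpartition(keys, n_spells - 1, axis=1)[:, :n_spells]
    onsets = season_idx[subset]  # (n_rep, n_spells)

    pos = onsets[:, :, None] + lags[None, None, :]
    valid = (pos >= 0) & (pos < dev.size)
    vals = np.where(valid, dev[np.clip(pos, 0, dev.size - 1)], np.nan)
    with warnings.catch_warnings():
        # a lag with no in-period day in any replicate yields NaN bounds
        warnings.simplefilter("ignore", RuntimeWarning)
        rep_profiles = np.nanmean(vals, axis=1)  # (n_rep, n_lags)

    qlevels = [0.025, 0.05, 0.95, 0.975]
    qnames = ["lo95", "lo90", "hi90", "hi95"]
    per_lag_q = np.quantile(rep_profiles, qlevels, axis=0)
    per_lag = pd.DataFrame({"lag": lags})
    for name, row in zip(qnames, per_lag_q):
        per_lag[name] = row

    def _wsum(lo, hi):
        sel = (lags >= lo) & (lags <= hi)
        return rep_profiles[:, sel].sum(axis=1)

    cum = {
        "sum_0_3": _wsum(*IMMEDIATE_WINDOW),
        "sum_4_14": _wsum(*LAGGED_WINDOW),
        "total": _wsum(IMMEDIATE_WINDOW[0], LAGGED_WINDOW[1]),
    }
    cum_rows = []
    for key, reps in cum.items():
        qs = np.quantile(reps, qlevels)
        cum_rows.append(dict(window=key, **dict(zip(qnames, qs))))
    return per_lag, pd.DataFrame(cum_rows)


def cumulative_excess(
    profile: LagProfile, cumulative_quantiles: pd.DataFrame | None = None,
    two_sided: bool = False,
) -> dict:
    """Window sums of the lag profile and their Monte-Carlo significance.

    Significance follows the one-sided convention (sum above the 95 %
    null quantile) unless ``two_sided`` is set.
    """
    sums = {
        "sum_0_3": profile.cumulative_immediate,
        "sum_4_14": profile.cumulative_lagged,
        "total": profile.cumulative_total,
    }
    flags = {}
    if cumulative_quantiles is not None:
        cq = cumulative_quantiles.set_index("window")
        for key, value in sums.items():
            if two_sided:
                flags[key] = bool(
                    value > cq.loc[key, "hi95"] or value < cq.loc[key, "lo95"]
                )
            else:
                flags[key] = bool(value > cq.loc[key, "hi90"])  # 95% quantile
    return {**sums, "significant": flags}
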