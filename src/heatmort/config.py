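"""Study configuration, district registry and design constants.

A :class:`StudyConfig` collects every fixed analysis constant — season
definition, hot-day quantile, spell length, lag window, Monte-Carlo
replicate count, spline budget and the grouping cut-offs — so that each
pipeline stage receives a single validated object.  Configs round-trip
through flat YAML files; unspecified keys fall back to the defaults below.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "StudyConfig",
    "DistrictRegistry",
    "ConfigError",
    "load_config",
    "write_config",
    "apply_merge",
]

log = logging.getLogger("heatmort")


class ConfigError(ValueError):
    """Raised for unparseable config files or invariant violations."""


@dataclass(frozen=True)
class StudyConfig:
    """Resolved analysis constants for one run.

    Defaults encode the study design: June–August season, strict 90th
    percentile hot days, hot spells of at least two consecutive days,
    deviations examined at lags -2..+14 around spell onset, 7 spline df
    per year, SES grouping cut at +/-0.5 SD and the 25 % / 37.5 %
    urban/rural thresholds.
    """

    start_date: dt.date = dt.date(1994, 1, 1)
    end_date: dt.date = dt.date(2009, 12, 31)
    season_months: frozenset[int] = frozenset({6, 7, 8})
    hot_day_quantile: float = 0.90
    min_spell_length: int = 2
    lag_window: tuple[int, int] = (-2, 14)
    mc_replicates: int = 10_000
    rng_seed: int = 0
    df_per_year: int = 7
    ses_cut: float = 0.50
    urban_cut: float = 25.0
    rural_cut: float = 37.5
    vif_cut: float = 7.5
    alpha_f: float = 0.05

    def __post_init__(self) -> None:
        if self.start_date >= self.end_date:
            raise ConfigError("start_date must precede end_date")
        if not (0.0 < self.hot_day_quantile < 1.0):
            raise ConfigError(
                f"hot_day_quantile must lie in (0, 1), got {self.hot_day_quantile}"
            )
        if self.min_spell_length < 2:
            raise ConfigError("min_spell_length must be >= 2")
        lo, hi = self.lag_window
        if not (lo <= 0 <= hi):
            raise ConfigError("lag_window must contain lag 0")
        if self.mc_replicates < 1:
            raise ConfigError("mc_replicates must be positive")
        if self.df_per_year < 1:
            raise ConfigError("df_per_year must be >= 1")
        if not self.season_months or not all(1 <= m <= 12 for m in self.season_months):
            raise ConfigError("season_months must be month numbers in 1..12")
        for name in ("ses_cut", "urban_cut", "rural_cut", "vif_cut", "alpha_f"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or value != value or value in (
                float("inf"),
                float("-inf"),
            ):
                raise ConfigError(f"{name} must be finite, got {value!r}")

    @property
    def n_years(self) -> int:
        """Whole calendar years covered by the study period."""
        return self.end_date.year - self.start_date.year + 1

    @property
    def total_df(self) -> int:
        return self.df_per_year * self.n_years

    @property
    def lags(self) -> range:
        lo, hi = self.lag_window
        return range(lo, hi + 1)

    def replace(self, **kwargs) -> "StudyConfig":
        return dataclasses.replace(self, **kwargs)

    def log_resolved(self) -> None:
        """Log every resolved parameter (reproducibility contract)."""
        for f in dataclasses.fields(self):
            log.info("config %s = %r", f.name, getattr(self, f.name))


_KEY_PARSERS = {
    "start_date": dt.date.fromisoformat,
    "end_date": dt.date.fromisoformat,
    "season_months": lambda v: frozenset(int(m) for m in v),
    "hot_day_quantile": float,
    "min_spell_length": int,
    "lag_window": lambda v: (int(v[0]), int(v[1])),
    "mc_replicates": int,
    "rng_seed": int,
    "df_per_year": int,
    "ses_cut": float,
    "urban_cut": float,
    "rural_cut": float,
    "vif_cut": float,
    "alpha_f": float,
}


def load_config(path: str | Path, **overrides) -> StudyConfig:
    """Read a flat YAML config; missing keys take defaults.

    ``overrides`` (e.g. from CLI flags) take precedence over file values.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - message path
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config {path} must be a mapping of key: value pairs")
    values: dict = {}
    for key, value in {**raw, **overrides}.items():
        if key not in _KEY_PARSERS:
            raise ConfigError(f"unknown config key {key!r}")
        try:
            if isinstance(value, dt.date) and key in ("start_date", "end_date"):
                values[key] = value
            else:
                values[key] = _KEY_PARSERS[key](value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad value for config key {key!r}: {value!r}") from exc
    return StudyConfig(**values)


def write_config(config: StudyConfig, path: str | Path) -> None:
    """Serialize a config to flat YAML such that ``load_config`` round-trips."""
    doc = {
        "start_date": config.start_date.isoformat(),
        "end_date": config.end_date.isoformat(),
        "season_months": sorted(config.season_months),
        "hot_day_quantile": config.hot_day_quantile,
        "min_spell_length": config.min_spell_length,
        "lag_window": list(config.lag_window),
        "mc_replicates": config.mc_replicates,
        "rng_seed": config.rng_seed,
        "df_per_year": config.df_per_year,
        "ses_cut": config.ses_cut,
        "urban_cut": config.urban_cut,
        "rural_cut": config.rural_cut,
        "vif_cut": config.vif_cut,
        "alpha_f": config.alpha_f,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


@dataclass(frozen=True)
class DistrictRegistry:
    """Raw administrative codes plus the merge map defining analysis units."""

    raw_units: tuple[str, ...]
    merge_map: Mapping[str, str] = field(default_factory=dict)

    def analysis_units(self) -> list[str]:
        return apply_merge(self.raw_units, self.merge_map)


def apply_merge(raw_units: Sequence[str], merge_map: Mapping[str, str]) -> list[str]:
    """Fold merged-away codes into their targets, preserving input order.

    Every merge source and target must appear in ``raw_units``; sources are
    dropped, targets are retained once, and the result has
    ``len(raw_units) - len(merge_map)`` units.  Applying the same map again
    is a no-op (idempotence).
    """
    units = list(raw_units)
    unit_set = set(units)
    for source, target in merge_map.items():
        if target not in unit_set:
            raise ValueError(f"merge target {target!r} not among raw units")
        if source not in unit_set and source not in merge_map:
            raise ValueError(f"merge source {source!r} not among raw units")
    sources = set(merge_map)
    return [u for u in units if u not in sources]
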