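"""Direct age standardization of daily death counts.

Rates are expressed per 100 000 of the standard population per day:
``rate = sum_a (deaths_a / pop_a) * w_a`` with the standard weights ``w_a``
summing to 100 000.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "StandardPopulation",
    "load_standard_population",
    "directly_standardized_rate",
    "standardize_series",
]

_WEIGHT_TOTAL = 100_000.0


class StandardPopulation:
    """Age-band weights of a standard population (sum = 100 000)."""

    def __init__(self, weights: dict[str, float]):
        if not weights:
            raise ValueError("standard population needs at least one band")
        if any(w <= 0 for w in weights.values()):
            raise ValueError("standard-population weights must be positive")
        total = float(sum(weights.values()))
        if abs(total - _WEIGHT_TOTAL) > 1e-6:
            raise ValueError(
                f"standard-population weights must sum to {_WEIGHT_TOTAL:g}, got {total:g}"
            )
        self.weights = dict(weights)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StandardPopulation":
        return cls(dict(zip(frame["age_band"], frame["weight"].astype(float))))

    @property
    def bands(self) -> list[str]:
        return list(self.weights)

    def __repr__(self) -> str:  # pragma: no cover
        return f"StandardPopulation({self.weights})"


def load_standard_population(path) -> StandardPopulation:
    return StandardPopulation.from_frame(pd.read_csv(path))


def directly_standardized_rate(
    deaths_by_band: dict[str, float],
    pop_by_band: dict[str, float],
    standard: StandardPopulation,
) -> float:
    """Directly standardized rate for one district-day."""
    missing = [
        b for b in standard.bands if b not in deaths_by_band or b not in pop_by_band
    ]
    if missing:
        raise ValueError(f"age band(s) missing from inputs: {missing}")
    rate = 0.0
    for band, w in standard.weights.items():
        d, p = deaths_by_band[band], pop_by_band[band]
        if d > 0 and p <= 0:
            raise ValueError(f"band {band!r} has deaths but zero population")
        rate += (d / p if p > 0 else 0.0) * w
    return rate


def standardize_series(
    mortality: pd.DataFrame, standard: StandardPopulation
) -> pd.DataFrame:
    """Standardize a full district-day-band panel in one vectorized pass.

    ``mortality`` columns: ``district_id, date, age_band, deaths,
    midyear_pop`` with a complete panel (every band for every
    district-day).  Mid-year populations are taken as given per row
    (callers provide the calendar-year value, constant within the year).

    Returns a DataFrame ``district_id, date, rate``.
    """
    bands = standard.bands
    present = set(mortality["age_band"].unique())
    missing = [b for b in bands if b not in present]
    if missing:
        raise ValueError(f"age band(s) missing from mortality table: {missing}")

    wide_d = mortality.pivot_table(
        index=["district_id", "date"], columns="age_band", values="deaths", aggfunc="sum"
    )
    wide_p = mortality.pivot_table(
        index=["district_id", "date"],
        columns="age_band",
        values="midyear_pop",
        aggfunc="first",
    )
    if wide_d[bands].isna().any().any() or wide_p[bands].isna().any().any():
        bad = wide_d[bands].isna().any(axis=1) | wide_p[bands].isna().any(axis=1)
        raise ValueError(
            f"incomplete panel: {int(bad.sum())} district-days lack some band"
        )
    d = wide_d[bands].to_numpy(dtype=float)
    p = wide_p[bands].to_numpy(dtype=float)
    if np.any((d > 0) & (p <= 0)):
        raise ValueError("some band has deaths with zero population")
    with np.errstate(invalid="ignore", divide="ignore"):
        band_rates = np.where(p > 0, d / np.where(p > 0, p, 1.0), 0.0)
    w = np.array([standard.weights[b] for b in bands])
    rates = band_rates @ w
    out = wide_d.index.to_frame(index=False)
    out["rate"] = rates
    return out.sort_values(["district_id", "date"], ignore_index=True)
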