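"""Location-stratified additive baseline model for expected daily mortality.

One model is fitted over the pooled district panel:

    rate ~ spline(time, total_df) + day_of_week + district

with a natural cubic regression spline on the day index (``df_per_year``
degrees of freedom per whole year, knots equally spaced, boundary knots at
the first and last day).  The default family is quasi-Poisson with log
link, which guarantees strictly positive baselines for the relative
deviation statistic; a Gaussian identity option is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import CubicSpline

from .config import StudyConfig

__all__ = [
    "BaselineSpec",
    "BaselineFit",
    "build_time_spline_basis",
    "fit_stratified_baseline",
    "predict_baseline",
]


@dataclass(frozen=True)
class BaselineSpec:
    df_per_year: int = 7
    n_years: int = 16
    family: str = "quasipoisson"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.df_per_year < 1:
            raise ValueError("df_per_year must be >= 1")
        if self.family not in ("quasipoisson", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def total_df(self) -> int:
        return self.df_per_year * self.n_years

    @classmethod
    def from_config(cls, config: StudyConfig, family: str = "quasipoisson"):
        return cls(df_per_year=config.df_per_year, n_years=config.n_years, family=family)


def build_time_spline_basis(dates: pd.DatetimeIndex, df_per_year: int) -> pd.DataFrame:
    """Natural cubic regression-spline basis over a contiguous daily axis.

    The basis has ``df_per_year * n_whole_years`` columns — the cardinal
    natural cubic splines on that many equally spaced knots spanning the
    period (boundary knots at the first and last day).  Its span contains
    every natural cubic spline on those knots, including constants, so the
    caller should not add a separate intercept.
    """
    if df_per_year < 1:
        raise ValueError("df_per_year must be >= 1")
    dates = pd.DatetimeIndex(dates)
    if len(dates) < 2 or not (np.diff(dates.to_numpy()) == np.timedelta64(1, "D")).all():
        raise ValueError("dates must be a contiguous daily sequence")
    n_years = dates[-1].year - dates[0].year + 1
    total_df = df_per_year * n_years
    if total_df < 2:
        raise ValueError("total df must be >= 2")
    x = np.arange(len(dates), dtype=float)
    knots = np.linspace(x[0], x[-1], total_df)
    cols = np.empty((len(x), total_df))
    eye = np.eye(total_df)
    for j in range(total_df):
        cols[:, j] = CubicSpline(knots, eye[j], bc_type="natural")(x)
    return pd.DataFrame(
        cols, index=dates, columns=[f"s{j}" for j in range(total_df)]
    )


@dataclass
class BaselineFit:
    """Fitted stratified baseline with per-district-day expected rates."""

    spec: BaselineSpec
    params: pd.Series
    dow_effects: pd.Series  # link-scale contrasts vs Monday
    district_effects: pd.Series  # link-scale contrasts vs reference district
    fitted: pd.DataFrame  # district_id, date, observed_rate, baseline_rate
    dispersion: float
    converged: bool

    def baseline_lookup(self) -> pd.Series:
        return self.fitted.set_index(["district_id", "date"])["baseline_rate"]


_DOW_NAMES = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]


def _design(rates: pd.DataFrame, spec: BaselineSpec):
    rates = rates.sort_values(["district_id", "date"], ignore_index=True)
    dates = pd.DatetimeIndex(sorted(rates["date"].unique()))
    per_district = rates.groupby("district_id")["date"].nunique()
    if per_district.nunique() > 1 or per_district.iloc[0] != len(dates):
        raise ValueError("all districts must share a complete date axis")

    basis = build_time_spline_basis(dates, spec.df_per_year)
    if basis.shape[1] != spec.total_df:
        raise ValueError(
            f"date axis spans {basis.shape[1] // spec.df_per_year} years, "
            f"spec expects {spec.n_years}"
        )
    districts = sorted(rates["district_id"].unique())
    n_d, n_t = len(districts), len(dates)
    # district-major, shared date axis: one basis block tiled per district
    bmat = np.tile(basis.to_numpy(), (n_d, 1))

    dow = dates.dayofweek.to_numpy()
    dow_block = np.zeros((n_t, 6))
    for k in range(1, 7):
        dow_block[:, k - 1] = dow == k
    dow_dummies = np.tile(dow_block, (n_d, 1))

    dist_dummies = np.zeros((len(rates), n_d - 1))
    for k in range(1, n_d):
        dist_dummies[k * n_t : (k + 1) * n_t, k - 1] = 1.0

    names = (
        list(basis.columns)
        + [f"dow_{n}" for n in _DOW_NAMES[1:]]
        + [f"district_{d}" for d in districts[1:]]
    )
    X = np.column_stack([bmat, dow_dummies, dist_dummies])
    return rates, X, names, districts


def _irls_poisson(
    y: np.ndarray, X: np.ndarray, maxiter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Quasi-Poisson (log link) fit by iteratively reweighted least squares."""
    mu = np.maximum((y + y.mean()) / 2.0, 1e-8)
    eta = np.log(mu)
    trace: list[float] = []
    beta = None
    for _ in range(maxiter):
        w = mu
        z = eta + (y - mu) / mu
        xtw = X.T * w
        beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        eta = X @ beta_new
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        deviance = 2.0 * float(dev_terms.sum())
        trace.append(deviance)
        if beta is not None and len(trace) > 1:
            if abs(trace[-2] - deviance) <= tol * (abs(deviance) + 0.1):
                beta = beta_new
                return beta, mu, trace
        beta = beta_new
    raise RuntimeError(
        f"baseline GLM failed to converge in {maxiter} iterations; "
        f"deviance trace tail: {trace[-5:]!r}"
    )


def fit_stratified_baseline(
    rates: pd.DataFrame, spec: BaselineSpec
) -> BaselineFit:
    """Fit the pooled panel model and store per-district-day baselines.

    ``rates`` columns: ``district_id, date, rate``; the panel must be
    complete (every district for every date).
    """
    rates, X, names, districts = _design(rates, spec)
    y = rates["rate"].to_numpy(dtype=float)

    if spec.family == "quasipoisson":
        beta, baseline, _ = _irls_poisson(y, X)
        resid_df = max(len(y) - X.shape[1], 1)
        dispersion = float(np.sum((y - baseline) ** 2 / baseline) / resid_df)
    else:
        res = sm.OLS(y, X).fit()
        beta = np.asarray(res.params)
        baseline = np.asarray(res.fittedvalues)
        dispersion = float(res.scale)
        if np.any(baseline <= 0):
            raise ValueError(
                "Gaussian baseline produced non-positive expected rates; "
                "use the quasipoisson (log link) family"
            )

    params = pd.Series(beta, index=names)
    fitted = rates[["district_id", "date"]].copy()
    fitted["observed_rate"] = y
    fitted["baseline_rate"] = baseline
    return BaselineFit(
        spec=spec,
        params=params,
        dow_effects=params[[f"dow_{n}" for n in _DOW_NAMES[1:]]],
        district_effects=params[[f"district_{d}" for d in districts[1:]]],
        fitted=fitted,
        dispersion=dispersion,
        converged=True,
    )


def predict_baseline(fit: BaselineFit, district: str, date) -> float:
    """Stored fitted value for a district-day; no extrapolation."""
    key = (district, pd.Timestamp(date))
    lookup = fit.baseline_lookup()
    if key not in lookup.index:
        raise KeyError(f"district-day {key} outside the fitted domain")
    return float(lookup.loc[key])
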