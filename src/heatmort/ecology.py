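"""Ecological regression of district excess mortality on covariates.

Builds the socioeconomic-status index and the OECD rurality criterion,
screens collinearity with variance inflation factors, selects a model by
bidirectional stepwise AIC subject to per-term F-significance, tests
residual spatial autocorrelation with Global Moran's I (permutation null)
and runs SES-stratified simple regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "RegressionReport",
    "ses_index",
    "oecd_criterion",
    "spearman_matrix",
    "vif_screen",
    "stepwise_aic",
    "morans_i",
    "stratified_regressions",
]


def ses_index(shares: pd.DataFrame, degenerate: str = "error") -> pd.Series:
    """Socioeconomic-status index per district.

    The negated sum of z-scores of the three deprivation shares
    (``pct_unemployed``, ``pct_low_education``, ``pct_singles``), so higher
    values mean less deprivation.  ``degenerate`` controls what a
    zero-variance share does: ``"error"`` raises, ``"zero"`` contributes a
    zero z-score (useful for deliberately identical synthetic districts).
    """
    cols = ["pct_unemployed", "pct_low_education", "pct_singles"]
    z_total = np.zeros(len(shares))
    for col in cols:
        x = shares[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            if degenerate == "zero":
                continue
            raise ValueError(f"share {col!r} has zero variance across districts")
        z_total += (x - x.mean()) / sd
    return pd.Series(-z_total, index=shares["district_id"].to_numpy(), name="ses")


def oecd_criterion(municipalities: pd.DataFrame, density_cut: float = 150.0) -> pd.Series:
    """Percent of district inhabitants in municipalities below the density cut.

    A municipality with density exactly at the cut is NOT low-density
    (strict ``<``).
    """
    m = municipalities.copy()
    totals = m.groupby("district_id")["municipality_pop"].sum()
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"zero population for district(s): {bad}")
    low = m[m["density"] < density_cut].groupby("district_id")["municipality_pop"].sum()
    share = 100.0 * low.reindex(totals.index, fill_value=0.0) / totals
    return share.rename("oecd")


def spearman_matrix(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations with t-approximation p-values.

    Mid-ranks for ties.  Constant columns yield NaN correlations and
    p-values (undefined, reported as such).

    Returns ``(rho, pvalues)`` as symmetric DataFrames with unit diagonal.
    """
    cols = columns or [c for c in table.columns if table[c].dtype.kind in "fi"]
    n = len(table)
    if n < 4:
        raise ValueError("need at least 4 districts for rank correlations")
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                res = stats.spearmanr(table[a], table[b])
            r, p = float(res.statistic), float(res.pvalue)
            if table[a].nunique() == 1 or table[b].nunique() == 1:
                r, p = np.nan, np.nan
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    Xc = sm.add_constant(X, has_constant="add")
    return float(sm.OLS(y, Xc).fit().rsquared)


def _vifs(design: pd.DataFrame) -> pd.Series:
    out = {}
    X = design.to_numpy(dtype=float)
    for j, col in enumerate(design.columns):
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            out[col] = 1.0
            continue
        r2 = _ols_r2(X[:, j], others)
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_screen(
    design: pd.DataFrame, response: pd.Series, vif_cut: float = 7.5
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop collinear covariates until all VIFs are below cut.

    Among variables whose VIF exceeds the cut, the one whose single-variable
    OLS against the response explains the least variance is removed;
    VIFs are then recomputed.  Perfect collinearity counts as infinite VIF.

    Returns ``(retained_columns, trail)`` where ``trail`` records each
    dropped variable with its VIF and response R-squared.
    """
    kept = list(design.columns)
    y = response.to_numpy(dtype=float)
    trail = []
    while len(kept) > 1:
        vifs = _vifs(design[kept])
        offenders = vifs[vifs > vif_cut]
        if offenders.empty:
            break
        r2 = {
            col: _ols_r2(y, design[[col]].to_numpy(dtype=float))
            for col in offenders.index
        }
        drop = min(r2, key=lambda c: (r2[c], c))
        trail.append(dict(dropped=drop, vif=float(vifs[drop]), response_r2=r2[drop]))
        kept.remove(drop)
    return kept, pd.DataFrame(trail, columns=["dropped", "vif", "response_r2"])


@dataclass
class RegressionReport:
    selected: list[str]
    coefficients: pd.Series
    pvalues: pd.Series
    r_squared: float
    aic: float
    aic_trail: list[tuple[str, float]] = field(default_factory=list)
    moran_i: float | None = None
    moran_p: float | None = None
    warning: str | None = None


def _fit_ols(y: np.ndarray, design: pd.DataFrame, terms: tuple[str, ...]):
    X = sm.add_constant(
        design[list(terms)].to_numpy(dtype=float) if terms else np.empty((len(y), 0)),
        has_constant="add",
    )
    return sm.OLS(y, X).fit()


def _terms_significant(res, n_terms: int, alpha: float) -> bool:
    # partial F for a single column equals the squared t-test
    return bool((res.pvalues[1 : 1 + n_terms] < alpha).all()) if n_terms else True


def stepwise_aic(
    design: pd.DataFrame, response: pd.Series, alpha_f: float = 0.05
) -> RegressionReport:
    """Bidirectional stepwise selection by AIC with an F-significance screen.

    Starts from the intercept-only model; at each step takes the single
    add or drop that most lowers the AIC (ties favour the smaller model);
    stops when no move improves it.  Among all models visited, the one with
    the lowest AIC in which every term's partial F-test has ``p < alpha_f``
    is returned; if none qualifies the intercept-only model is reported
    with a warning.
    """
    y = response.to_numpy(dtype=float)
    candidates = list(design.columns)
    if len(y) <= len(candidates) + 2:
        raise ValueError("need n > p + 2 observations for stepwise selection")

    def key(terms):
        return tuple(sorted(terms))

    fits: dict[tuple[str, ...], object] = {}

    def fit(terms):
        k = key(terms)
        if k not in fits:
            fits[k] = _fit_ols(y, design, k)
        return fits[k]

    current: tuple[str, ...] = ()
    current_aic = fit(current).aic
    trail = [("start", float(current_aic))]
    while True:
        moves = []
        for c in candidates:
            if c in current:
                moves.append((key(tuple(t for t in current if t != c)), f"-{c}"))
            else:
                moves.append((key(current + (c,)), f"+{c}"))
        # smaller model wins AIC ties
        scored = sorted(
            ((fit(t).aic, len(t), t, label) for t, label in moves),
            key=lambda x: (round(x[0], 10), x[1]),
        )
        best_aic, _, best_terms, best_label = scored[0]
        if best_aic < current_aic - 1e-10:
            current, current_aic = best_terms, best_aic
            trail.append((best_label, float(best_aic)))
        else:
            break

    # lowest-AIC visited model whose every term passes the F screen
    qualifying = [
        (res.aic, terms)
        for terms, res in fits.items()
        if _terms_significant(res, len(terms), alpha_f)
    ]
    warning = None
    if qualifying:
        _, best_terms = min(qualifying, key=lambda x: (x[0], len(x[1])))
    else:  # pragma: no cover - requires pathological design
        best_terms, warning = (), "no visited model passes the significance screen"
    res = fit(best_terms)
    names = ["const"] + list(best_terms)
    return RegressionReport(
        selected=list(best_terms),
        coefficients=pd.Series(np.asarray(res.params), index=names),
        pvalues=pd.Series(np.asarray(res.pvalues), index=names),
        r_squared=float(res.rsquared) if best_terms else 0.0,
        aic=float(res.aic),
        aic_trail=trail,
        warning=warning,
    )


def _row_standardize(w: np.ndarray) -> np.ndarray:
    sums = w.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("weight matrix has a row with no positive entries")
    return w / sums


def morans_i(
    values: np.ndarray,
    weights: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Global Moran's I with a two-sided permutation p-value.

    The weight matrix (non-negative, zero diagonal) is row-standardized
    before use.  ``I = (n/S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) /
    sum_i (x_i - xbar)^2``; the p-value compares |I - E[I]| against
    permutations of the values over locations, E[I] = -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if w.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    if np.any(np.diag(w) != 0) or np.any(w < 0):
        raise ValueError("weights must be non-negative with zero diagonal")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant values")
    w = _row_standardize(w)
    s0 = w.sum()

    def _i(vec: np.ndarray) -> float:
        z = vec - vec.mean()
        return float(n / s0 * z @ w @ z / (z @ z))

    observed = _i(x)
    if n_permutations < 1:
        return observed, float("nan")
    rng = np.random.default_rng(seed)
    expect = -1.0 / (n - 1)
    count = 0
    for _ in range(n_permutations):
        perm = _i(rng.permutation(x))
        if abs(perm - expect) >= abs(observed - expect) - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return observed, float(p)


def adjacency_to_weights(adjacency: pd.DataFrame, districts: list[str]) -> np.ndarray:
    """Binary contiguity matrix from an edge list (symmetrized)."""
    idx = {d: i for i, d in enumerate(districts)}
    w = np.zeros((len(districts), len(districts)))
    for row in adjacency.itertuples(index=False):
        a, b = idx[row.district_id_a], idx[row.district_id_b]
        w[a, b] = w[b, a] = 1.0
    return w


def stratified_regressions(
    covariates: pd.DataFrame, ses_cut: float = 0.50, min_stratum: int = 5
) -> pd.DataFrame:
    """Simple regressions of DevCVD within low/intermediate/high SES strata.

    For each stratum, DevCVD is regressed on SES, on summer temperature and
    on the OECD criterion, and SES on OECD; slopes and p-values are
    reported.  Strata smaller than ``min_stratum`` are skipped.
    """
    ses = covariates["ses"].to_numpy(dtype=float)
    sd = ses.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate SES index")
    z = (ses - ses.mean()) / sd
    strata = np.where(z < -ses_cut, "low", np.where(z > ses_cut, "high", "intermediate"))

    pairs = [
        ("dev_cvd", "ses"),
        ("dev_cvd", "summer_t"),
        ("dev_cvd", "oecd"),
        ("ses", "oecd"),
    ]
    rows = []
    for stratum in ("low", "intermediate", "high"):
        sub = covariates[strata == stratum]
        if len(sub) < min_stratum:
            rows.append(
                dict(stratum=stratum, n=len(sub), response=None, predictor=None,
                     slope=np.nan, pvalue=np.nan, skipped=True)
            )
            continue
        for resp, pred in pairs:
            if sub[pred].nunique() == 1:  # degenerate predictor within stratum
                rows.append(
                    dict(stratum=stratum, n=len(sub), response=resp, predictor=pred,
                         slope=np.nan, pvalue=np.nan, skipped=False)
                )
                continue
            res = stats.linregress(sub[pred], sub[resp])
            rows.append(
                dict(stratum=stratum, n=len(sub), response=resp, predictor=pred,
                     slope=float(res.slope), pvalue=float(res.pvalue), skipped=False)
            )
    return pd.DataFrame(rows)
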