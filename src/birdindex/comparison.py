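"""Index-correspondence statistics across resolutions and scales.

State-level series are compared with Pearson correlation, falling back to
Spearman rank correlation when either vector fails a Shapiro-Wilk normality
check (p < 0.05); town-level series use a weighted Pearson correlation with
weights built from the two series' inverse SEs.  Multi-year trends come from
a Gaussian GLM of the standardized index on centered year plus its square,
and two indices' trends are called consistent when the 95% CIs of their
linear coefficients overlap.  Town-level correspondence is regressed on town
attributes (survey density, habitat-class proportions) with a species random
intercept.  A LOESS smoother (span may exceed 1) supports the trend figures
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from birdindex.indices import ChangeSeries, IndexSeries

__all__ = [
    "CorrelationResult",
    "TrendFit",
    "SpatialRegressionResult",
    "correlate_state",
    "weighted_pearson",
    "fit_trend",
    "trends_consistent",
    "spatial_regression",
    "loess_overlay",
]

Z95 = 1.959963984540054


@dataclass
class CorrelationResult:
    species_id: str
    pair: tuple
    resolution: str         # "annual" | "interannual"
    scale: str
    method: str             # "pearson" | "spearman" | "weighted-pearson"
    r: float | None
    p: float | None
    n: int


@dataclass
class TrendFit:
    species_id: str
    index_id: str
    linear: float
    linear_ci: tuple
    quadratic: float
    quadratic_ci: tuple
    standardized: bool = True
    centered_year: bool = True

    @property
    def directional(self) -> bool:
        """CI of the linear coefficient excludes zero."""
        lo, hi = self.linear_ci
        return lo > 0 or hi < 0


@dataclass
class SpatialRegressionResult:
    estimates: pd.DataFrame   # term, estimate, ci_low, ci_high
    n_obs: int
    n_groups: int


def _values(x):
    if isinstance(x, IndexSeries):
        return x.estimates
    if isinstance(x, ChangeSeries):
        return x.changes
    return np.asarray(x, dtype=float)


def correlate_state(a, b, species_id: str = "", pair=(), resolution: str = "annual",
                    scale: str = "state") -> CorrelationResult:
    """Pearson correlation with a Shapiro-Wilk normality gate.

    Both vectors are tested; if either is non-normal at p < 0.05 the method
    falls back to Spearman rank correlation.  Zero-variance input yields a
    missing r.
    """
    xa, xb = _values(a), _values(b)
    mask = np.isfinite(xa) & np.isfinite(xb)
    xa, xb = xa[mask], xb[mask]
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 aligned points")
    if np.std(xa) == 0 or np.std(xb) == 0:
        return CorrelationResult(species_id, tuple(pair), resolution, scale,
                                 "pearson", None, None, n)
    normal = all(stats.shapiro(v).pvalue >= 0.05 for v in (xa, xb))
    if normal:
        r, p = stats.pearsonr(xa, xb)
        method = "pearson"
    else:
        r, p = stats.spearmanr(xa, xb)
        method = "spearman"
    return CorrelationResult(species_id, tuple(pair), resolution, scale, method,
                             float(r), float(p), n)


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation with weighted means and central moments.

    r = s_xy / sqrt(s_xx s_yy), m = sum(w v)/sum(w),
    s_uv = sum(w (u-m_u)(v-m_v))/sum(w).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)) or len(x) < 3:
        raise ValueError("x, y, w must have equal length >= 3")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = w.sum()
    mx, my = np.sum(w * x) / sw, np.sum(w * y) / sw
    sxy = np.sum(w * (x - mx) * (y - my)) / sw
    sxx = np.sum(w * (x - mx) ** 2) / sw
    syy = np.sum(w * (y - my) ** 2) / sw
    if sxx == 0 or syy == 0:
        return np.nan
    return float(sxy / np.sqrt(sxx * syy))


def correlate_town(a: IndexSeries, b: IndexSeries, resolution: str = "annual") -> CorrelationResult:
    """Town-level weighted Pearson; pairwise weight = 1/(SE_a * SE_b)."""
    if not np.array_equal(a.years, b.years):
        raise ValueError("series must be aligned on the same years")
    if resolution == "annual":
        x, y = a.estimates, b.estimates
        w = 1.0 / (a.ses * b.ses)
    else:
        ca, cb = a.estimates, b.estimates
        x = np.diff(ca) / ca[:-1]
        y = np.diff(cb) / cb[:-1]
        w = 1.0 / (a.ses[1:] * b.ses[1:])
        mask = np.isfinite(x) & np.isfinite(y)
        x, y, w = x[mask], y[mask], w[mask]
    r = weighted_pearson(x, y, w)
    return CorrelationResult(a.species_id, (a.index_id, b.index_id), resolution,
                             a.scale, "weighted-pearson", r, None, len(x))


def fit_trend(series: IndexSeries) -> TrendFit:
    """Multi-year trend: Gaussian GLM of the standardized index on centered
    year plus a quadratic term; Wald 95% CIs.

    The response is z-scored across years (a constant series has undefined
    z-scores and is reported as a zero trend with a warning).
    """
    import statsmodels.api as sm

    if len(series) < 4:
        raise ValueError("need at least 4 years for a trend fit")
    y = series.estimates
    sd = y.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(float(y.mean()))):
        warnings.warn("constant series; reporting zero trend")
        return TrendFit(series.species_id, series.index_id, 0.0, (0.0, 0.0), 0.0, (0.0, 0.0))
    z = (y - y.mean()) / sd
    t = series.years - series.years.mean()
    X = np.column_stack([np.ones_like(t, dtype=float), t, t**2])
    res = sm.OLS(z, X).fit()
    b, se = res.params, res.bse
    return TrendFit(
        series.species_id, series.index_id,
        float(b[1]), (float(b[1] - Z95 * se[1]), float(b[1] + Z95 * se[1])),
        float(b[2]), (float(b[2] - Z95 * se[2]), float(b[2] + Z95 * se[2])),
    )


def trends_consistent(a: TrendFit, b: TrendFit) -> dict:
    """Two indices agree on the multi-year trend when their linear-coefficient
    95% CIs overlap; each index is 'directional' when its CI excludes zero."""
    (alo, ahi), (blo, bhi) = a.linear_ci, b.linear_ci
    return {
        "consistent": bool(alo <= bhi and blo <= ahi),
        "directional": {a.index_id: a.directional, b.index_id: b.directional},
    }


def spatial_regression(town_correlations: pd.DataFrame, attributes: pd.DataFrame,
                       covariates=None) -> SpatialRegressionResult:
    """Regress per-(species, town) correspondence on town attributes.

    Gaussian linear mixed model with a species random intercept; fixed
    effects are survey density and the habitat-class area proportions, all
    scaled and centered.  With a single species a plain linear model is used
    with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    covariates = list(covariates) if covariates is not None else (
        ["survey_density"] + [c for c in ("deciduous", "shrub", "herbaceous", "developed", "wetland")
                              if c in attributes.columns]
    )
    d = town_correlations.merge(attributes, on="town", how="left").dropna(subset=["r"])
    n_towns = d["town"].nunique()
    if len(covariates) >= n_towns:
        raise ValueError(
            f"{len(covariates)} town-level covariates cannot be identified from "
            f"{n_towns} towns; pass a smaller `covariates` list"
        )
    for c in covariates:
        v = d[c].to_numpy(dtype=float)
        d[c] = (v - v.mean()) / (v.std(ddof=1) if v.std(ddof=1) > 0 else 1.0)
    formula = "r ~ " + " + ".join(covariates)
    n_groups = d["species_id"].nunique()
    degenerate = d["r"].std(ddof=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n_groups >= 2 and not degenerate:
            model = smf.mixedlm(formula, d, groups=d["species_id"])
            res = model.fit(reml=True)
            params = res.fe_params
            bse = res.bse_fe
        else:
            warnings.warn("degenerate grouping or response; using a plain linear model")
            res = smf.ols(formula, d).fit()
            params = res.params
            bse = res.bse
    terms = ["Intercept"] + covariates
    rows = [
        {
            "term": t,
            "estimate": float(params[t]),
            "ci_low": float(params[t] - Z95 * bse[t]),
            "ci_high": float(params[t] + Z95 * bse[t]),
        }
        for t in terms
    ]
    return SpatialRegressionResult(pd.DataFrame(rows), n_obs=len(d), n_groups=n_groups)


def loess_overlay(series: IndexSeries, span: float = 2.0) -> np.ndarray:
    """LOESS (local linear, tricube weights) smoothed values for plotting.

    Spans greater than 1 use all points with the tricube bandwidth inflated
    by span^(1/1) times the maximum distance, matching the usual local
    regression convention for span > 1.  Plot-support only; never feeds
    numeric results.
    """
    x = series.years.astype(float)
    y = series.estimates
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points")
    out = np.empty(n)
    for i, x0 in enumerate(x):
        d = np.abs(x - x0)
        if span >= 1.0:
            h = d.max() * span
        else:
            k = max(2, int(np.ceil(span * n)))
            h = np.sort(d)[k - 1]
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3 if h > 0 else np.ones(n)
        sw = w.sum()
        xm = np.sum(w * x) / sw
        ym = np.sum(w * y) / sw
        sxx = np.sum(w * (x - xm) ** 2)
        b = np.sum(w * (x - xm) * (y - ym)) / sxx if sxx > 0 else 0.0
        out[i] = ym + b * (x0 - xm)
    return out
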