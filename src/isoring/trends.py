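"""Per-site ordinary least-squares trends against calendar year.

Each site × species × variable series gets a closed-form OLS slope, its
standard error from the residual variance, and a two-sided t-test p-value.
Autocorrelation is deliberately not corrected here; temporal dependence is
handled by the mixed models, these exploratory trends mirror simple
regression lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError

__all__ = ["TrendResult", "ols_trend", "trend_table", "significance_stars"]

log = logging.getLogger(__name__)

#: variables fitted only over the deposition monitoring window
DEPOSITION_VARS = ("nh4_n", "no3_n", "n_dep", "s_dep", "an_dep", "as_dep")
DEPOSITION_WINDOW = (1995, 2010)


def significance_stars(p: float) -> str:
    """Star code used in the trend and model tables."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.10:
        return "¥"
    return ""


@dataclass
class TrendResult:
    """Slope, standard error and p-value of one linear trend."""

    slope: float
    slope_se: float
    p_value: float
    n: int
    intercept: float
    perfect_fit: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    @property
    def p_label(self) -> str:
        return "<1e-12" if self.perfect_fit else f"{self.p_value:.4g}"


def ols_trend(years, values) -> TrendResult:
    """Closed-form OLS regression of ``values`` on ``years``.

    Requires at least 3 finite pairs and non-constant years. A numerically
    perfect fit is flagged and reported with SE 0 and p as a "<1e-12"
    bound rather than dividing by zero.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(years) & np.isfinite(values)
    x, y = years[keep], values[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 paired observations, got {n}")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValidationError("years are all equal; trend undefined")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    # perfect-fit threshold relative to the data scale
    scale = max(float(np.sum((y - ym) ** 2)), float(np.sum(y**2)), 1e-300)
    if sse / scale < 1e-24 or sse == 0.0:
        # an exactly flat series carries no evidence of trend (p = 1);
        # an exact non-zero slope is reported as a "<1e-12" bound
        flat = abs(slope) * np.sqrt(sxx) < 1e-12 * np.sqrt(scale)
        return TrendResult(slope, 0.0, 1.0 if flat else 0.0, n, intercept,
                           perfect_fit=not flat)
    se = float(np.sqrt(sse / (n - 2) / sxx))
    t = slope / se
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return TrendResult(slope, se, p, n, intercept)


def trend_table(
    data: pd.DataFrame,
    variables,
    by=("site_id", "species"),
    year_col: str = "year",
    windows: dict | None = None,
) -> pd.DataFrame:
    """One OLS trend per site × species × variable.

    ``windows`` maps variable names to (first, last) year restrictions;
    deposition fluxes default to the 1995-2010 monitoring window while the
    isotope-derived series use the full chronology. Series that are
    entirely missing (or too short) are omitted with a log entry.
    """
    windows = dict(windows or {})
    for v in DEPOSITION_VARS:
        windows.setdefault(v, DEPOSITION_WINDOW)
    by = list(by)
    rows = []
    for key, grp in data.groupby(by, sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        for var in variables:
            if var not in grp.columns:
                log.info("trend_table: %s missing for %s; row omitted", var, key)
                continue
            sub = grp
            if var in windows:
                y0, y1 = windows[var]
                sub = grp[(grp[year_col] >= y0) & (grp[year_col] <= y1)]
            series = sub[[year_col, var]].dropna()
            # pooled deposition/climate series repeat per record; collapse
            series = series.groupby(year_col, as_index=False)[var].first()
            try:
                res = ols_trend(series[year_col], series[var])
            except (InsufficientDataError, ValidationError):
                log.info("trend_table: %s for %s has too little data; row omitted", var, key)
                continue
            rows.append(
                dict(zip(by, key))
                | {
                    "variable": var,
                    "slope": res.slope,
                    "slope_se": res.slope_se,
                    "p_value": res.p_value,
                    "n": res.n,
                    "stars": res.stars,
                }
            )
    return pd.DataFrame(rows)
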