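"""Climate aggregation, deposition covariates, centering and the two PCAs.

Monthly station data are reduced to annual and growing-season (May to
September) aggregates; vapour pressure deficit is built from monthly
maximum temperature and minimum relative humidity with the Tetens
saturation-pressure curve. Two principal component analyses summarise the
climate space: a *spatial* PCA on globally-centered long-term site means
and an *annual* PCA on group-centered (within-site) yearly values, both on
scaled variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .exceptions import DomainError, ValidationError

__all__ = [
    "GROWING_SEASON",
    "vpd_from_t_rh",
    "aggregate_climate",
    "center_variables",
    "ClimatePCA",
    "PcaResult",
    "fit_pca",
    "deposition_covariates",
    "SPATIAL_PCA_VARS",
    "ANNUAL_PCA_VARS",
]

#: growing season months, May-September inclusive
GROWING_SEASON = (5, 6, 7, 8, 9)

#: long-term site means entering the spatial PCA
SPATIAL_PCA_VARS = ["t_a", "t_amax", "p_a", "vpd_a", "t_grs", "t_maxgrs", "p_grs", "vpd_grs"]

#: within-site annual values entering the annual PCA
ANNUAL_PCA_VARS = SPATIAL_PCA_VARS + ["spei8_1", "spei8_2", "spei8_3", "spei12_1", "spei12_12"]


def vpd_from_t_rh(t_max, rh_min):
    """Vapour pressure deficit (kPa) via Tetens over liquid water.

    VPD = e_s(T_max) · (1 − RH_min/100) with
    e_s(T) = 0.6108 · exp(17.27 T / (T + 237.3)).
    """
    t_max = np.asarray(t_max, dtype=float)
    rh_min = np.asarray(rh_min, dtype=float)
    if np.any((rh_min < 0) | (rh_min > 100)):
        raise DomainError("rh_min must lie in [0, 100]")
    es = 0.6108 * np.exp(17.27 * t_max / (t_max + 237.3))
    out = es * (1.0 - rh_min / 100.0)
    return out if out.ndim else float(out)


def aggregate_climate(monthly: pd.DataFrame) -> pd.DataFrame:
    """Annual and growing-season aggregates per site-year.

    Annual temperature fields are means of the 12 monthly values,
    precipitation the sum; growing-season fields average (or sum) May to
    September. P_grs is reported in cm (sum of May-Sep mm / 10) to match
    the trend-table convention; all other precipitation fields stay in mm.
    A year missing any month gets NaN annual fields; missing any
    growing-season month gets NaN growing-season fields.
    """
    df = monthly.copy()
    df["vpd"] = vpd_from_t_rh(df["t_max"], df["rh_min"])
    rows = []
    for (site, year), grp in df.groupby(["site_id", "year"], sort=True):
        months = set(grp["month"])
        row = {"site_id": site, "year": int(year)}
        if months >= set(range(1, 13)):
            row.update(
                t_a=grp["t_mean"].mean(),
                t_amax=grp["t_max"].mean(),
                p_a=grp["precip"].sum(),
                vpd_a=grp["vpd"].mean(),
            )
        else:
            row.update(t_a=np.nan, t_amax=np.nan, p_a=np.nan, vpd_a=np.nan)
        grs = grp[grp["month"].isin(GROWING_SEASON)]
        if months >= set(GROWING_SEASON):
            row.update(
                t_grs=grs["t_mean"].mean(),
                t_maxgrs=grs["t_max"].mean(),
                p_grs=grs["precip"].sum() / 10.0,
                vpd_grs=grs["vpd"].mean(),
            )
        else:
            row.update(t_grs=np.nan, t_maxgrs=np.nan, p_grs=np.nan, vpd_grs=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def center_variables(
    table: pd.DataFrame,
    mode: str = "global",
    group_key: str | None = None,
    scale: bool = False,
) -> pd.DataFrame:
    """Center (and optionally scale) the numeric columns of a table.

    ``global`` subtracts each variable's grand mean; ``group`` subtracts
    each group's own mean (requires ``group_key``). Scaling divides by the
    grand standard deviation computed after centering, as PCA inputs
    require. Columns constant after centering are dropped with a warning.
    """
    if mode not in ("global", "group"):
        raise ValidationError(f"unknown centering mode {mode!r}")
    if mode == "group" and group_key is None:
        raise ValidationError("group centering requires group_key")
    num = table.select_dtypes(include=[np.number]).columns
    num = [c for c in num if c != group_key]
    out = table.copy()
    if mode == "global":
        out[num] = out[num] - out[num].mean()
    else:
        out[num] = out[num] - out.groupby(group_key)[num].transform("mean")
    dropped = []
    for c in num:
        sd = out[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            dropped.append(c)
        elif scale:
            out[c] = out[c] / sd
    if dropped:
        warnings.warn(f"dropping constant column(s) after centering: {dropped}", stacklevel=2)
        out = out.drop(columns=dropped)
    return out


@dataclass
class PcaResult:
    """Loadings, scores and retention summary of one PCA."""

    kind: str
    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_fraction: np.ndarray
    n_retained: int
    variables: list = field(default_factory=list)


class ClimatePCA(BaseEstimator):
    """PCA on centered and scaled climate variables, sklearn-style.

    Parameters
    ----------
    kind : {"spatial", "annual"}
        Spatial mode centers globally; annual mode group-centers within
        ``group_key`` before scaling, so every site contributes anomalies.
    cumvar : float, optional
        Retain the smallest number of components whose cumulative explained
        variance reaches this fraction (default 0.90 spatial, 0.78 annual).
    group_key : str
        Grouping column for annual mode (default ``site_id``).

    Fitted attributes end in an underscore: ``loadings_`` (variable ×
    component), ``scores_``, ``explained_variance_fraction_``,
    ``n_retained_``. Component signs are fixed so each component's
    largest-magnitude loading is positive.
    """

    def __init__(self, kind: str = "spatial", cumvar: float | None = None,
                 group_key: str = "site_id"):
        self.kind = kind
        self.cumvar = cumvar
        self.group_key = group_key

    def _prepare(self, X: pd.DataFrame, fitting: bool) -> np.ndarray:
        num = [c for c in X.select_dtypes(include=[np.number]).columns
               if c != self.group_key]
        if fitting:
            self.variables_ = list(num)
            if self.kind == "annual":
                self.group_means_ = X.groupby(self.group_key)[num].mean()
                centered = X[num].to_numpy() - self.group_means_.loc[
                    X[self.group_key]
                ].to_numpy()
            else:
                self.mean_ = X[num].mean()
                centered = (X[num] - self.mean_).to_numpy()
            self.scale_ = np.asarray(np.std(centered, axis=0, ddof=1), dtype=float)
            if np.any(self.scale_ == 0):
                bad = [v for v, s in zip(num, self.scale_) if s == 0]
                raise ValidationError(f"constant variable(s) after centering: {bad}")
        else:
            if self.kind == "annual":
                centered = X[self.variables_].to_numpy() - self.group_means_.loc[
                    X[self.group_key]
                ].to_numpy()
            else:
                centered = (X[self.variables_] - self.mean_).to_numpy()
        return centered / self.scale_

    def fit(self, X: pd.DataFrame, y=None):
        if self.kind not in ("spatial", "annual"):
            raise ValidationError(f"unknown PCA kind {self.kind!r}")
        Z = self._prepare(X, fitting=True)
        n, p = Z.shape
        if n < 2 or p < 2:
            raise ValidationError("PCA needs at least 2 observations and 2 variables")
        k = min(n - 1, p)
        if p > n - 1:
            warnings.warn(
                f"more variables ({p}) than independent observations; "
                f"proceeding with {k} components",
                stacklevel=2,
            )
        pca = PCA(n_components=k)
        scores = pca.fit_transform(Z)
        load = pca.components_.T  # variable x component
        # sign convention: largest-magnitude loading positive per component
        for j in range(k):
            i = int(np.argmax(np.abs(load[:, j])))
            if load[i, j] < 0:
                load[:, j] *= -1
                scores[:, j] *= -1
        self._pca = pca
        frac = pca.explained_variance_ratio_
        threshold = self.cumvar if self.cumvar is not None else (
            0.90 if self.kind == "spatial" else 0.78
        )
        self.n_retained_ = int(np.searchsorted(np.cumsum(frac), threshold) + 1)
        self.n_retained_ = min(self.n_retained_, k)
        names = [f"pc{'s' if self.kind == 'spatial' else 'a'}{j + 1}" for j in range(k)]
        self.loadings_ = pd.DataFrame(load, index=self.variables_, columns=names)
        self.scores_ = pd.DataFrame(scores, index=X.index, columns=names)
        self.explained_variance_fraction_ = frac
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = self._prepare(X, fitting=False)
        scores = Z @ self.loadings_.to_numpy()
        return pd.DataFrame(scores, index=X.index, columns=list(self.loadings_.columns))

    def result(self) -> PcaResult:
        return PcaResult(
            kind=self.kind,
            loadings=self.loadings_,
            scores=self.scores_,
            explained_variance_fraction=self.explained_variance_fraction_,
            n_retained=self.n_retained_,
            variables=self.variables_,
        )


def fit_pca(table: pd.DataFrame, kind: str = "spatial", cumvar: float | None = None,
            group_key: str = "site_id") -> PcaResult:
    """Functional wrapper over :class:`ClimatePCA`; returns a :class:`PcaResult`."""
    est = ClimatePCA(kind=kind, cumvar=cumvar, group_key=group_key)
    est.fit(table)
    return est.result()


def deposition_covariates(deposition: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spatial and annual deposition covariates from the raw flux table.

    Returns ``(spatial, annual)``: spatial covariates are per-site means of
    *total* (wet + dry) deposition over the monitoring period (sn_dep,
    ss_dep); annual covariates are the yearly *wet* fluxes (an_dep =
    NH4-N + NO3-N, as_dep = SO4-S).
    """
    dep = deposition.copy()
    dep["n_dep"] = dep["nh4_n"] + dep["no3_n"]
    total = dep[dep["pathway"] == "total"]
    if len(total) == 0:  # fall back to wet if no total pathway supplied
        total = dep[dep["pathway"] == "wet"]
    spatial = (
        total.groupby("site_id")
        .agg(sn_dep=("n_dep", "mean"), ss_dep=("so4_s", "mean"))
        .reset_index()
    )
    wet = dep[dep["pathway"] == "wet"]
    annual = wet[["site_id", "year"]].copy()
    annual["an_dep"] = wet["n_dep"].to_numpy()
    annual["as_dep"] = wet["so4_s"].to_numpy()
    return spatial, annual.reset_index(drop=True)
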