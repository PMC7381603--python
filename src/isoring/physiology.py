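"""Leaf gas-exchange quantities derived from tree-ring stable isotopes.

Implements the simplified (no mesophyll conductance, no photorespiration)
form of the Farquhar carbon-isotope discrimination model and its inversions:

* carbon-isotope discrimination Δ13C from wood and atmospheric δ13C,
* intercellular CO2 (c_i) and the c_i/c_a ratio,
* intrinsic water-use efficiency iWUE = A/g_s = (c_a − c_i)/1.6,
* oxygen-isotope discrimination Δ18O of wood relative to source water,
* a temperature/precipitation/elevation regression for precipitation δ18O
  used as the source-water proxy,
* the relative-change statistic between two chronology endpoints.

All delta values are in per mil (δ13C vs VPDB, δ18O vs VSMOW), CO2
concentrations in ppm, iWUE in µmol CO2 mol⁻¹ H2O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientDataError

__all__ = [
    "FractionationConstants",
    "DEFAULT_CONSTANTS",
    "carbon_discrimination",
    "ci_from_discrimination",
    "iwue",
    "predict_d18op",
    "oxygen_discrimination",
    "relative_change",
    "derive_physiology",
]


@dataclass(frozen=True)
class FractionationConstants:
    """Fractionation constants of the discrimination model.

    a: fractionation during CO2 diffusion through stomata (per mil).
    b: fractionation during carboxylation by Rubisco (per mil).
    diffusivity_ratio: molar diffusivity ratio of H2O to CO2 through
        stomata (g_CO2 = g_H2O / diffusivity_ratio).
    """

    a: float = 4.4
    b: float = 27.0
    diffusivity_ratio: float = 1.6

    def __post_init__(self) -> None:
        if not (self.b > self.a > 0):
            raise DomainError(f"require b > a > 0, got a={self.a}, b={self.b}")
        if not self.diffusivity_ratio > 1:
            raise DomainError("diffusivity_ratio must exceed 1")


DEFAULT_CONSTANTS = FractionationConstants()


def carbon_discrimination(d13c_atm, d13c_wood):
    """Carbon-isotope discrimination Δ13C (per mil).

    Δ13C = (δ13C_a − δ13C_w) / (1 + δ13C_w/1000).
    """
    d13c_atm = np.asarray(d13c_atm, dtype=float)
    d13c_wood = np.asarray(d13c_wood, dtype=float)
    if np.any(d13c_wood <= -1000):
        raise DomainError("d13c_wood must exceed -1000 per mil")
    out = (d13c_atm - d13c_wood) / (1.0 + d13c_wood / 1000.0)
    return out if out.ndim else float(out)


def ci_from_discrimination(ca, delta13c, constants: FractionationConstants = DEFAULT_CONSTANTS):
    """Intercellular CO2 concentration (ppm) from discrimination.

    c_i = c_a (Δ13C − a)/(b − a). Values of Δ13C outside [a, b] give
    c_i/c_a outside [0, 1]; they are returned unclipped with a warning.
    """
    ca = np.asarray(ca, dtype=float)
    delta13c = np.asarray(delta13c, dtype=float)
    if np.any(ca <= 0):
        raise DomainError("ca must be positive")
    out_of_range = (delta13c < constants.a) | (delta13c > constants.b)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(np.sum(out_of_range))} discrimination value(s) outside "
            f"[{constants.a}, {constants.b}] per mil; c_i/c_a will fall outside [0, 1]",
            stacklevel=2,
        )
    out = ca * (delta13c - constants.a) / (constants.b - constants.a)
    return out if out.ndim else float(out)


def iwue(ca, delta13c, constants: FractionationConstants = DEFAULT_CONSTANTS):
    """Intrinsic water-use efficiency A/g_s (µmol CO2 mol⁻¹ H2O).

    iWUE = c_a/1.6 · (b − Δ13C)/(b − a), algebraically identical to
    (c_a − c_i)/1.6 with c_i from :func:`ci_from_discrimination`.
    """
    ca = np.asarray(ca, dtype=float)
    delta13c = np.asarray(delta13c, dtype=float)
    if np.any(ca <= 0):
        raise DomainError("ca must be positive")
    # grouping the fraction keeps the Δ = a and Δ = b limits exact
    out = ca / constants.diffusivity_ratio * (
        (constants.b - delta13c) / (constants.b - constants.a)
    )
    return out if out.ndim else float(out)


def predict_d18op(t_a, p_a_m, elevation_m):
    """Precipitation δ18O (per mil VSMOW) from site climate.

    Empirical surface: δ18O_P = 0.52 T − 0.006 T² + 2.42 P − 1.43 P²
    − 0.046 √E − 13.0, with T the mean annual temperature (°C), P the
    annual precipitation **in metres** and E the elevation (m a.s.l.).
    """
    t_a = np.asarray(t_a, dtype=float)
    p_a_m = np.asarray(p_a_m, dtype=float)
    elevation_m = np.asarray(elevation_m, dtype=float)
    if np.any(elevation_m < 0):
        raise DomainError("elevation must be non-negative")
    if np.any(p_a_m > 10):
        warnings.warn(
            "annual precipitation > 10 m; the regression expects metres — "
            "did you pass millimetres?",
            stacklevel=2,
        )
    out = (
        0.52 * t_a
        - 0.006 * t_a**2
        + 2.42 * p_a_m
        - 1.43 * p_a_m**2
        - 0.046 * np.sqrt(elevation_m)
        - 13.0
    )
    return out if out.ndim else float(out)


def oxygen_discrimination(d18o_wood, d18o_source):
    """Oxygen-isotope discrimination of wood vs source water (per mil).

    Δ18O = (δ18O_w − δ18O_s) / (1 + δ18O_s/1000). The source value is
    normally modelled precipitation δ18O (:func:`predict_d18op`) unless
    measured soil/source water is supplied.
    """
    d18o_wood = np.asarray(d18o_wood, dtype=float)
    d18o_source = np.asarray(d18o_source, dtype=float)
    if np.any(d18o_source <= -1000):
        raise DomainError("d18o_source must exceed -1000 per mil")
    out = (d18o_wood - d18o_source) / (1.0 + d18o_source / 1000.0)
    return out if out.ndim else float(out)


def relative_change(years, values, y0: int = 1980, y1: int = 2010) -> float:
    """Relative change (v(y1) − v(y0)) / v(y0) between two chronology years.

    ``years`` are representative years (pooled rings are dated to their
    central year); each endpoint must be present exactly.
    """
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    out = {}
    for y in (y0, y1):
        hit = np.flatnonzero(years == y)
        if hit.size == 0:
            raise InsufficientDataError(f"no value at endpoint year {y}")
        out[y] = float(values[hit[0]])
    if out[y0] == 0:
        raise DomainError(f"value at baseline year {y0} is zero; relative change undefined")
    return (out[y1] - out[y0]) / out[y0]


def _interval_mean(table: pd.DataFrame, year_col: str, value_cols, y0: int, y1: int):
    """Mean of annual values over the closed interval [y0, y1]."""
    sub = table[(table[year_col] >= y0) & (table[year_col] <= y1)]
    return {c: (float(sub[c].mean()) if len(sub) else np.nan) for c in value_cols}


def derive_physiology(
    isotopes: pd.DataFrame,
    atmosphere: pd.DataFrame,
    climate_annual: pd.DataFrame | None = None,
    sites: pd.DataFrame | None = None,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Derive the physiological series from an isotope chronology table.

    Parameters
    ----------
    isotopes
        Validated ring-level table (site_id, species, year_start, year_end,
        year, d13c, d18o, d15n, pct_n) as returned by
        :func:`isoring.io.read_isotope_table`.
    atmosphere
        Annual growing-season c_a (ppm) and δ13C_a (per mil) with columns
        year, ca, d13c_atm. Pooled rings use the mean over their interval.
    climate_annual, sites
        Optional annual climate (t_a, p_a per site-year) and site metadata
        (elevation); required to model precipitation δ18O and hence Δ18O.

    Returns
    -------
    DataFrame with one row per ring record: delta13c, ci, ci_over_ca, iwue,
    delta13c_in_range flag and, when climate is supplied, d18o_p and
    delta18o.
    """
    atm = atmosphere.set_index("year")
    rows = []
    for rec in isotopes.itertuples(index=False):
        y0, y1 = int(rec.year_start), int(rec.year_end)
        span = atm.loc[y0:y1]
        ca_val = float(span["ca"].mean())
        d13c_atm = float(span["d13c_atm"].mean())
        row = {
            "site_id": rec.site_id,
            "species": rec.species,
            "year": int(rec.year),
            "ca": ca_val,
            "d13c_atm": d13c_atm,
        }
        if pd.notna(rec.d13c):
            delta = carbon_discrimination(d13c_atm, rec.d13c)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ci = ci_from_discrimination(ca_val, delta, constants)
                row["iwue"] = iwue(ca_val, delta, constants)
            row["delta13c"] = delta
            row["ci"] = ci
            row["ci_over_ca"] = ci / ca_val
            row["delta13c_in_range"] = bool(constants.a <= delta <= constants.b)
        rows.append(row)
    out = pd.DataFrame(rows)

    if climate_annual is not None and sites is not None and "d18o" in isotopes.columns:
        elev = sites.drop_duplicates("site_id").set_index("site_id")["elevation"]
        d18o_p = []
        delta18o = []
        for rec, base in zip(isotopes.itertuples(index=False), out.itertuples(index=False)):
            clim = climate_annual[climate_annual["site_id"] == rec.site_id]
            means = _interval_mean(clim, "year", ["t_a", "p_a"], int(rec.year_start), int(rec.year_end))
            if np.isnan(means["t_a"]) or np.isnan(means["p_a"]) or rec.site_id not in elev.index:
                d18o_p.append(np.nan)
                delta18o.append(np.nan)
                continue
            dp = predict_d18op(means["t_a"], means["p_a"] / 1000.0, float(elev[rec.site_id]))
            d18o_p.append(dp)
            delta18o.append(
                oxygen_discrimination(rec.d18o, dp) if pd.notna(rec.d18o) else np.nan
            )
        out["d18o_p"] = d18o_p
        out["delta18o"] = delta18o

    if "d15n" in isotopes.columns:
        out["d15n"] = isotopes["d15n"].to_numpy()
    if "pct_n" in isotopes.columns:
        out["pct_n"] = isotopes["pct_n"].to_numpy()
    return out
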