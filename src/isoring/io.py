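"""Tabular data model and CSV input/output.

Every pipeline stage consumes and emits plain CSV (comma-separated, UTF-8,
"." decimal, empty cell = missing). Years are calendar years (integers) and
ring intervals are closed on both ends: annual rings have
year_start == year_end, pooled samples span three rings (year_end −
year_start == 2). Pooled samples are dated to their central year for all
downstream regressions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "SiteRecord",
    "SPECIES_PFT",
    "assign_pool_year",
    "read_isotope_table",
    "write_isotope_table",
    "read_climate_monthly",
    "read_deposition",
    "read_spei",
    "read_atmosphere",
    "read_sites",
    "load_default_atmosphere",
    "write_results_bundle",
    "validate_isotopes",
]

#: plant functional type per study species
SPECIES_PFT = {
    "Scots pine": "conifer",
    "Sitka spruce": "conifer",
    "oak": "deciduous",
    "beech": "deciduous",
}

#: UK critical load for nitrogen deposition to woodland, kg N ha-1 yr-1
CRITICAL_LOAD_N = (10.0, 12.0)


@dataclass
class SiteRecord:
    """Metadata for one forest stand (site × species)."""

    site_id: str
    species: str
    latitude: float
    longitude: float
    elevation: float
    planting_year: int
    soil_type: str = ""
    ndep_class: str | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES_PFT:
            raise ValidationError(
                f"unknown species {self.species!r}; expected one of {sorted(SPECIES_PFT)}"
            )
        if self.elevation < 0:
            raise ValidationError(f"{self.site_id}: elevation must be >= 0")

    @property
    def pft(self) -> str:
        return SPECIES_PFT[self.species]


def assign_pool_year(year_start: int, year_end: int) -> int:
    """Representative calendar year of a ring interval (central year)."""
    return (int(year_start) + int(year_end)) // 2


# ---------------------------------------------------------------------------
# readers

_ISO_COLUMNS = {
    "site_id": "site_id",
    "species": "species",
    "year_start": "year_start",
    "year_end": "year_end",
    "d13C": "d13c",
    "d18O": "d18o",
    "d15N": "d15n",
    "pctN": "pct_n",
}


def validate_isotopes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a ring-level isotope table and add representative years.

    Checks interval orientation, the annual/3-ring pooling contract and
    non-overlap within each site × species chronology; sorts each series
    by representative year.
    """
    df = df.copy()
    if np.any(df["year_start"] > df["year_end"]):
        bad = df.loc[df["year_start"] > df["year_end"], "site_id"].iloc[0]
        raise ValidationError(f"{bad}: year_start exceeds year_end")
    widths = (df["year_end"] - df["year_start"]).to_numpy()
    if not np.all(np.isin(widths, (0, 2))):
        bad = df.loc[~np.isin(widths, (0, 2)), "site_id"].iloc[0]
        raise ValidationError(
            f"{bad}: ring intervals must be annual or 3-ring pools "
            "(year_end - year_start in {0, 2})"
        )
    for col in ("d13c", "d18o", "d15n"):
        if col in df.columns and np.any(np.isinf(df[col].to_numpy(dtype=float))):
            raise ValidationError(f"non-finite {col} values")
    df["year"] = [assign_pool_year(a, b) for a, b in zip(df["year_start"], df["year_end"])]
    df = df.sort_values(["site_id", "species", "year"], kind="mergesort").reset_index(drop=True)
    for (site, species), grp in df.groupby(["site_id", "species"], sort=False):
        ends = grp["year_end"].to_numpy()
        starts = grp["year_start"].to_numpy()
        if np.any(starts[1:] <= ends[:-1]):
            raise ValidationError(
                f"overlapping ring intervals in chronology {site} / {species}"
            )
    return df


def read_isotope_table(path) -> pd.DataFrame:
    """Read and validate a ring-level isotope CSV.

    Expected header: site_id, species, year_start, year_end, d13C, d18O,
    d15N, pctN (isotope cells may be empty). Returns a frame with
    snake_case columns plus the representative ``year``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_ISO_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing isotope columns {sorted(missing)}")
    df = df.rename(columns=_ISO_COLUMNS)[list(_ISO_COLUMNS.values())]
    df["year_start"] = df["year_start"].astype(int)
    df["year_end"] = df["year_end"].astype(int)
    return validate_isotopes(df)


def write_isotope_table(df: pd.DataFrame, path) -> None:
    """Write a ring-level isotope table back to the CSV schema."""
    inv = {v: k for k, v in _ISO_COLUMNS.items()}
    out = df[list(_ISO_COLUMNS.values())].rename(columns=inv)
    # repr round-trips doubles exactly, preserving full precision
    out.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def _read_typed(path, required, int_cols=()) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    for c in int_cols:
        df[c] = df[c].astype(int)
    return df


def read_climate_monthly(path) -> pd.DataFrame:
    df = _read_typed(
        path, ["site_id", "year", "month", "t_mean", "t_max", "precip", "rh_min"],
        int_cols=("year", "month"),
    )
    if df["month"].min() < 1 or df["month"].max() > 12:
        raise ValidationError("month must be in 1..12")
    if (df["precip"] < 0).any():
        raise ValidationError("precipitation must be non-negative")
    if ((df["rh_min"] < 0) | (df["rh_min"] > 100)).any():
        raise ValidationError("rh_min must lie in [0, 100]")
    return df


def read_deposition(path) -> pd.DataFrame:
    df = _read_typed(
        path, ["site_id", "year", "nh4_n", "no3_n", "so4_s", "pathway"], int_cols=("year",)
    )
    if (df[["nh4_n", "no3_n", "so4_s"]] < 0).any().any():
        raise ValidationError("deposition fluxes must be non-negative")
    if not df["pathway"].isin(["wet", "total"]).all():
        raise ValidationError("pathway must be 'wet' or 'total'")
    return df


def read_spei(path) -> pd.DataFrame:
    cols = ["site_id", "year", "spei8_1", "spei8_2", "spei8_3", "spei12_1", "spei12_12"]
    df = _read_typed(path, cols, int_cols=("year",))
    for c in cols[2:]:
        m = df[c].mean()
        if np.isfinite(m) and abs(m) >= 1:
            raise ValidationError(f"{c}: |mean| >= 1 — not an anomaly-scaled index")
    return df


def read_atmosphere(path) -> pd.DataFrame:
    df = _read_typed(path, ["year", "ca", "d13c_atm"], int_cols=("year",))
    if (df["ca"] <= 0).any():
        raise ValidationError("ca must be positive")
    years = np.sort(df["year"].to_numpy())
    if len(years) > 1 and np.any(np.diff(years) != 1):
        raise ValidationError("atmospheric record years must be contiguous")
    return df


def read_sites(path) -> pd.DataFrame:
    df = _read_typed(
        path,
        ["site_id", "species", "latitude", "longitude", "elevation", "planting_year"],
        int_cols=("planting_year",),
    )
    for rec in df.itertuples(index=False):
        SiteRecord(
            site_id=rec.site_id,
            species=rec.species,
            latitude=rec.latitude,
            longitude=rec.longitude,
            elevation=rec.elevation,
            planting_year=rec.planting_year,
        )
    return df


def load_default_atmosphere() -> pd.DataFrame:
    """Packaged annual growing-season c_a / δ13C_a table, 1980–2010.

    A synthetic emulation of the published atmospheric records (c_a rising
    339→390 ppm with the observed acceleration; δ13C_a declining with the
    Suess effect). Override with a measured record via
    :func:`read_atmosphere` for replication work.
    """
    with resources.files("isoring.data").joinpath(
        "atmosphere_1980_2010_synthetic.csv"
    ).open("rb") as fh:
        return read_atmosphere(fh)


# ---------------------------------------------------------------------------
# results bundle


def write_results_bundle(results: dict[str, pd.DataFrame], outdir) -> dict:
    """Write a named collection of result tables as CSVs plus a manifest.

    Returns the manifest (also written as ``manifest.json``): one entry per
    table with its file name and row count. Re-running with identical
    inputs produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"files": []}
    for name in sorted(results):
        fname = f"{name}.csv"
        results[name].to_csv(outdir / fname, index=False)
        manifest["files"].append({"name": fname, "rows": int(len(results[name]))})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
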