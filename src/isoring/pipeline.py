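"""End-to-end orchestration: generate or read → derive → trends → PCA →
mixed models → path model → results bundle.

The pipeline is a pure function of (input tables, configuration, seed):
re-running with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iio
from .climate import (
    ANNUAL_PCA_VARS,
    SPATIAL_PCA_VARS,
    aggregate_climate,
    deposition_covariates,
    fit_pca,
)
from .exceptions import ValidationError
from .lmm import LmmSpec, simplify_model
from .physiology import derive_physiology
from .sem import PathModel, fit_path_model
from .synthetic import generate_dataset, scenario_presets
from .trends import trend_table

__all__ = [
    "RunConfig",
    "default_model_variants",
    "default_path_model",
    "assemble_analysis_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

#: environmental variables in the per-site trend table
ENV_TREND_VARS = ["nh4_n", "no3_n", "n_dep", "s_dep", "spei8_3",
                  "t_grs", "t_maxgrs", "p_grs", "vpd_grs", "t_a"]
#: isotope-derived variables in the per-stand trend table
ISO_TREND_VARS = ["iwue", "ci_over_ca", "delta18o", "d15n"]


def default_model_variants() -> dict:
    """The four attribution-model variants: (i) all sites with spatial
    deposition covariates; (ii) as (i) without Sitka spruce; (iii) adding
    the annual wet-deposition covariates; (iv) as (iii) without Sitka
    spruce."""
    base = ["pft", "pcs1", "pcs2", "pca1", "pca2", "pca3", "pca4",
            "ca", "sn_dep", "ss_dep"]
    full = base + ["an_dep", "as_dep"]
    return {
        "i": LmmSpec(response="iwue", fixed_terms=list(base)),
        "ii": LmmSpec(response="iwue", fixed_terms=list(base),
                      exclude_species=["Sitka spruce"]),
        "iii": LmmSpec(response="iwue", fixed_terms=list(full)),
        "iv": LmmSpec(response="iwue", fixed_terms=list(full),
                      exclude_species=["Sitka spruce"]),
    }


def default_path_model() -> PathModel:
    """Confirmatory path model over the isotope-derived responses.

    Spatial climate (pcs1), annual climate (pca1, pca3) and spatial N
    deposition drive the three responses; oxygen discrimination also
    feeds iWUE (shared stomatal control); pcs1 and sn_dep have correlated
    errors (deposition tracks the precipitation gradient).
    """
    return PathModel(
        nodes=["pcs1", "pca1", "pca3", "sn_dep", "iwue", "delta18o", "d15n"],
        edges=[
            ("pcs1", "iwue"), ("pcs1", "delta18o"), ("pcs1", "d15n"),
            ("pca1", "iwue"), ("pca1", "delta18o"),
            ("pca3", "iwue"), ("pca3", "delta18o"),
            ("sn_dep", "d15n"), ("delta18o", "iwue"),
        ],
        correlated_errors=[("pcs1", "sn_dep")],
    )


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``preset`` (synthetic scenario name) or ``inputs``
    (mapping table name → CSV path; requires isotopes, climate_monthly,
    deposition, spei, sites and optionally atmosphere) must be set.
    """

    preset: str | None = None
    inputs: dict | None = None
    outdir: str = "results"
    seed: int = 0
    exclude_species: list = field(default_factory=list)
    variants: dict = field(default_factory=default_model_variants)
    path_model: PathModel = field(default_factory=default_path_model)
    pca_spatial_cumvar: float = 0.90
    pca_annual_cumvar: float = 0.78

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.inputs is None):
            raise ValidationError("set exactly one of preset or inputs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "variants" in raw:
            raw["variants"] = {
                k: LmmSpec(**v) for k, v in raw["variants"].items()
            }
        if "path_model" in raw:
            raw["path_model"] = PathModel(**raw["path_model"])
        return cls(**raw)


def _load_inputs(inputs: dict):
    isotopes = iio.read_isotope_table(inputs["isotopes"])
    climate = iio.read_climate_monthly(inputs["climate_monthly"])
    deposition = iio.read_deposition(inputs["deposition"])
    spei = iio.read_spei(inputs["spei"])
    sites = iio.read_sites(inputs["sites"])
    if inputs.get("atmosphere"):
        atmosphere = iio.read_atmosphere(inputs["atmosphere"])
    else:
        atmosphere = iio.load_default_atmosphere()
    return isotopes, climate, deposition, spei, sites, atmosphere


def assemble_analysis_table(
    isotopes: pd.DataFrame,
    climate_monthly: pd.DataFrame,
    deposition: pd.DataFrame,
    spei: pd.DataFrame,
    sites: pd.DataFrame,
    atmosphere: pd.DataFrame,
    pca_spatial_cumvar: float = 0.90,
    pca_annual_cumvar: float = 0.78,
):
    """Build the per-observation analysis table and its side artifacts.

    Returns ``(analysis, artifacts)``. The analysis table has one row per
    ring record with the derived physiology, PCA scores (pooled records
    average the scores over their interval), atmospheric c_a (interval
    mean), the globally-relevant spatial deposition covariates and the
    annual wet-deposition covariates (missing before the monitoring
    window). ``artifacts`` holds the annual climate, physiology table and
    both PCA results.
    """
    clim_annual = aggregate_climate(climate_monthly)
    clim_annual = clim_annual.merge(spei, on=["site_id", "year"], how="left")

    physio = derive_physiology(isotopes, atmosphere, clim_annual, sites)

    site_means = (
        clim_annual.groupby("site_id")[SPATIAL_PCA_VARS].mean().reset_index()
    )
    pca_s = fit_pca(site_means, kind="spatial", cumvar=pca_spatial_cumvar)
    s_scores = pca_s.scores.copy()
    s_scores["site_id"] = site_means["site_id"].to_numpy()

    annual_in = clim_annual[["site_id"] + ANNUAL_PCA_VARS].dropna()
    pca_a = fit_pca(annual_in, kind="annual", cumvar=pca_annual_cumvar)
    a_scores = pca_a.scores.copy()
    a_scores["site_id"] = clim_annual.loc[annual_in.index, "site_id"].to_numpy()
    a_scores["year"] = clim_annual.loc[annual_in.index, "year"].to_numpy()

    dep_spatial, dep_annual = deposition_covariates(deposition)

    n_s = min(2, len([c for c in s_scores.columns if c.startswith("pcs")]))
    n_a = min(4, len([c for c in a_scores.columns if c.startswith("pca")]))
    s_cols = [f"pcs{j + 1}" for j in range(n_s)]
    a_cols = [f"pca{j + 1}" for j in range(n_a)]
    s_lookup = s_scores.set_index("site_id")[s_cols]
    a_lookup = a_scores.set_index(["site_id", "year"])[a_cols]
    dep_a_lookup = dep_annual.set_index(["site_id", "year"])[["an_dep", "as_dep"]]

    rows = []
    for iso, phys in zip(isotopes.itertuples(index=False), physio.itertuples(index=False)):
        y0, y1 = int(iso.year_start), int(iso.year_end)
        row = {
            "site_id": iso.site_id,
            "species": iso.species,
            "group": f"{iso.site_id}:{iso.species}",
            "year": int(iso.year),
            "year_start": y0,
            "year_end": y1,
            "iwue": getattr(phys, "iwue", np.nan),
            "ci_over_ca": getattr(phys, "ci_over_ca", np.nan),
            "delta18o": getattr(phys, "delta18o", np.nan),
            "d15n": getattr(phys, "d15n", np.nan),
            "ca": phys.ca,
        }
        if iso.site_id in s_lookup.index:
            for c in s_cols:
                row[c] = float(s_lookup.loc[iso.site_id, c])
        span_years = [(iso.site_id, y) for y in range(y0, y1 + 1)]
        hit = [sy for sy in span_years if sy in a_lookup.index]
        for c in a_cols:
            row[c] = float(np.mean([a_lookup.loc[sy, c] for sy in hit])) if hit else np.nan
        dep_hit = [sy for sy in span_years if sy in dep_a_lookup.index]
        if len(dep_hit) == (y1 - y0 + 1):
            row["an_dep"] = float(np.mean([dep_a_lookup.loc[sy, "an_dep"] for sy in dep_hit]))
            row["as_dep"] = float(np.mean([dep_a_lookup.loc[sy, "as_dep"] for sy in dep_hit]))
        else:
            row["an_dep"] = np.nan
            row["as_dep"] = np.nan
        rows.append(row)
    analysis = pd.DataFrame(rows)
    analysis = analysis.merge(dep_spatial, on="site_id", how="left")

    artifacts = {
        "climate_annual": clim_annual,
        "physiology": physio,
        "pca_spatial": pca_s,
        "pca_annual": pca_a,
        "deposition_spatial": dep_spatial,
        "deposition_annual": dep_annual,
    }
    return analysis, artifacts


def _model_table(name: str, model, elimination) -> pd.DataFrame:
    summ = model.summary().reset_index(names="term")
    summ.insert(0, "variant", name)
    meta = pd.DataFrame(
        {
            "variant": name,
            "term": ["<autocorrelation>", "<random_sd>", "<residual_sd>",
                     "<residual_var>", "<r2_marginal>", "<r2_conditional>", "<n_obs>"],
            "estimate": [model.phi_, model.sigma_group_, model.sigma_resid_,
                         model.sigma_resid_**2, model.r2_marginal_,
                         model.r2_conditional_, model.n_obs_],
            "se": np.nan, "z": np.nan, "p_value": np.nan, "stars": "",
        }
    )
    elim = pd.DataFrame(
        {
            "variant": name,
            "term": [f"<dropped:{t}>" for t, _, _ in elimination],
            "estimate": np.nan, "se": np.nan, "z": np.nan,
            "p_value": [p for _, p, _ in elimination],
            "stars": "",
        }
    )
    return pd.concat([summ, meta, elim], ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the results bundle.

    Returns a dict with the manifest, the analysis table, fitted models
    and the d-separation report. Any stage failure aborts with the stage
    name attached.
    """
    stage = "load"
    try:
        if config.preset is not None:
            presets = scenario_presets()
            if config.preset not in presets:
                raise ValidationError(f"unknown preset {config.preset!r}")
            scen = dataclasses.replace(presets[config.preset], seed=config.seed)
            dataset = generate_dataset(scen)
            tables = dataset.tables()
        else:
            iso, clim, dep, spei, sites, atm = _load_inputs(config.inputs)
            dataset = None
            tables = {
                "isotopes": iso, "climate_monthly": clim, "deposition": dep,
                "spei": spei, "sites": sites, "atmosphere": atm,
            }

        stage = "assemble"
        analysis, artifacts = assemble_analysis_table(
            tables["isotopes"], tables["climate_monthly"], tables["deposition"],
            tables["spei"], tables["sites"], tables["atmosphere"],
            pca_spatial_cumvar=config.pca_spatial_cumvar,
            pca_annual_cumvar=config.pca_annual_cumvar,
        )
        if config.exclude_species:
            analysis = analysis[~analysis["species"].isin(config.exclude_species)]

        stage = "trends"
        env = artifacts["climate_annual"].merge(
            artifacts["deposition_annual"], on=["site_id", "year"], how="left"
        )
        env = env.rename(columns={"an_dep": "n_dep", "as_dep": "s_dep"})
        wet = tables["deposition"][tables["deposition"]["pathway"] == "wet"]
        env = env.merge(wet[["site_id", "year", "nh4_n", "no3_n"]],
                        on=["site_id", "year"], how="left")
        env_trends = trend_table(env, ENV_TREND_VARS, by=["site_id"])
        iso_trends = trend_table(analysis, ISO_TREND_VARS, by=["site_id", "species"])
        trends = pd.concat([env_trends, iso_trends], ignore_index=True)

        stage = "lmm"
        model_tables = []
        models = {}
        for name, spec in config.variants.items():
            model, elim = simplify_model(spec, analysis)
            models[name] = (model, elim)
            model_tables.append(_model_table(name, model, elim))
        model_table = pd.concat(model_tables, ignore_index=True)

        stage = "sem"
        report = fit_path_model(config.path_model, analysis)

        stage = "write"
        pca_s, pca_a = artifacts["pca_spatial"], artifacts["pca_annual"]
        results = {
            "analysis_table": analysis,
            "trend_table": trends,
            "model_table": model_table,
            "pca_spatial_loadings": pca_s.loadings.reset_index(names="variable"),
            "pca_annual_loadings": pca_a.loadings.reset_index(names="variable"),
            "sem_claims": report.claims,
            "sem_paths": report.path_table,
            "sem_r2": report.r2,
        }
        outdir = Path(config.outdir)
        manifest = iio.write_results_bundle(results, outdir)
        manifest["stages"] = ["load", "assemble", "trends", "lmm", "sem", "write"]
        manifest["settings"] = {
            "preset": config.preset,
            "seed": config.seed,
            "exclude_species": list(config.exclude_species),
            "variants": {k: v.fixed_terms for k, v in config.variants.items()},
        }
        manifest["fisher_c"] = {"C": report.fisher_c, "df": report.df,
                                "p": report.c_p_value}
        blob = json.dumps(manifest, sort_keys=True, default=str).encode()
        manifest["hash"] = hashlib.sha256(blob).hexdigest()
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
        (outdir / "sem_summary.txt").write_text(report.summary() + "\n")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {
        "manifest": manifest,
        "analysis": analysis,
        "artifacts": artifacts,
        "models": models,
        "sem": report,
        "trends": trends,
        "dataset": dataset,
    }
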