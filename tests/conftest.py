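import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from isoring.pipeline import assemble_analysis_table
from isoring.synthetic import generate_dataset, scenario_presets


@pytest.fixture(scope="session")
def paper_like_dataset():
    cfg = dataclasses.replace(scenario_presets()["paper-like"], seed=1)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def paper_like_analysis(paper_like_dataset):
    ds = paper_like_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        analysis, artifacts = assemble_analysis_table(
            ds.isotopes, ds.climate_monthly, ds.deposition,
            ds.spei, ds.sites, ds.atmosphere,
        )
    return analysis, artifacts


def simulate_grouped_ar1(seed, n_groups=6, n_t=25, beta=(2.0, 1.5, -0.8),
                         phi=0.5, sd_resid=1.5, sd_group=2.0):
    """Small grouped AR(1) regression dataset with known coefficients."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, sd_group)
        x1 = rng.normal(0, 1, n_t)
        x2 = rng.normal(0, 1, n_t)
        e = np.empty(n_t)
        e[0] = rng.normal(0, sd_resid)
        innov = sd_resid * np.sqrt(1 - phi**2)
        for i in range(1, n_t):
            e[i] = phi * e[i - 1] + rng.normal(0, innov)
        y = beta[0] + beta[1] * x1 + beta[2] * x2 + b + e
        for i in range(n_t):
            rows.append((f"g{g}", i, x1[i], x2[i], y[i]))
    return pd.DataFrame(rows, columns=["group", "year", "x1", "x2", "y"])
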