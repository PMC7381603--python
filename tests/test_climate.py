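"""Climate aggregation, centering and the climate PCAs."""

import warnings

import numpy as np
import pandas as pd
import pytest

from isoring.climate import (
    ClimatePCA,
    aggregate_climate,
    center_variables,
    deposition_covariates,
    fit_pca,
    vpd_from_t_rh,
)
from isoring.exceptions import DomainError


@pytest.mark.parametrize(
    "t, rh, expected",
    [(20.0, 100.0, 0.0), (20.0, 50.0, 1.169), (0.0, 0.0, 0.6108)],
)
def test_vpd_values(t, rh, expected):
    assert vpd_from_t_rh(t, rh) == pytest.approx(expected, abs=5e-4)


def test_vpd_domain_error():
    with pytest.raises(DomainError):
        vpd_from_t_rh(20.0, 120.0)


def _monthly(site, year, t=10.0, p=50.0, months=range(1, 13)):
    return pd.DataFrame(
        {
            "site_id": site, "year": year, "month": list(months),
            "t_mean": t, "t_max": t + 5.0, "precip": p, "rh_min": 60.0,
        }
    )


def test_aggregate_constant_months():
    ann = aggregate_climate(_monthly("s1", 2000))
    row = ann.iloc[0]
    assert row["t_a"] == pytest.approx(10.0)
    assert row["p_a"] == pytest.approx(600.0)
    assert row["t_grs"] == pytest.approx(10.0)
    assert row["p_grs"] == pytest.approx(25.0)  # cm


def test_aggregate_incomplete_year_flagged():
    ann = aggregate_climate(_monthly("s1", 2000, months=range(1, 5)))
    row = ann.iloc[0]
    assert np.isnan(row["t_a"]) and np.isnan(row["t_grs"])


def test_aggregate_growing_season_slice_oracle():
    rng = np.random.default_rng(11)
    months = np.arange(1, 13)
    t = 9.0 + 6.0 * np.cos(np.pi * (months - 7) / 6) + rng.normal(0, 0.5, 12)
    df = _monthly("s1", 2001)
    df["t_mean"] = t
    ann = aggregate_climate(df)
    assert ann["t_grs"].iloc[0] == pytest.approx(t[4:9].mean(), abs=1e-12)


def test_centering_modes():
    df = pd.DataFrame({"site_id": ["a"] * 3 + ["b"] * 3, "v": [4.0, 5.0, 6.0, 8.0, 9.0, 10.0]})
    glob = center_variables(df, "global")
    grp = center_variables(df, "group", group_key="site_id")
    assert glob["v"].mean() == pytest.approx(0.0)
    assert grp.groupby("site_id")["v"].mean().abs().max() == pytest.approx(0.0)
    assert grp["v"].mean() == pytest.approx(0.0)  # grand mean also zero
    single = df[df["site_id"] == "a"]
    pd.testing.assert_frame_equal(
        center_variables(single, "global"),
        center_variables(single, "group", group_key="site_id"),
    )


def test_centering_drops_constant_column():
    df = pd.DataFrame({"v": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning, match="constant"):
        out = center_variables(df, "global", scale=True)
    assert "c" not in out.columns


def test_pca_rank_one():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 40)
    df = pd.DataFrame({"a": x, "b": 3.0 * x})
    res = fit_pca(df, kind="spatial")
    assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
    assert res.n_retained == 1


def test_pca_against_eigendecomposition_oracle():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    res = fit_pca(df, kind="spatial", cumvar=1.0)
    z = (df - df.mean()) / df.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    np.testing.assert_allclose(
        res.explained_variance_fraction, evals / evals.sum(), atol=1e-8
    )


def test_pca_reconstruction_and_variance_sum():
    rng = np.random.default_rng(13)
    df = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
    est = ClimatePCA(kind="spatial", cumvar=1.0).fit(df)
    z = (df - df.mean()).to_numpy() / df.std(ddof=1).to_numpy()
    recon = est.scores_.to_numpy() @ est.loadings_.to_numpy().T
    np.testing.assert_allclose(recon, z, atol=1e-8)
    assert est.explained_variance_fraction_.sum() == pytest.approx(1.0, abs=1e-8)
    # sign convention: each component's largest-magnitude loading positive
    L = est.loadings_.to_numpy()
    for j in range(L.shape[1]):
        assert L[np.argmax(np.abs(L[:, j])), j] > 0


def test_group_centered_pca_zero_group_means():
    rng = np.random.default_rng(21)
    df = pd.DataFrame(
        {
            "site_id": np.repeat(["a", "b", "c"], 20),
            "x": rng.normal(np.repeat([0.0, 5.0, -3.0], 20), 1.0),
            "y": rng.normal(np.repeat([1.0, -2.0, 4.0], 20), 1.0),
        }
    )
    est = ClimatePCA(kind="annual", group_key="site_id").fit(df)
    # scores are built from group-centered data: per-group mean ~ 0
    scores = est.scores_.copy()
    scores["site_id"] = df["site_id"].to_numpy()
    assert scores.groupby("site_id").mean().abs().to_numpy().max() < 1e-10


def test_pca_more_variables_than_observations_warns():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.normal(size=(4, 6)), columns=list("abcdef"))
    with pytest.warns(UserWarning, match="components"):
        res = fit_pca(df, kind="spatial", cumvar=1.0)
    assert res.loadings.shape[1] == 3


def test_deposition_covariates():
    dep = pd.DataFrame(
        {
            "site_id": ["s1"] * 4,
            "year": [1995, 1996, 1995, 1996],
            "nh4_n": [7.0, 6.0, 9.0, 8.0],
            "no3_n": [3.0, 2.0, 4.0, 3.0],
            "so4_s": [5.0, 4.0, 7.0, 6.0],
            "pathway": ["wet", "wet", "total", "total"],
        }
    )
    spatial, annual = deposition_covariates(dep)
    assert spatial.loc[0, "sn_dep"] == pytest.approx((13.0 + 11.0) / 2)  # total pathway
    assert spatial.loc[0, "ss_dep"] == pytest.approx(6.5)
    assert list(annual["an_dep"]) == [10.0, 8.0]  # wet pathway
    assert list(annual["as_dep"]) == [5.0, 4.0]
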