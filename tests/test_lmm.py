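"""AR(1) random-intercept mixed model: exactness, oracle agreement and
backward simplification."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from isoring.exceptions import DomainError
from isoring.lmm import AR1MixedLM, LmmSpec, fit_lmm, lr_test, r2_nakagawa, simplify_model

from conftest import simulate_grouped_ar1


@pytest.mark.parametrize(
    "vf, vr, ve, expected",
    [(4.0, 0.0, 4.0, (0.5, 0.5)), (4.0, 2.0, 2.0, (0.5, 0.75)), (0.0, 1.0, 1.0, (0.0, 0.5))],
)
def test_r2_nakagawa_closed_form(vf, vr, ve, expected):
    assert r2_nakagawa(vf, vr, ve) == pytest.approx(expected)


def test_r2_nakagawa_errors():
    with pytest.raises(DomainError):
        r2_nakagawa(0.0, 0.0, 0.0)
    with pytest.raises(DomainError):
        r2_nakagawa(-1.0, 1.0, 1.0)


def test_noiseless_recovery():
    rng = np.random.default_rng(1)
    rows = []
    for g in range(4):
        x = rng.normal(0, 1, 10)
        for i, xi in enumerate(x):
            rows.append((f"g{g}", i, xi, 2.0 + 3.0 * xi))
    df = pd.DataFrame(rows, columns=["g", "t", "x", "y"])
    m = AR1MixedLM().fit(df[["x"]], df["y"], df["g"].to_numpy(), df["t"].to_numpy())
    assert m.params_["intercept"] == pytest.approx(2.0, abs=1e-8)
    assert m.params_["x"] == pytest.approx(3.0, abs=1e-8)
    assert m.sigma_group_ == pytest.approx(0.0, abs=1e-6)


def test_matches_ols_with_independent_errors_one_obs_per_group():
    rng = np.random.default_rng(8)
    n = 40
    x = rng.normal(0, 1, n)
    y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
    groups = np.array([f"g{i}" for i in range(n)])
    m = AR1MixedLM(phi=0.0).fit(pd.DataFrame({"x": x}), y, groups, np.zeros(n))
    X = np.column_stack([np.ones(n), x])
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert m.params_.to_numpy() == pytest.approx(beta_ols, abs=1e-6)


def test_agrees_with_r_nlme_oracle(tmp_path):
    """Independent oracle: R nlme::lme with corAR1, REML."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    df = simulate_grouped_ar1(42)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    out = tmp_path / "fit.csv"
    script = textwrap.dedent(
        f"""
        library(nlme)
        d <- read.csv("{csv}")
        m <- lme(y ~ x1 + x2, random = ~1|group,
                 correlation = corAR1(form = ~year|group), data = d, method = "REML")
        tt <- summary(m)$tTable
        vc <- VarCorr(m)
        res <- c(tt[,1], tt[,2], coef(m$modelStruct$corStruct, unconstrained=FALSE),
                 as.numeric(vc["(Intercept)","StdDev"]), as.numeric(vc["Residual","StdDev"]),
                 as.numeric(logLik(m)))
        write.csv(data.frame(v=res), "{out}", row.names=FALSE)
        """
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = pd.read_csv(out)["v"].to_numpy()
    m = AR1MixedLM().fit(
        df[["x1", "x2"]], df["y"], df["group"].to_numpy(), df["year"].to_numpy()
    )
    np.testing.assert_allclose(m.params_.to_numpy(), ref[0:3], rtol=1e-4, atol=1e-5)
    np.testing.assert_allclose(m.bse_.to_numpy(), ref[3:6], rtol=1e-3)
    assert m.phi_ == pytest.approx(ref[6], abs=2e-3)
    assert m.sigma_group_ == pytest.approx(ref[7], rel=2e-3)
    assert m.sigma_resid_ == pytest.approx(ref[8], rel=2e-3)
    assert m.loglike_ == pytest.approx(ref[9], abs=1e-3)


def test_centering_invariance():
    df = simulate_grouped_ar1(5)
    m1 = AR1MixedLM().fit(df[["x1", "x2"]], df["y"], df["group"].to_numpy(), df["year"].to_numpy())
    shifted = df.copy()
    shifted["x1"] = shifted["x1"] + 100.0
    m2 = AR1MixedLM().fit(
        shifted[["x1", "x2"]], shifted["y"], shifted["group"].to_numpy(), shifted["year"].to_numpy()
    )
    assert m2.params_["x1"] == pytest.approx(m1.params_["x1"], abs=1e-5)
    assert m2.params_["x2"] == pytest.approx(m1.params_["x2"], abs=1e-5)
    assert m2.params_["intercept"] != pytest.approx(m1.params_["intercept"], abs=1.0)


def test_r2_ordering_and_phi_bounds():
    df = simulate_grouped_ar1(12)
    m = AR1MixedLM().fit(df[["x1", "x2"]], df["y"], df["group"].to_numpy(), df["year"].to_numpy())
    assert 0.0 <= m.r2_marginal_ <= m.r2_conditional_ <= 1.0
    assert abs(m.phi_) < 1.0


def test_phi_recovery_median():
    """Median AR(1) estimate over seeded replicates near the truth."""
    phis = []
    for seed in range(20):
        df = simulate_grouped_ar1(300 + seed, n_groups=12, n_t=31)
        m = AR1MixedLM().fit(
            df[["x1", "x2"]], df["y"], df["group"].to_numpy(), df["year"].to_numpy()
        )
        phis.append(m.phi_)
    assert 0.3 < float(np.median(phis)) < 0.7


def test_ml_likelihood_ratio_chi2_oracle():
    """LR statistic and p agree with direct χ²(1) computation."""
    from scipy import stats

    df = simulate_grouped_ar1(77)
    df["noise"] = np.random.default_rng(78).normal(0, 1, len(df))
    full = AR1MixedLM(method="ml").fit(
        df[["x1", "x2", "noise"]], df["y"], df["group"].to_numpy(), df["year"].to_numpy()
    )
    reduced = AR1MixedLM(method="ml").fit(
        df[["x1", "x2"]], df["y"], df["group"].to_numpy(), df["year"].to_numpy()
    )
    lr, p = lr_test(full, reduced, df=1)
    assert lr == pytest.approx(2.0 * (full.loglike_ - reduced.loglike_))
    assert p == pytest.approx(float(stats.chi2.sf(max(lr, 0.0), 1)))
    assert lr >= -1e-6  # adding a term cannot reduce the ML likelihood


def _analysis_frame(seed, with_noise_col=False):
    df = simulate_grouped_ar1(seed)
    df["species"] = "oak"
    if with_noise_col:
        df["noise"] = np.random.default_rng(seed + 1).normal(0, 1, len(df))
    return df


def test_simplify_keeps_strong_effects():
    spec = LmmSpec(response="y", fixed_terms=["x1", "x2"], group_col="group",
                   protected=())
    final, log = simplify_model(spec, _analysis_frame(55))
    assert log == []
    assert set(final.exog_names_) == {"intercept", "x1", "x2"}


def test_simplify_removes_pure_noise_covariate():
    df = _analysis_frame(60, with_noise_col=True)
    spec = LmmSpec(response="y", fixed_terms=["x1", "x2", "noise"], group_col="group",
                   protected=())
    final, log = simplify_model(spec, df)
    assert [t for t, _, _ in log] == ["noise"]
    assert "noise" not in final.exog_names_


def test_fit_lmm_species_exclusion_row_accounting(paper_like_analysis):
    analysis, _ = paper_like_analysis
    base = LmmSpec(response="iwue", fixed_terms=["pft", "ca"])
    all_sites = fit_lmm(base, analysis)
    no_spruce = fit_lmm(
        LmmSpec(response="iwue", fixed_terms=["pft", "ca"],
                exclude_species=["Sitka spruce"]),
        analysis,
    )
    n_spruce = int((analysis["species"] == "Sitka spruce").sum())
    assert all_sites.n_obs_ - no_spruce.n_obs_ == n_spruce
    assert no_spruce.n_groups_ == all_sites.n_groups_ - 2
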