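"""Path-model basis sets, d-separation claim tests and Fisher's C."""

import numpy as np
import pandas as pd
import pytest

from isoring.exceptions import DomainError, ValidationError
from isoring.pipeline import default_path_model
from isoring.sem import Claim, PathModel, basis_set, fisher_c, standardize_paths
from isoring.sem import test_claim as claim_pvalue

from conftest import simulate_grouped_ar1


def test_basis_set_chain():
    model = PathModel(nodes=["x", "y", "z"], edges=[("x", "y"), ("y", "z")])
    claims = basis_set(model)
    assert len(claims) == 1
    assert (claims[0].x, claims[0].y) == ("x", "z")
    assert claims[0].conditioning == ("y",)


def test_basis_set_fully_connected_empty():
    model = PathModel(
        nodes=["a", "b", "c"], edges=[("a", "b"), ("a", "c"), ("b", "c")]
    )
    assert basis_set(model) == []


def test_cyclic_graph_rejected():
    with pytest.raises(ValidationError, match="acyclic"):
        PathModel(nodes=["a", "b"], edges=[("a", "b"), ("b", "a")])


def test_basis_set_default_topology_hand_enumeration():
    """Hand enumeration of the missing-edge claims for the default model:
    exogenous pairs and the correlated-error pair are excluded; the six
    remaining non-adjacent pairs each get one claim conditioned on the
    union of both nodes' parents."""
    claims = basis_set(default_path_model())
    got = {(c.x, c.y): set(c.conditioning) for c in claims}
    expected = {
        ("pca1", "d15n"): {"pcs1", "sn_dep"},
        ("pca3", "d15n"): {"pcs1", "sn_dep"},
        ("sn_dep", "iwue"): {"pcs1", "pca1", "pca3", "delta18o"},
        ("sn_dep", "delta18o"): {"pcs1", "pca1", "pca3"},
        ("d15n", "iwue"): {"pcs1", "pca1", "pca3", "delta18o", "sn_dep"},
        ("d15n", "delta18o"): {"pcs1", "pca1", "pca3", "sn_dep"},
    }
    # orientation of the endogenous-endogenous pairs follows topological
    # order; accept either orientation with the same conditioning union
    normalized = {frozenset((x, y)): cond for (x, y), cond in got.items()}
    expected_norm = {frozenset(k): v for k, v in expected.items()}
    assert set(normalized) == set(expected_norm)
    for pair, cond in expected_norm.items():
        assert normalized[pair] - pair == cond - pair


@pytest.mark.parametrize(
    "pvals, expected",
    [((1.0, 1.0), (0.0, 4, 1.0)), ((0.5, 0.5), (2.7726, 4, 0.5966)), ((), (0.0, 0, 1.0))],
)
def test_fisher_c_values(pvals, expected):
    c, df, p = fisher_c(pvals)
    assert c == pytest.approx(expected[0], abs=5e-4)
    assert df == expected[1]
    assert p == pytest.approx(expected[2], abs=5e-4)


def test_fisher_c_domain_and_invariance():
    with pytest.raises(DomainError):
        fisher_c([0.5, 0.0])
    rng = np.random.default_rng(4)
    p = rng.uniform(0.01, 1.0, 6)
    c1, _, _ = fisher_c(p)
    c2, _, _ = fisher_c(p[::-1])
    assert c1 == pytest.approx(c2, abs=1e-12)
    # monotone: shrinking any p grows C
    p2 = p.copy()
    p2[2] *= 0.5
    assert fisher_c(p2)[0] > c1


def test_claim_power_and_degenerate():
    df = simulate_grouped_ar1(101, n_groups=12, n_t=25)  # n = 300
    # y depends on x1 through the generating model; claiming x1 missing
    # from y's parents must be strongly rejected
    claim = Claim(x="x1", y="y", conditioning=("x2",))
    assert claim_pvalue(claim, df) < 0.001
    df["const"] = 1.0
    with pytest.raises(DomainError, match="constant"):
        claim_pvalue(Claim(x="const", y="y", conditioning=()), df)


def test_standardize_paths_invariance():
    rng = np.random.default_rng(6)
    df = simulate_grouped_ar1(7)
    table = pd.DataFrame(
        [{"response": "y", "term": "x1", "estimate": 1.5, "se": 0.1,
          "p_value": 0.001, "stars": "***"}]
    )
    out = standardize_paths(table, df)
    expected = 1.5 * df["x1"].std(ddof=1) / df["y"].std(ddof=1)
    assert out.loc[0, "std_estimate"] == pytest.approx(expected)
    # doubling x's scale halves the raw coefficient, std coefficient fixed
    df2 = df.copy()
    df2["x1"] = 2.0 * df2["x1"]
    table2 = table.copy()
    table2["estimate"] = 0.75
    out2 = standardize_paths(table2, df2)
    assert out2.loc[0, "std_estimate"] == pytest.approx(expected)


def test_standardized_coefficient_recovers_correlation():
    """Bivariate normal with correlation 0.6: the standardized simple-path
    coefficient estimates the correlation."""
    rng = np.random.default_rng(60)
    rows = []
    for g in range(10):
        x = rng.normal(0, 1, 200)
        y = 0.6 * x + rng.normal(0, np.sqrt(1 - 0.36), 200)
        for i in range(200):
            rows.append((f"g{g}", i, x[i], y[i]))
    df = pd.DataFrame(rows, columns=["group", "year", "x", "y"])
    from isoring.lmm import AR1MixedLM

    m = AR1MixedLM().fit(df[["x"]], df["y"], df["group"].to_numpy(), df["year"].to_numpy())
    table = pd.DataFrame(
        [{"response": "y", "term": "x", "estimate": float(m.params_["x"]),
          "se": 0.0, "p_value": 0.0, "stars": ""}]
    )
    out = standardize_paths(table, df)
    assert out.loc[0, "std_estimate"] == pytest.approx(0.6, abs=0.05)
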