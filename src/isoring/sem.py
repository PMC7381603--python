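"""Piecewise structural-equation modelling with directed-separation tests.

A :class:`PathModel` is a DAG over observed variables, with optional
correlated-error pairs. Each endogenous node gets a component mixed model
(same site × species random intercept and AR(1) residual correlation as
the attribution models). The basis set enumerates one conditional
independence claim per missing edge, each claim is tested by adding the
missing predictor to the response's component model, and the claim
p-values combine into Fisher's C = −2 Σ ln p ~ χ²(2k) for overall
goodness of fit. Path coefficients are standardized as β·sd(x)/sd(y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, ValidationError
from .lmm import AR1MixedLM
from .trends import significance_stars

__all__ = [
    "PathModel",
    "Claim",
    "DsepReport",
    "basis_set",
    "test_claim",
    "fisher_c",
    "standardize_paths",
    "fit_path_model",
]


@dataclass(frozen=True)
class Claim:
    """One conditional-independence claim (x ⊥ y | conditioning set)."""

    x: str
    y: str
    conditioning: tuple


@dataclass
class PathModel:
    """Directed acyclic path model with optional correlated errors."""

    nodes: list
    edges: list  # (cause, effect)
    correlated_errors: list = field(default_factory=list)  # unordered pairs

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(f"edge ({a}, {b}) references unknown node")
            g.add_edge(a, b)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("path model must be acyclic")
        self._graph = g
        self._corr = {frozenset(p) for p in self.correlated_errors}

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def parents(self, node) -> list:
        return sorted(self._graph.predecessors(node))

    @property
    def endogenous(self) -> list:
        return sorted(n for n in self.nodes if self._graph.in_degree(n) > 0)

    @property
    def exogenous(self) -> list:
        return sorted(n for n in self.nodes if self._graph.in_degree(n) == 0)


def basis_set(model: PathModel) -> list[Claim]:
    """Independence claims implied by the missing edges of the DAG.

    One claim per non-adjacent pair, conditioned on the union of both
    variables' parents (the directed-separation convention used
    throughout this package). The tested response is the causally later
    node. Pairs joined by correlated errors and pairs where both nodes
    are exogenous are excluded — the latter because exogenous inputs
    (e.g. orthogonal PCA axes) carry no modelled dependence.
    """
    order = list(nx.topological_sort(model.graph))
    pos = {n: i for i, n in enumerate(order)}
    claims = []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if model.graph.has_edge(a, b) or model.graph.has_edge(b, a):
                continue
            if frozenset((a, b)) in model._corr:
                continue
            if model.graph.in_degree(a) == 0 and model.graph.in_degree(b) == 0:
                continue
            x, y = (a, b) if pos[a] < pos[b] else (b, a)
            cond = sorted((set(model.parents(x)) | set(model.parents(y))) - {x, y})
            claims.append(Claim(x=x, y=y, conditioning=tuple(cond)))
    return claims


def test_claim(
    claim: Claim,
    data: pd.DataFrame,
    group_col: str = "group",
    time_col: str = "year",
) -> float:
    """p-value of the claim's missing path.

    Fits the response's component mixed model with the conditioning set
    plus the claimed-independent variable, and returns the Wald p-value
    of that variable's coefficient.
    """
    cols = [claim.y, claim.x, *claim.conditioning]
    sub = data[[group_col, time_col, *cols]].dropna()
    x_sd = float(sub[claim.x].std(ddof=1))
    if not np.isfinite(x_sd) or x_sd == 0:
        raise DomainError(f"claim variable {claim.x!r} is constant")
    X = sub[[claim.x, *claim.conditioning]]
    model = AR1MixedLM().fit(
        X, sub[claim.y], sub[group_col].to_numpy(), sub[time_col].to_numpy()
    )
    return float(model.pvalues_[claim.x])


def fisher_c(p_values) -> tuple[float, int, float]:
    """Fisher's C statistic, its degrees of freedom and χ² p-value.

    C = −2 Σ ln p_i with df = 2k. An empty claim list (saturated model)
    gives (0, 0, 1).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("claim p-values must lie in (0, 1]")
    c = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return c, df, float(stats.chi2.sf(c, df))


def standardize_paths(path_table: pd.DataFrame, data: pd.DataFrame) -> pd.DataFrame:
    """Add standardized coefficients β·sd(x)/sd(y) to a raw path table."""
    sds = {}
    for v in set(path_table["term"]) | set(path_table["response"]):
        if v in data.columns:
            sd = float(data[v].std(ddof=1))
            if not np.isfinite(sd) or sd == 0:
                raise DomainError(f"zero-variance node {v!r}")
            sds[v] = sd
    out = path_table.copy()
    out["std_estimate"] = [
        row.estimate * sds[row.term] / sds[row.response]
        for row in out.itertuples(index=False)
    ]
    return out


@dataclass
class DsepReport:
    """Directed-separation test report for one path model."""

    claims: pd.DataFrame  # x, y, conditioning, p_value
    fisher_c: float
    df: int
    c_p_value: float
    path_table: pd.DataFrame  # response, term, estimate, se, p_value, std_estimate, stars
    r2: pd.DataFrame  # response, r2_marginal, r2_conditional

    def summary(self) -> str:
        lines = [
            f"Fisher's C = {self.fisher_c:.3f}, df = {self.df}, p = {self.c_p_value:.3f}",
            "",
            "paths (standardized coefficients):",
        ]
        for row in self.path_table.itertuples(index=False):
            lines.append(
                f"  {row.term} -> {row.response}: {row.std_estimate:+.3f} {row.stars}"
            )
        lines.append("")
        for row in self.r2.itertuples(index=False):
            lines.append(
                f"  {row.response}: R2m = {row.r2_marginal:.2f}, R2c = {row.r2_conditional:.2f}"
            )
        return "\n".join(lines)


def fit_path_model(
    model: PathModel,
    data: pd.DataFrame,
    group_col: str = "group",
    time_col: str = "year",
) -> DsepReport:
    """Fit all component models, run the d-separation tests and combine.

    Component models are the same AR(1) random-intercept family used by
    the attribution models, so path coefficients and the mixed-model
    tables are mutually consistent.
    """
    claims = basis_set(model)
    rows = []
    for cl in claims:
        p = test_claim(cl, data, group_col, time_col)
        rows.append(
            {"x": cl.x, "y": cl.y, "conditioning": ";".join(cl.conditioning), "p_value": p}
        )
    claim_df = pd.DataFrame(rows, columns=["x", "y", "conditioning", "p_value"])
    c, df, c_p = fisher_c(claim_df["p_value"]) if len(claim_df) else (0.0, 0, 1.0)

    path_rows = []
    r2_rows = []
    for node in model.endogenous:
        parents = model.parents(node)
        sub = data[[group_col, time_col, node, *parents]].dropna()
        fit = AR1MixedLM().fit(
            sub[parents], sub[node], sub[group_col].to_numpy(), sub[time_col].to_numpy()
        )
        for term in parents:
            path_rows.append(
                {
                    "response": node,
                    "term": term,
                    "estimate": float(fit.params_[term]),
                    "se": float(fit.bse_[term]),
                    "p_value": float(fit.pvalues_[term]),
                    "stars": significance_stars(float(fit.pvalues_[term])),
                }
            )
        r2_rows.append(
            {
                "response": node,
                "r2_marginal": fit.r2_marginal_,
                "r2_conditional": fit.r2_conditional_,
            }
        )
    path_table = standardize_paths(pd.DataFrame(path_rows), data)
    return DsepReport(
        claims=claim_df,
        fisher_c=c,
        df=df,
        c_p_value=c_p,
        path_table=path_table,
        r2=pd.DataFrame(r2_rows),
    )
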