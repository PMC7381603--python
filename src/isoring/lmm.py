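"""Linear mixed models with a site × species random intercept and AR(1)
residual correlation.

The model for observation t in group g (a site × species chronology) is

    y_gt = x_gt' β + b_g + ε_gt,   b_g ~ N(0, σ_b²),
    corr(ε_gt, ε_gs) = φ^|t−s|,    ε marginally N(0, σ_e²),

with the AR(1) lag measured in representative years, so the 3-ring pooled
samples (3 years apart) decay as φ³. Variance components are estimated by
REML (ML available for likelihood-ratio comparisons of nested fixed
structures) with the error scale profiled out, leaving a two-parameter
numerical optimization over (φ, σ_b²/σ_e²).

Backward simplification removes the least significant non-protected term
until all remaining terms are significant, judging significance by
single-step Šidák-adjusted Wald tests over the initial candidate family —
the family-wise analogue of simultaneous general-linear-hypothesis
testing. Raw per-term Wald elimination is available via ``adjust="none"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator

from .exceptions import ConvergenceError, DomainError, InsufficientDataError, ValidationError
from .io import SPECIES_PFT
from .trends import significance_stars

__all__ = [
    "AR1MixedLM",
    "LmmSpec",
    "fit_lmm",
    "simplify_model",
    "r2_nakagawa",
    "lr_test",
]


def r2_nakagawa(var_fixed: float, var_random: float, var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R² from the three variance components.

    R²m = σ²_f / (σ²_f + σ²_b + σ²_e); R²c adds the random-intercept
    variance to the numerator.
    """
    if min(var_fixed, var_random, var_resid) < 0:
        raise DomainError("variance components must be non-negative")
    total = var_fixed + var_random + var_resid
    if total == 0:
        raise DomainError("all variance components are zero; R² undefined")
    return var_fixed / total, (var_fixed + var_random) / total


class AR1MixedLM(BaseEstimator):
    """Random-intercept mixed model with AR(1) residuals, sklearn-style.

    Parameters
    ----------
    method : {"reml", "ml"}
        REML for reported variance components; ML for likelihood-ratio
        comparisons of nested fixed structures.
    phi : "estimate" or float
        AR(1) coefficient; a float fixes it (0 gives independent errors).
    add_intercept : bool
        Prepend an intercept column (named ``intercept``).

    Fitted attributes: ``params_``, ``bse_``, ``zvalues_``, ``pvalues_``
    (pandas Series), ``phi_``, ``sigma_group_``, ``sigma_resid_``,
    ``loglike_``, ``r2_marginal_``, ``r2_conditional_``, ``n_obs_``,
    ``n_groups_``, ``degenerate_`` (random-intercept variance collapsed
    to zero), ``cov_params_``.
    """

    _MIN_GROUP_OBS = 1

    def __init__(self, method: str = "reml", phi="estimate", add_intercept: bool = True):
        self.method = method
        self.phi = phi
        self.add_intercept = add_intercept

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _group_blocks(X, y, groups, times):
        """Group the data and pool groups sharing one AR(1) lag matrix.

        Groups with identical (sorted) time grids share the same working
        covariance, so their [X y] blocks are stacked column-wise and
        factorized once per likelihood evaluation.
        """
        order = np.argsort(groups, kind="mergesort")
        Xo, yo, go, to = X[order], y[order], groups[order], times[order]
        raw = []
        start = 0
        for i in range(1, len(go) + 1):
            if i == len(go) or go[i] != go[start]:
                t = to[start:i]
                s = np.argsort(t, kind="mergesort")
                raw.append((Xo[start:i][s], yo[start:i][s], t[s]))
                start = i
        pooled = {}
        for Xg, yg, t in raw:
            key = tuple(np.rint(t).astype(int))
            pooled.setdefault(key, []).append(np.column_stack([Xg, yg]))
        blocks = []
        for key, mats in pooled.items():
            t = np.asarray(key)
            lag = np.abs(t[:, None] - t[None, :])
            blocks.append((np.concatenate(mats, axis=1), lag, len(mats)))
        return blocks

    def _profiled_nll(self, theta, blocks, p, reml):
        """Negative profiled log-likelihood over (arctanh φ, log λ)."""
        j = 0
        if self._estimate_phi:
            phi = np.tanh(theta[j])
            j += 1
        else:
            phi = float(self.phi)
        lam = np.exp(theta[j])  # sigma_b^2 / sigma_e^2
        n = sum(b[1].shape[0] * b[2] for b in blocks)
        logdet = 0.0
        XtWiX = np.zeros((p, p))
        XtWiy = np.zeros(p)
        ytWiy = 0.0
        q = p + 1
        for M, lag, n_groups in blocks:
            W = lam + np.power(phi, lag)
            try:
                L = np.linalg.cholesky(W)
            except np.linalg.LinAlgError:
                return np.inf, None
            logdet += 2.0 * n_groups * float(np.sum(np.log(np.diag(L))))
            A = solve_triangular(L, M, lower=True, check_finite=False)
            S = A.reshape(A.shape[0], n_groups, q)
            G = np.einsum("mgi,mgj->ij", S, S)
            XtWiX += G[:p, :p]
            XtWiy += G[:p, p]
            ytWiy += float(G[p, p])
        try:
            beta = np.linalg.solve(XtWiX, XtWiy)
        except np.linalg.LinAlgError:
            return np.inf, None
        quad = max(ytWiy - float(beta @ XtWiy), 1e-300)
        dof = n - p if reml else n
        sigma2 = quad / dof
        nll = 0.5 * (dof * np.log(sigma2) + logdet + dof * (1.0 + np.log(2.0 * np.pi)))
        if reml:
            sign, ld = np.linalg.slogdet(XtWiX)
            if sign <= 0:
                return np.inf, None
            nll += 0.5 * ld
        return nll, (phi, lam, sigma2, beta, XtWiX)

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, groups, times):
        """Fit the model.

        X may be a DataFrame (column names become term names) or 2-D
        array; groups label the site × species chronology; times are the
        representative years (integer-spaced) driving the AR(1) lags.
        """
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"x{i}" for i in range(Xa.shape[1])]
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        times = np.asarray(times, dtype=float)
        keep = np.isfinite(y) & np.all(np.isfinite(Xa), axis=1)
        Xa, y, groups, times = Xa[keep], y[keep], groups[keep], times[keep]
        if self.add_intercept:
            Xa = np.column_stack([np.ones(len(y)), Xa])
            names = ["intercept"] + names
        n, p = Xa.shape
        uniq = pd.unique(groups)
        if len(uniq) < 2:
            raise InsufficientDataError("need at least 2 groups")
        if n <= p:
            raise InsufficientDataError(f"{n} observations for {p} fixed terms")
        blocks = self._group_blocks(Xa, y, groups, times)
        reml = self.method == "reml"
        self._estimate_phi = self.phi == "estimate"

        if self._estimate_phi:
            x0s = [[np.arctanh(0.3), 0.0], [0.0, 1.5]]
        else:
            x0s = [[0.0], [1.5]]
        best = None
        trace = []
        for x0 in x0s:
            res = optimize.minimize(
                lambda th: self._profiled_nll(th, blocks, p, reml)[0],
                x0=np.asarray(x0, dtype=float),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1000},
            )
            trace.append(res)
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise ConvergenceError("mixed-model optimizer failed", trace=trace)
        nll, parts = self._profiled_nll(best.x, blocks, p, reml)
        phi, lam, sigma2, beta, XtWiX = parts

        self.exog_names_ = names
        self.params_ = pd.Series(beta, index=names)
        cov = sigma2 * np.linalg.inv(XtWiX)
        self.cov_params_ = pd.DataFrame(cov, index=names, columns=names)
        bse = np.sqrt(np.diag(cov))
        self.bse_ = pd.Series(bse, index=names)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / bse
        self.zvalues_ = pd.Series(z, index=names)
        self.pvalues_ = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names)
        self.phi_ = float(phi)
        self.sigma_resid_ = float(np.sqrt(sigma2))
        self.degenerate_ = bool(lam < 1e-6)
        self.sigma_group_ = 0.0 if self.degenerate_ else float(np.sqrt(lam * sigma2))
        self.loglike_ = -float(nll)
        self.converged_ = bool(best.success or best.fun < np.inf)
        self.n_obs_ = int(n)
        self.n_groups_ = int(len(uniq))
        fixed_pred = Xa @ beta
        var_f = float(np.var(fixed_pred))
        self.var_fixed_ = var_f
        self.r2_marginal_, self.r2_conditional_ = r2_nakagawa(
            var_f, self.sigma_group_**2, self.sigma_resid_**2
        )
        self._fit_data = (Xa, y, groups, times)
        return self

    def predict(self, X):
        """Fixed-effects (population-level) prediction."""
        if isinstance(X, pd.DataFrame):
            Xa = X[[n for n in self.exog_names_ if n != "intercept"]].to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
        if self.add_intercept:
            Xa = np.column_stack([np.ones(len(Xa)), Xa])
        return Xa @ self.params_.to_numpy()

    def summary(self) -> pd.DataFrame:
        """Fixed-effect table with estimates, SEs, z, p and star codes."""
        return pd.DataFrame(
            {
                "estimate": self.params_,
                "se": self.bse_,
                "z": self.zvalues_,
                "p_value": self.pvalues_,
                "stars": [significance_stars(p) for p in self.pvalues_],
            }
        )


def lr_test(full: AR1MixedLM, reduced: AR1MixedLM, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio χ² test of nested fixed structures (fit with ML)."""
    if full.method != "ml" or reduced.method != "ml":
        raise ValidationError("likelihood-ratio tests require ML fits")
    lr = 2.0 * (full.loglike_ - reduced.loglike_)
    return lr, float(stats.chi2.sf(max(lr, 0.0), df))


# ---------------------------------------------------------------------------
# declarative model specification


@dataclass
class LmmSpec:
    """Declarative specification of one attribution model.

    ``fixed_terms`` name columns of the assembled analysis table, plus the
    special term ``pft`` (conifer-vs-deciduous contrast built from the
    species column). All covariates are centered before fitting.
    """

    response: str
    fixed_terms: list = field(default_factory=list)
    group_col: str = "group"
    time_col: str = "year"
    exclude_species: list = field(default_factory=list)
    center: bool = True
    protected: tuple = ("pft",)
    alpha: float = 0.05


def build_design(spec: LmmSpec, data: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Assemble (X, y, groups, times) for a spec, applying exclusions,
    the PFT contrast, row-wise completeness and covariate centering."""
    df = data.copy()
    if spec.exclude_species:
        df = df[~df["species"].isin(spec.exclude_species)]
    cols = {}
    for term in spec.fixed_terms:
        if term == "pft":
            cols["pft"] = df["species"].map(lambda s: 1.0 if SPECIES_PFT[s] == "conifer" else 0.0)
        elif term in df.columns:
            cols[term] = df[term].astype(float)
        else:
            raise ValidationError(f"fixed term {term!r} not in analysis table")
    X = pd.DataFrame(cols, index=df.index)
    keep = df[spec.response].notna() & X.notna().all(axis=1)
    df, X = df[keep], X[keep]
    if spec.center:
        X = X - X.mean()
    return X, df[spec.response].astype(float), df[spec.group_col], df[spec.time_col]


def fit_lmm(spec: LmmSpec, data: pd.DataFrame, method: str = "reml", phi="estimate") -> AR1MixedLM:
    """Fit the mixed model described by ``spec`` on the analysis table."""
    X, y, groups, times = build_design(spec, data)
    model = AR1MixedLM(method=method, phi=phi)
    return model.fit(X, y, groups.to_numpy(), times.to_numpy())


def simplify_model(
    spec: LmmSpec,
    data: pd.DataFrame,
    alpha: float | None = None,
    adjust: str = "sidak",
) -> tuple[AR1MixedLM, list]:
    """Backward elimination to the minimal significant model.

    Iteratively refits, removing the least significant non-protected term
    whose (Šidák-adjusted, family = initial candidate count) p-value
    exceeds α, until every remaining term is significant. The PFT
    contrast and intercept are never removed. Returns the final fit and
    the elimination log of ``(term, p_raw, p_adjusted)`` tuples.
    """
    if adjust not in ("sidak", "none"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    alpha = spec.alpha if alpha is None else alpha
    protected = set(spec.protected) | {"intercept"}
    terms = list(spec.fixed_terms)
    k_family = max(len([t for t in terms if t not in protected]), 1)
    # freeze the row set implied by the *initial* term list so every step
    # of the elimination is fitted and compared on the same observations
    X0, _, _, _ = build_design(spec, data)
    data = data.loc[X0.index]
    log = []
    while True:
        cur = LmmSpec(
            response=spec.response,
            fixed_terms=terms,
            group_col=spec.group_col,
            time_col=spec.time_col,
            exclude_species=spec.exclude_species,
            center=spec.center,
            protected=spec.protected,
            alpha=alpha,
        )
        model = fit_lmm(cur, data)
        candidates = [t for t in terms if t not in protected]
        if not candidates:
            return model, log
        p_raw = model.pvalues_[candidates]
        if adjust == "sidak":
            p_adj = 1.0 - (1.0 - p_raw) ** k_family
        else:
            p_adj = p_raw
        worst = p_adj.idxmax()
        if p_adj[worst] <= alpha:
            return model, log
        log.append((worst, float(p_raw[worst]), float(p_adj[worst])))
        terms = [t for t in terms if t != worst]
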