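"""Downstream statistics on phylobetadiversity matrices and alpha metrics.

* NMDS: two-dimensional nonmetric ordination of a D_pw matrix (Kruskal
  stress-1, monotone regression via SMACOF), initialized from classical
  metric scaling with seeded random restarts.
* 95% confidence ellipses per tree type around ordination points.
* PERMANOVA: adonis-style sequential partitioning of a distance matrix by
  tree type and year, pseudo-F and r-squared per term, free row permutation.
* Linear mixed-effect models of tree-type effects on PD/MPD/NRI with
  hybrid as the reference level, random intercepts for branch-length
  realization, year and (for individual-tree analyses) tree id, REML
  estimation and t-based 95% confidence intervals. A contrast is called
  significant iff its CI excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import smacof

from .beta_metrics import DpwMatrix

__all__ = [
    "NmdsResult",
    "EllipseSpec",
    "PermanovaResult",
    "PermanovaTerm",
    "LmeResult",
    "FixedEffect",
    "LmeConvergenceError",
    "nmds",
    "confidence_ellipse",
    "permanova",
    "fit_lme_tree_type",
]


# ---------------------------------------------------------------- NMDS


@dataclass(frozen=True)
class NmdsResult:
    coordinates: pd.DataFrame  # index community id, columns NMDS1, NMDS2
    stress: float  # Kruskal stress-1
    converged: bool
    n_iter: int


def _as_square(dmatrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(dmatrix, DpwMatrix):
        return np.asarray(dmatrix.values, dtype=float), list(dmatrix.community_ids)
    if isinstance(dmatrix, pd.DataFrame):
        return dmatrix.to_numpy(dtype=float), [str(i) for i in dmatrix.index]
    arr = np.asarray(dmatrix, dtype=float)
    return arr, [f"community_{i}" for i in range(arr.shape[0])]


def _classical_scaling(d: np.ndarray, ndim: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d * d) @ j
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1][:ndim]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def nmds(
    dmatrix,
    dimensions: int = 2,
    seed: int | None = None,
    n_restarts: int = 20,
    max_iter: int = 500,
    eps: float = 1e-9,
) -> NmdsResult:
    """Nonmetric multidimensional scaling minimizing Kruskal stress-1.

    Runs SMACOF with isotonic (monotone) regression once from a classical
    metric-scaling configuration and ``n_restarts`` times from seeded random
    configurations, keeping the lowest-stress solution. Coordinates are
    centered at the origin. Requires >= 4 communities and a zero diagonal.
    """
    d, ids = _as_square(dmatrix)
    n = d.shape[0]
    if n < 4:
        raise ValueError("NMDS needs at least 4 communities")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.all(d == 0):
        raise ValueError("degenerate all-zero distance matrix")

    rng = np.random.default_rng(seed)
    inits = [_classical_scaling(d, dimensions)]
    for _ in range(n_restarts):
        inits.append(rng.normal(size=(n, dimensions)))

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for init in inits:
            coords, stress, n_iter = smacof(
                d,
                metric=False,
                n_components=dimensions,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=eps,
                normalized_stress=True,
                return_n_iter=True,
            )
            if best is None or stress < best[1] - 1e-15:
                best = (coords, float(stress), n_iter)
    coords, stress, n_iter = best
    coords = coords - coords.mean(axis=0)
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"NMDS{k + 1}" for k in range(dimensions)]
    )
    return NmdsResult(
        coordinates=frame, stress=stress, converged=n_iter < max_iter, n_iter=n_iter
    )


# ------------------------------------------------------- confidence ellipses


@dataclass(frozen=True)
class EllipseSpec:
    """A group's confidence ellipse: mean, covariance and chi-square scaling."""

    group: str
    center: np.ndarray
    covariance: np.ndarray
    level: float = 0.95

    @property
    def radius2(self) -> float:
        """Squared Mahalanobis radius of the boundary."""
        return float(stats.chi2.ppf(self.level, df=2))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.covariance)
        m2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return m2 <= self.radius2

    def boundary(self, n_points: int = 100) -> np.ndarray:
        theta = np.linspace(0, 2 * np.pi, n_points)
        circle = np.c_[np.cos(theta), np.sin(theta)]
        l = np.linalg.cholesky(self.covariance)
        return self.center + np.sqrt(self.radius2) * circle @ l.T


def confidence_ellipse(
    points: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    level: float = 0.95,
) -> list[EllipseSpec]:
    """Per-group confidence ellipses from the group mean and covariance,
    scaled by the chi-square(2) quantile. Groups with < 3 points are skipped
    with a warning (their covariance is singular or undefined)."""
    pts = points.to_numpy() if isinstance(points, pd.DataFrame) else np.asarray(points)
    groups = np.asarray(list(groups))
    out = []
    for g in pd.unique(groups):
        sub = pts[groups == g]
        if sub.shape[0] < 3:
            warnings.warn(f"group {g!r} has < 3 points; ellipse skipped")
            continue
        out.append(
            EllipseSpec(
                group=str(g),
                center=sub.mean(axis=0),
                covariance=np.cov(sub, rowvar=False),
                level=level,
            )
        )
    return out


# ------------------------------------------------------------- PERMANOVA


@dataclass(frozen=True)
class PermanovaTerm:
    term: str
    df: int
    ss: float
    r2: float
    pseudo_f: float
    p_value: float


@dataclass(frozen=True)
class PermanovaResult:
    terms: tuple[PermanovaTerm, ...]
    residual_df: int
    residual_ss: float
    total_ss: float
    permutations: int

    @property
    def residual_r2(self) -> float:
        return self.residual_ss / self.total_ss

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"term": t.term, "df": t.df, "SS": t.ss, "r2": t.r2,
             "pseudo_F": t.pseudo_f, "p_value": t.p_value}
            for t in self.terms
        ]
        rows.append({"term": "Residual", "df": self.residual_df,
                     "SS": self.residual_ss, "r2": self.residual_r2,
                     "pseudo_F": np.nan, "p_value": np.nan})
        return pd.DataFrame(rows)


def _dummy(series: pd.Series) -> np.ndarray:
    levels = pd.unique(series)
    if len(levels) < 2:
        raise ValueError(f"factor has a single level: {series.name!r}")
    return pd.get_dummies(series.astype("category"), drop_first=True).to_numpy(float)


def _hat(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse hat matrix: robust to rank-deficient dummy blocks
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def permanova(
    dmatrix,
    factors: pd.DataFrame,
    terms: Sequence[str] = ("tree_type", "year"),
    permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix (adonis-style).

    The squared distance matrix is Gower-centered and partitioned by
    sequential (order-of-entry) sums of squares over ``terms`` (each treated
    as a factor). Pseudo-F per term uses the residual mean square of the
    full model; p-values come from free permutation of the rows (and the
    matching columns) of the centered matrix.
    """
    d, ids = _as_square(dmatrix)
    n = d.shape[0]
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    if len(factors) != n:
        raise ValueError("factor table length does not match distance matrix")
    if not all(str(a) == str(b) for a, b in zip(factors.index, ids)):
        raise ValueError("factor table index must match distance-matrix ids in order")

    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d * d) @ j
    ss_total = float(np.trace(g))

    ones = np.ones((n, 1))
    design_blocks = [ones]
    projectors, dfs = [], []
    h_prev = _hat(ones)
    for term in terms:
        design_blocks.append(_dummy(factors[term]))
        x = np.hstack(design_blocks)
        h = _hat(x)
        projectors.append(h - h_prev)
        dfs.append(int(round(np.trace(h - h_prev))))
        h_prev = h
    resid_proj = np.eye(n) - h_prev
    df_resid = int(round(np.trace(resid_proj)))
    if df_resid <= 0:
        raise ValueError("model saturates the data: no residual degrees of freedom")

    def _stats(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(p * gm.T)) for p in projectors])
        ss_res = float(np.sum(resid_proj * gm.T))
        return ss, ss_res

    ss_terms, ss_res = _stats(g)
    ms_res = ss_res / df_resid
    f_obs = (ss_terms / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=int)
    for _ in range(permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = _stats(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_resid)
        # ties (e.g. symmetric relabelings) count as exceedances: without a
        # tolerance, float jitter would split exact ties at random
        exceed += f_p >= f_obs - 1e-8 * np.abs(f_obs)
    p_vals = (exceed + 1) / (permutations + 1)

    term_results = tuple(
        PermanovaTerm(
            term=t, df=dfs[i], ss=float(ss_terms[i]), r2=float(ss_terms[i] / ss_total),
            pseudo_f=float(f_obs[i]), p_value=float(p_vals[i]),
        )
        for i, t in enumerate(terms)
    )
    return PermanovaResult(
        terms=term_results, residual_df=df_resid, residual_ss=ss_res,
        total_ss=ss_total, permutations=permutations,
    )


# ------------------------------------------------------------------ LME


class LmeConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer's diagnostics."""


@dataclass(frozen=True)
class FixedEffect:
    name: str
    estimate: float
    se: float
    t_value: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        """CI-excludes-zero rule."""
        return self.ci_low > 0 or self.ci_high < 0


@dataclass(frozen=True)
class LmeResult:
    fixed_effects: tuple[FixedEffect, ...]
    variance_components: dict = field(default_factory=dict)
    residual_variance: float = float("nan")
    method: str = "REML"
    converged: bool = True
    n_obs: int = 0
    df: int = 0
    fitted: np.ndarray | None = field(default=None, repr=False)

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"variable": fe.name, "estimate": fe.estimate, "SE": fe.se,
                 "t_value": fe.t_value, "ci_low": fe.ci_low, "ci_high": fe.ci_high,
                 "significant": fe.significant}
                for fe in self.fixed_effects
            ]
        )


def fit_lme_tree_type(
    data: pd.DataFrame,
    metric_col: str = "value",
    pooled: bool = False,
    include_richness: bool = False,
    reference: str = "hybrid",
    conf_level: float = 0.95,
    random_effects: Sequence[str] | None = None,
) -> LmeResult:
    """Mixed model of a phylogenetic metric on tree type (hybrid reference).

    Fixed effects: intercept at the reference level plus contrasts for the
    other tree types, optionally a species-richness covariate (used for PD
    models, where richness is a known driver). Random intercepts: crossed
    variance components for branch-length ``realization``, ``year`` and
    (individual-tree analyses only) ``tree_id``, fitted by REML. Random
    factors with fewer than two levels in ``data`` carry no information and
    are dropped; with no random factor left the model collapses to ordinary
    least squares (its exact degenerate limit). Confidence intervals are
    t-based with residual degrees of freedom.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = data.copy()
    if random_effects is None:
        random_effects = ["realization", "year"] + ([] if pooled else ["tree_id"])
    levels = [lvl for lvl in pd.unique(data["tree_type"])]
    if len(levels) < 2:
        raise ValueError("need at least two tree types")
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")

    fixed = f"{metric_col} ~ C(tree_type, Treatment(reference='{reference}'))"
    if include_richness:
        fixed += " + richness"
    usable_re = [
        f for f in random_effects
        if f in data.columns and data[f].nunique() > 1
    ]

    if not usable_re:
        model = smf.ols(fixed, data=data)
        fit = model.fit()
        params, bse = fit.params, fit.bse
        vc: dict = {}
        resid_var = float(fit.mse_resid)
        fitted = np.asarray(fit.fittedvalues)
        converged = True
    else:
        vc_formula = {f: f"0 + C({f})" for f in usable_re}
        data["_all"] = 1
        model = smf.mixedlm(fixed, data=data, groups="_all", vc_formula=vc_formula,
                            re_formula="0")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = model.fit(reml=True, method=["lbfgs", "powell"])
            except Exception as exc:
                raise LmeConvergenceError(f"REML optimization failed: {exc}") from exc
        if not fit.converged:
            raise LmeConvergenceError(
                "REML optimization did not converge; variance components "
                f"at exit: {dict(zip(usable_re, np.atleast_1d(fit.vcomp)))}"
            )
        params, bse = fit.fe_params, fit.bse_fe
        vc = {name: float(v) for name, v in zip(usable_re, np.atleast_1d(fit.vcomp))}
        resid_var = float(fit.scale)
        fitted = np.asarray(fit.fittedvalues)
        converged = bool(fit.converged)

    exog = np.asarray(model.exog, dtype=float)
    dfs = _containment_dfs(exog, list(params.index), data, usable_re)
    effects = []
    for name in params.index:
        pretty = _pretty_term(name, reference)
        est, se = float(params[name]), float(bse[name])
        tcrit = stats.t.ppf(0.5 + conf_level / 2.0, dfs[name])
        effects.append(
            FixedEffect(
                name=pretty, estimate=est, se=se,
                t_value=est / se if se > 0 else float("inf"),
                ci_low=est - tcrit * se, ci_high=est + tcrit * se,
            )
        )
    return LmeResult(
        fixed_effects=tuple(effects), variance_components=vc,
        residual_variance=resid_var, method="REML" if usable_re else "OLS",
        converged=converged, n_obs=len(data), df=int(min(dfs.values())),
        fitted=fitted,
    )


def _containment_dfs(
    exog: np.ndarray, names: list[str], data: pd.DataFrame,
    random_factors: Sequence[str],
) -> dict[str, float]:
    """Containment degrees of freedom per fixed-effect column.

    A fixed effect that is constant within every level of a random factor is
    estimated between that factor's levels, so its t reference has
    (number of levels) - (number of fixed effects constant within the factor)
    degrees of freedom; effects varying within all groupings use the
    residual df. The smallest qualifying df is used per effect.
    """
    n, p = exog.shape
    resid_df = max(n - p, 1)
    const_within: dict[str, np.ndarray] = {}
    for f in random_factors:
        codes = pd.Categorical(data[f]).codes
        flags = np.array([
            all(np.ptp(exog[codes == lvl, j]) == 0 for lvl in np.unique(codes))
            for j in range(p)
        ])
        const_within[f] = flags
    dfs: dict[str, float] = {}
    for j, name in enumerate(names):
        candidates = [
            max(data[f].nunique() - int(const_within[f].sum()), 1)
            for f in random_factors if const_within[f][j]
        ]
        dfs[name] = float(min(candidates)) if candidates else float(resid_df)
    return dfs


def _pretty_term(name: str, reference: str) -> str:
    if name == "Intercept":
        return f"Intercept ({reference})"
    if "[T." in name:
        return name.split("[T.")[1].rstrip("]")
    return name
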