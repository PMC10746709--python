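"""Piecewise path analysis with site-level random intercepts.

Each endogenous variable of a directed acyclic metamodel is fit by its own
random-intercept linear mixed model (site as the grouping factor), the
models are combined, and the DAG's implied conditional independencies are
tested by Shipley's d-separation procedure: each independence claim
``x _||_ y | pa(x) u pa(y)`` contributes a p-value, pooled into Fisher's
C = -2 sum(ln p), compared to a chi-square with 2k degrees of freedom.

Mixed models are fit by maximum likelihood with the fixed effects and the
residual variance profiled out, leaving a one-dimensional search over the
variance ratio theta = sigma_b^2 / sigma_e^2.  ML (not REML) keeps the
d-separation p-values from sequentially refit models internally
consistent.  Wald z tests give coefficient p-values.

Variance explained is summarised by the marginal / conditional R^2 of
Nakagawa & Schielzeth (fixed effects alone vs fixed plus random).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from marshcarbon.datamodel import logger

__all__ = [
    "PathDAG",
    "LmmFit",
    "SemResult",
    "fit_lmm",
    "standardize_paths",
    "basis_set",
    "fishers_c",
    "r2_nakagawa",
    "simplify_and_fit_sem",
    "read_dag",
    "DEFAULT_TRANSFORMS",
]

# analysis-scale transforms used for the observational covariates
DEFAULT_TRANSFORMS = {
    "belowground_oc_stock": "log10",
    "bg_biomass": "log10",
    "cn_senescent": "log10",
    "cn_green": "log10",
    "cn_roots": "log10",
    "burrow_surface": "sqrt",
    "litter": "sqrt",
    "ag_biomass": "sqrt",
}


@dataclass(frozen=True)
class PathDAG:
    """Directed acyclic metamodel over observed variables."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        for cause, effect in self.edges:
            if cause not in self.nodes or effect not in self.nodes:
                raise ValueError(f"edge ({cause!r}, {effect!r}) uses undeclared node")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("metamodel contains a cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(c for c, e in self.edges if e == node))

    @property
    def endogenous(self) -> tuple[str, ...]:
        order = self.topological_order()
        return tuple(n for n in order if self.parents(n))

    @property
    def exogenous(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if not self.parents(n))

    def topological_order(self) -> tuple[str, ...]:
        return tuple(nx.lexicographical_topological_sort(self.graph()))

    def without_edge(self, cause: str, effect: str) -> "PathDAG":
        return PathDAG(self.nodes, tuple(e for e in self.edges if e != (cause, effect)))

    def with_edge(self, cause: str, effect: str) -> "PathDAG":
        return PathDAG(self.nodes, self.edges + ((cause, effect),))


def read_dag(path) -> PathDAG:
    """Read a plain-text edge list: one ``cause -> effect`` per line.

    Lines starting with ``#`` are comments; a bare node name declares an
    isolated node.
    """
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" in line:
                cause, effect = (s.strip() for s in line.split("->", 1))
                for n in (cause, effect):
                    if n not in nodes:
                        nodes.append(n)
                edges.append((cause, effect))
            elif line not in nodes:
                nodes.append(line)
    return PathDAG(tuple(nodes), tuple(edges))


@dataclass(frozen=True)
class LmmFit:
    """One random-intercept linear mixed model fit (maximum likelihood)."""

    response: str
    names: tuple[str, ...]  # coefficient names, intercept first
    beta: tuple[float, ...]
    se: tuple[float, ...]
    pvalues: tuple[float, ...]
    sigma_b2: float  # random-intercept variance
    sigma_e2: float  # residual variance
    loglik: float
    n: int
    n_groups: int
    fitted_fixed: tuple[float, ...] = field(repr=False, default=())

    def coef(self, name: str) -> float:
        return self.beta[self.names.index(name)]

    def pvalue(self, name: str) -> float:
        return self.pvalues[self.names.index(name)]


def _profiled_ml(y: np.ndarray, X: np.ndarray, gidx: list[np.ndarray], theta: float):
    """Profile beta and sigma_e^2 at a fixed variance ratio theta.

    Block-diagonal V = I + theta * J per group inverts in closed form
    (Woodbury): V^-1 = I - theta/(1 + theta n_g) J.
    """
    n, p = X.shape
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for ix in gidx:
        Xg, yg = X[ix], y[ix]
        ng = len(ix)
        c = theta / (1.0 + theta * ng)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        xtvx += Xg.T @ Xg - c * np.outer(sx, sx)
        xtvy += Xg.T @ yg - c * sx * sy
        ytvy += yg @ yg - c * sy * sy
        logdet += math.log1p(theta * ng)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - 2.0 * beta @ xtvy + beta @ xtvx @ beta
    rss = max(rss, 1e-300)
    sigma_e2 = rss / n
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma_e2) + n + logdet)
    return beta, sigma_e2, loglik, xtvx


def fit_lmm(
    y,
    X,
    groups,
    names: tuple[str, ...] | None = None,
    response: str = "y",
) -> LmmFit:
    """Fit ``y = X beta + b_group + eps`` by profiled maximum likelihood.

    ``X`` must include an intercept column if one is wanted.  With a
    single group the model degenerates to ordinary least squares (warned).
    Rank-deficient designs raise, naming the collinear column.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    if n <= p:
        raise ValueError("need n > number of coefficients")
    # rank check via QR
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]
    if bad.size:
        raise ValueError(f"design matrix is rank deficient; collinear column(s): "
                         f"{[names[j] for j in bad]}")
    labels = pd.factorize(np.asarray(groups))[0]
    gidx = [np.where(labels == g)[0] for g in range(labels.max() + 1)]
    n_groups = len(gidx)
    if n_groups == 1:
        logger.warning("single group: mixed model reduces to ordinary least squares")

    def negll(log_theta: float) -> float:
        return -_profiled_ml(y, X, gidx, math.exp(log_theta))[2]

    theta = 0.0
    if n_groups > 1:
        res = optimize.minimize_scalar(negll, bounds=(-12.0, 12.0), method="bounded",
                                       options={"xatol": 1e-10})
        theta_hat = math.exp(res.x)
        # the boundary theta = 0 is not in the log parameterisation: compare
        ll_zero = _profiled_ml(y, X, gidx, 0.0)[2]
        theta = 0.0 if ll_zero >= -res.fun - 1e-9 else theta_hat
    beta, sigma_e2, loglik, xtvx = _profiled_ml(y, X, gidx, theta)
    cov = sigma_e2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LmmFit(
        response=response,
        names=tuple(names),
        beta=tuple(beta),
        se=tuple(se),
        pvalues=tuple(pvals),
        sigma_b2=theta * sigma_e2,
        sigma_e2=sigma_e2,
        loglik=loglik,
        n=n,
        n_groups=n_groups,
        fitted_fixed=tuple(X @ beta),
    )


def standardize_paths(fit: LmmFit, data: pd.DataFrame) -> dict[str, float]:
    """Standardised coefficients beta * sd(x)/sd(y) on the analysis scale."""
    sd_y = float(data[fit.response].std(ddof=1))
    out = {}
    for name, b in zip(fit.names, fit.beta):
        if name == "(intercept)":
            continue
        sd_x = float(data[name].std(ddof=1))
        if sd_x == 0:
            raise ValueError(f"zero-variance predictor {name!r}")
        out[name] = b * sd_x / sd_y
    return out


def basis_set(dag: PathDAG) -> list[tuple[str, str, tuple[str, ...]]]:
    """Shipley's d-separation basis set of a DAG.

    One claim per non-adjacent ordered pair ``(x, y)`` with ``y`` not an
    ancestor of ``x``, conditioned on the union of the parents of both.
    Claims are emitted in canonical (topological, then lexicographic)
    order so reports are diffable.
    """
    g = dag.graph()
    order = dag.topological_order()
    pos = {n: i for i, n in enumerate(order)}
    adjacent = {frozenset(e) for e in dag.edges}
    claims = []
    for i, x in enumerate(order):
        for y in order[i + 1:]:
            if frozenset((x, y)) in adjacent:
                continue
            # y is after x in a topological order, hence not an ancestor of x
            cond = sorted((set(dag.parents(x)) | set(dag.parents(y))) - {x, y})
            claims.append((x, y, tuple(cond)))
    claims.sort(key=lambda c: (pos[c[0]], pos[c[1]]))
    return claims


def fishers_c(claim_pvalues) -> tuple[float, int, float]:
    """Fisher's C over d-separation p-values: C = -2 sum(ln p), df = 2k."""
    ps = list(claim_pvalues)
    if any(p <= 0 or p > 1 for p in ps):
        raise ValueError("all p-values must lie in (0, 1]")
    c = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    return c, df, float(stats.chi2.sf(c, df)) if df else 1.0


def r2_nakagawa(fit: LmmFit) -> tuple[float, float]:
    """Marginal and conditional R^2 for a random-intercept mixed model."""
    var_f = float(np.var(fit.fitted_fixed, ddof=1)) if len(fit.fitted_fixed) > 1 else 0.0
    denom = var_f + fit.sigma_b2 + fit.sigma_e2
    if denom == 0:
        raise ValueError("all variance components are zero; R^2 undefined")
    return var_f / denom, (var_f + fit.sigma_b2) / denom


@dataclass(frozen=True)
class SemResult:
    """Fitted piecewise SEM: per-response models, paths and global fit."""

    dag: PathDAG
    fits: dict[str, LmmFit]
    std_coefficients: dict[tuple[str, str], float]
    path_pvalues: dict[tuple[str, str], float]
    claims: tuple[tuple[str, str, tuple[str, ...], float], ...]
    fisher_c: float
    df: int
    p_value: float
    r2: dict[str, tuple[float, float]]  # (marginal, conditional) per response
    dsep_ok: bool


def _design(data: pd.DataFrame, predictors: tuple[str, ...]):
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in predictors])
    return X, ("(intercept)",) + tuple(predictors)


def _fit_node(data: pd.DataFrame, node: str, predictors: tuple[str, ...], group_col: str):
    X, names = _design(data, predictors)
    return fit_lmm(data[node].to_numpy(float), X, data[group_col], names, response=node)


def _claim_pvalue(data: pd.DataFrame, claim, group_col: str) -> float:
    x, y, cond = claim
    predictors = (x,) + tuple(c for c in cond if c != x)
    fit = _fit_node(data, y, predictors, group_col)
    return fit.pvalue(x)


def apply_transforms(data: pd.DataFrame, transforms: dict[str, str] | None) -> pd.DataFrame:
    """Return a copy of ``data`` on the declared analysis scale."""
    out = data.copy()
    for col, how in (transforms or {}).items():
        if col not in out.columns:
            continue
        if how == "log10":
            out[col] = np.log10(out[col])
        elif how == "sqrt":
            out[col] = np.sqrt(out[col])
        else:
            raise ValueError(f"unknown transform {how!r} for {col!r}")
    return out


def _evaluate(dag: PathDAG, data: pd.DataFrame, group_col: str):
    fits = {node: _fit_node(data, node, dag.parents(node), group_col)
            for node in dag.endogenous}
    claims = []
    for claim in basis_set(dag):
        claims.append((*claim, _claim_pvalue(data, claim, group_col)))
    c, df, p = fishers_c([cl[3] for cl in claims])
    return fits, tuple(claims), c, df, p


def simplify_and_fit_sem(
    dag: PathDAG,
    data: pd.DataFrame,
    alpha: float = 0.05,
    keep: tuple[tuple[str, str], ...] = (),
    transforms: dict[str, str] | None = None,
    group_col: str = "site_id",
    candidate_edges: tuple[tuple[str, str], ...] = (),
    max_steps: int = 100,
) -> SemResult:
    """Simplify the metamodel and fit the final piecewise SEM.

    Unsupported paths (Wald P > ``alpha``) are removed one at a time,
    least-supported first, as long as the d-separation fit (Fisher's C
    P > alpha) holds or improves; paths listed in ``keep`` are retained
    regardless of significance.  If the simplified model fails the d-sep
    test, edges from ``candidate_edges`` matching the most significant
    violated claim are added back.  A final model that still fails is
    returned flagged (``dsep_ok=False``), never silently.
    """
    keep = {tuple(e) for e in keep}
    data = apply_transforms(data, transforms)
    current = dag
    fits, claims, c, df, p = _evaluate(current, data, group_col)
    for _ in range(max_steps):
        # candidate removals: edge with the largest unsupported p-value
        worst, worst_p = None, alpha
        for node in current.endogenous:
            fit = fits[node]
            for parent in current.parents(node):
                pv = fit.pvalue(parent)
                if (parent, node) not in keep and pv > worst_p:
                    worst, worst_p = (parent, node), pv
        if worst is None:
            break
        trial = current.without_edge(*worst)
        t_fits, t_claims, t_c, t_df, t_p = _evaluate(trial, data, group_col)
        if t_p > alpha or t_p >= p:
            current, fits, claims, c, df, p = trial, t_fits, t_claims, t_c, t_df, t_p
        else:
            logger.info("keeping path %s -> %s: removal would break d-sep fit", *worst)
            break
    # d-sep-suggested additions restricted to the declared candidate set
    for _ in range(max_steps):
        if p > alpha or not candidate_edges:
            break
        violated = [cl for cl in claims if cl[3] < alpha]
        added = False
        for x, y, _cond, _pv in sorted(violated, key=lambda cl: cl[3]):
            for cand in ((x, y), (y, x)):
                if tuple(cand) in {tuple(e) for e in candidate_edges} and cand not in current.edges:
                    current = current.with_edge(*cand)
                    fits, claims, c, df, p = _evaluate(current, data, group_col)
                    added = True
                    break
            if added:
                break
        if not added:
            break
    dsep_ok = p > alpha
    if not dsep_ok:
        logger.warning("final model fails the d-separation test (P = %.4f)", p)
    std_coefs: dict[tuple[str, str], float] = {}
    path_p: dict[tuple[str, str], float] = {}
    r2 = {}
    for node in current.endogenous:
        fit = fits[node]
        std = standardize_paths(fit, data)
        for parent in current.parents(node):
            std_coefs[(parent, node)] = std[parent]
            path_p[(parent, node)] = fit.pvalue(parent)
        r2[node] = r2_nakagawa(fit)
    return SemResult(
        dag=current,
        fits=fits,
        std_coefficients=std_coefs,
        path_pvalues=path_p,
        claims=claims,
        fisher_c=c,
        df=df,
        p_value=p,
        dsep_ok=dsep_ok,
        r2=r2,
    )
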