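"""Causal attribution: piecewise structural equation model and
random-forest variable importance.

The piecewise SEM fits one ordinary least-squares regression per
endogenous node of a directed acyclic graph on that node's parents,
reports standardized path coefficients, and judges overall consistency of
the graph with the data by Shipley's test of directed separation: each
independence claim in the basis set (non-adjacent pairs, conditioned on
the union of the pair's parents) contributes a p-value, combined as
Fisher's C = -2 * sum(ln p) ~ chi-square with 2k degrees of freedom.  The
model is accepted when the chi-square p exceeds 0.05.

Variable importance for the season-start response uses a regression
random forest (ntree trees, mtry candidate variables per split) with
permutation importance measured on each tree's out-of-bag samples and
rescaled to percentage shares.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                      _get_n_samples_bootstrap)

from .errors import CollinearityError, ConfigError, GraphError
from .synthetic import CLIMATE_VARS, default_flux_edges


@dataclass
class SEMSpec:
    """Directed acyclic graph of the structural model."""

    nodes: tuple
    edges: tuple

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        self.edges = tuple(tuple(e) for e in self.edges)
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("SEM specification contains a cycle")
        unknown = {u for e in self.edges for u in e} - set(self.nodes)
        if unknown:
            raise GraphError(f"edges reference unknown nodes {sorted(unknown)}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> list:
        return sorted(u for u, v in self.edges if v == node)

    @property
    def endogenous(self) -> list:
        return [n for n in self.nodes if self.parents(n)]

    @property
    def exogenous(self) -> set:
        return {n for n in self.nodes if not self.parents(n)}

    @classmethod
    def default(cls) -> "SEMSpec":
        """The climate -> GPPmax -> SOS graph: every climate driver points
        at both GPPmax and SOS, and GPPmax points at SOS."""
        nodes = (*CLIMATE_VARS, "gppmax", "sos")
        return cls(nodes, tuple(default_flux_edges()))


@dataclass
class SEMResult:
    paths: pd.DataFrame      # source, target, coef, se, p
    r2: dict                 # endogenous node -> R^2
    fisher_c: float
    fisher_df: int
    fisher_p: float
    claims: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def accepted(self) -> bool:
        """Directed-separation test does not reject the graph (or the graph
        is saturated: no testable claims, flagged df = 0)."""
        return self.fisher_df == 0 or self.fisher_p > 0.05

    def coef(self, source: str, target: str) -> float:
        row = self.paths[(self.paths.source == source)
                         & (self.paths.target == target)]
        if row.empty:
            raise KeyError(f"no path {source} -> {target}")
        return float(row.coef.iloc[0])


def basis_set(spec: SEMSpec) -> list:
    """Shipley's basis set of independence claims for the DAG.

    One claim per non-adjacent ordered pair (i, j) with j later in
    topological order, conditioned on the union of both nodes' parents.
    Pairs of two exogenous variables are excluded (their free covariance is
    not a claim of the directed model).
    """
    g = spec.graph()
    order = list(nx.topological_sort(g))
    pos = {n: i for i, n in enumerate(order)}
    adjacent = {frozenset(e) for e in spec.edges}
    claims = []
    exo = spec.exogenous
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if frozenset((a, b)) in adjacent:
                continue
            if a in exo and b in exo:
                continue
            cond = sorted((set(spec.parents(a)) | set(spec.parents(b)))
                          - {a, b})
            claims.append((a, b, tuple(cond)))
    return claims


def _zscore(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise CollinearityError(f"constant columns: {bad}", columns=bad)
    return (frame - frame.mean()) / sd


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS with intercept; returns (beta, se, p, r2) for the slope terms."""
    n = y.size
    Z = np.column_stack([np.ones(n), X])
    k = Z.shape[1]
    if np.linalg.matrix_rank(Z) < k:
        raise CollinearityError("collinear parents in a component regression")
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    p = 2 * sps.t.sf(np.abs(tvals), dof)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    return beta[1:], se[1:], p[1:], r2


def fit_piecewise_sem(data: pd.DataFrame, spec: SEMSpec | None = None,
                      ) -> SEMResult:
    """Fit the piecewise SEM on a site-year table.

    All model variables are z-scored before fitting, so the component OLS
    coefficients are the standardized path coefficients.  With the fully
    saturated default graph the basis set is empty and Fisher's C is 0 on
    0 degrees of freedom (reported, flagged by ``fisher_df == 0``).
    """
    spec = spec or SEMSpec.default()
    missing = set(spec.nodes) - set(data.columns)
    if missing:
        raise ConfigError(f"data lacks SEM variables {sorted(missing)}")
    n = len(data)
    max_parents = max((len(spec.parents(v)) for v in spec.endogenous),
                      default=0)
    if n <= max_parents + 2:
        raise ConfigError("too few rows for the component regressions")
    Z = _zscore(data[list(spec.nodes)].astype(float))
    rows = []
    r2 = {}
    for node in spec.endogenous:
        parents = spec.parents(node)
        beta, se, p, node_r2 = _ols(Z[node].to_numpy(),
                                    Z[parents].to_numpy())
        r2[node] = node_r2
        for src, b, s, pv in zip(parents, beta, se, p):
            rows.append({"source": src, "target": node, "coef": float(b),
                         "se": float(s), "p": float(pv)})
    claims = basis_set(spec)
    claim_rows = []
    logps = []
    for a, b, cond in claims:
        X = Z[[a, *cond]].to_numpy()
        beta, se, p, _ = _ols(Z[b].to_numpy(), X)
        claim_rows.append({"a": a, "b": b, "conditioning": ";".join(cond),
                           "coef": float(beta[0]), "p": float(p[0])})
        logps.append(np.log(max(p[0], 1e-300)))
    k = len(claims)
    fisher_c = float(-2.0 * np.sum(logps)) if k else 0.0
    fisher_df = 2 * k
    fisher_p = float(sps.chi2.sf(fisher_c, fisher_df)) if k else 1.0
    return SEMResult(pd.DataFrame(rows), r2, fisher_c, fisher_df, fisher_p,
                     pd.DataFrame(claim_rows))


def direct_vs_indirect_effects(sem: SEMResult,
                               mediator: str = "gppmax",
                               response: str = "sos") -> pd.DataFrame:
    """Per-driver decomposition: direct path to the response, indirect path
    through the mediator (product of coefficients), and their sum."""
    b_med = sem.coef(mediator, response)
    rows = []
    drivers = sorted(set(sem.paths.source) - {mediator})
    for d in drivers:
        direct = sem.coef(d, response)
        indirect = sem.coef(d, mediator) * b_med
        rows.append({"driver": d, "direct": direct, "indirect": indirect,
                     "total": direct + indirect})
    return pd.DataFrame(rows)


@dataclass
class ImportanceResult:
    importance: pd.Series     # raw mean OOB-MSE increase per predictor
    shares: pd.Series         # percentage shares, sum to 100
    ranking: list
    settings: dict

    def top(self) -> str:
        return self.ranking[0]


def rf_importance(data: pd.DataFrame, response: str = "sos",
                  predictors: tuple | None = None, ntree: int = 1000,
                  mtry: int = 4, seed: int = 0) -> ImportanceResult:
    """Random-forest relative importance of the predictors for the response.

    Importance of a predictor is the mean increase in out-of-bag mean
    squared error across trees when that predictor's values are permuted
    among each tree's out-of-bag samples.  Percentage shares are taken on
    the magnitude of these increases, so that pure-noise responses (whose
    importances fluctuate around zero) yield near-uniform shares instead of
    an ill-posed ratio of clipped values.
    """
    predictors = (tuple(p for p in ("gppmax", *CLIMATE_VARS))
                  if predictors is None else tuple(predictors))
    if mtry > len(predictors):
        raise ConfigError("mtry exceeds the number of predictors")
    sub = data[[response, *predictors]].dropna()
    n = len(sub)
    if n < 30:
        raise ConfigError("need at least 30 complete rows")
    X = sub[list(predictors)].to_numpy()
    y = sub[response].to_numpy()
    forest = RandomForestRegressor(n_estimators=ntree, max_features=mtry,
                                   bootstrap=True, random_state=seed,
                                   n_jobs=1)
    forest.fit(X, y)
    rng = np.random.default_rng(seed)
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    total = np.zeros(len(predictors))
    n_used = 0
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if oob.size < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base_mse = float(np.mean((tree.predict(Xo) - yo) ** 2))
        for j in range(len(predictors)):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            mse = float(np.mean((tree.predict(Xp) - yo) ** 2))
            total[j] += mse - base_mse
        n_used += 1
    imp = pd.Series(total / max(n_used, 1), index=list(predictors))
    mag = imp.abs()
    if mag.sum() <= 0:
        shares = pd.Series(100.0 / len(predictors), index=list(predictors))
    else:
        shares = 100.0 * mag / mag.sum()
    ranking = list(imp.sort_values(ascending=False).index)
    return ImportanceResult(imp, shares, ranking,
                            {"ntree": ntree, "mtry": mtry, "seed": seed,
                             "n": n, "oob_trees": n_used})
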