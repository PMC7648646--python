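"""Piecewise structural equation modelling.

A piecewise SEM estimates a causal hypothesis (a DAG over observed
variables) as a set of local regressions, one per endogenous node, instead
of a single global covariance fit.  Goodness of fit of the graph as a whole
is tested through its d-separation *basis set*: the conditional
independencies the graph implies between non-adjacent variable pairs.  Each
claim is tested by regressing one node of the pair on the other plus the
union of both nodes' parents; the claim p-values are combined into Fisher's

    C = -2 * sum(log(p_i)),

which is chi-square distributed with 2k degrees of freedom (k claims) when
the hypothesized graph generated the data.  Large C signals missing paths.

Model comparison uses the C-based information criteria

    BIC = C + K * ln(n)        CIC = C + 2 * K

with K the total number of estimated parameters across component
regressions and n the number of observations.

Component regressions are ordinary least squares, or random-intercept
mixed models when plots are spatially clustered (inventory tracks/grids).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DagSpec",
    "EquationSpec",
    "ComponentFit",
    "IndependenceClaim",
    "PsemFit",
    "basis_set",
    "test_claim",
    "fisher_c",
    "information_criteria",
    "fit_psem",
    "load_model",
]

OLS = "ols"
RANDOM_INTERCEPT = "random_intercept"

# Smallest positive double; p-values of exactly zero are floored here so
# that log-p sums stay finite.  A flooring is reported as a warning.
P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class DagSpec:
    """A directed acyclic graph over named variables.

    ``nodes`` fixes the declaration order used for deterministic claim
    ordering and tie-breaking.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        seen = set()
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) references undeclared node")
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u}, {v})")
            seen.add((u, v))
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("graph contains a directed cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(u for u, v in self.edges if v == node)

    @property
    def exogenous(self) -> tuple[str, ...]:
        with_parents = {v for _, v in self.edges}
        return tuple(n for n in self.nodes if n not in with_parents)

    @property
    def endogenous(self) -> tuple[str, ...]:
        with_parents = {v for _, v in self.edges}
        return tuple(n for n in self.nodes if n in with_parents)

    def adjacent(self, x: str, y: str) -> bool:
        return (x, y) in self.edges or (y, x) in self.edges


@dataclass(frozen=True)
class EquationSpec:
    """One component regression: ``response ~ predictors``."""

    response: str
    predictors: tuple[str, ...]
    estimator: str = OLS
    grouping: str | None = None

    def __post_init__(self):
        if self.estimator not in (OLS, RANDOM_INTERCEPT):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if (self.estimator == RANDOM_INTERCEPT) != (self.grouping is not None):
            raise ValueError("grouping must be given iff estimator is random_intercept")


@dataclass
class ComponentFit:
    """Estimates for one component regression."""

    response: str
    predictors: tuple[str, ...]
    estimator: str
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    residual_variance: float
    n: int
    k: int
    loglik: float
    random_effect_variance: float | None = None

    @property
    def bic(self) -> float:
        """Likelihood-based BIC of this component alone."""
        return self.k_loglik * math.log(self.n) - 2.0 * self.loglik

    @property
    def k_loglik(self) -> int:
        # parameters entering the likelihood: same count as k
        return self.k


@dataclass
class IndependenceClaim:
    """One basis-set claim: X independent of Y given the conditioning set."""

    x: str
    y: str
    conditioning_set: tuple[str, ...]
    response_node: str
    p_value: float | None = None

    @property
    def partner(self) -> str:
        return self.y if self.response_node == self.x else self.x

    def label(self) -> str:
        cond = ", ".join(self.conditioning_set) or "∅"
        return f"{self.x} ⊥ {self.y} | {{{cond}}}"


@dataclass
class PsemFit:
    """A fitted piecewise SEM."""

    dag: DagSpec
    components: list[ComponentFit]
    claims: list[IndependenceClaim]
    fisher_c: float
    df: int
    c_p_value: float
    K: int
    n: int
    bic: float
    cic: float
    bic_components: float  # sum of component likelihood BICs (alternative criterion)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.dag.nodes),
            "edges": [list(e) for e in self.dag.edges],
            "components": [
                {
                    "response": c.response,
                    "predictors": list(c.predictors),
                    "estimator": c.estimator,
                    "coefficients": c.coefficients,
                    "std_errors": c.std_errors,
                    "p_values": c.p_values,
                    "residual_variance": c.residual_variance,
                    "random_effect_variance": c.random_effect_variance,
                    "n": c.n,
                    "k": c.k,
                }
                for c in self.components
            ],
            "claims": [
                {
                    "x": cl.x,
                    "y": cl.y,
                    "conditioning_set": list(cl.conditioning_set),
                    "response_node": cl.response_node,
                    "p_value": cl.p_value,
                }
                for cl in self.claims
            ],
            "fisher_c": self.fisher_c,
            "df": self.df,
            "c_p_value": self.c_p_value,
            "K": self.K,
            "n": self.n,
            "bic": self.bic,
            "cic": self.cic,
            "bic_components": self.bic_components,
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def load_model(path) -> tuple[DagSpec, list[EquationSpec]]:
    """Read a DAG and its component equations from a YAML (or JSON) file.

    Expected keys: ``nodes`` (list), ``edges`` (list of [cause, effect]
    pairs) and optionally ``estimator`` (``ols`` | ``random_intercept``)
    and ``grouping``; equations are derived from the DAG parents, one per
    endogenous node.
    """
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    for key in ("nodes", "edges"):
        if key not in payload:
            raise ValueError(f"model file {path} missing {key!r}")
    dag = DagSpec(
        nodes=tuple(payload["nodes"]),
        edges=tuple((str(u), str(v)) for u, v in payload["edges"]),
    )
    estimator = payload.get("estimator", OLS)
    grouping = payload.get("grouping")
    equations = [
        EquationSpec(node, dag.parents(node), estimator=estimator, grouping=grouping)
        for node in dag.endogenous
    ]
    return dag, equations


# ---------------------------------------------------------------------------
# basis set


def basis_set(dag: DagSpec) -> list[IndependenceClaim]:
    """The d-separation basis set of a DAG.

    One claim per non-adjacent node pair, conditioned on the union of both
    nodes' parents.  Pairs in which *both* nodes are exogenous are excluded
    (their association is treated as a free covariance, as is conventional
    for piecewise SEM).  The regression direction within a claim is chosen
    deterministically: the causally downstream node responds if a directed
    path orders the pair; otherwise the node with more parents; remaining
    ties go to the node declared later.
    """
    g = dag.graph()
    order = {node: i for i, node in enumerate(dag.nodes)}
    exogenous = set(dag.exogenous)
    claims: list[IndependenceClaim] = []
    for i, x in enumerate(dag.nodes):
        for y in dag.nodes[i + 1 :]:
            if dag.adjacent(x, y):
                continue
            if x in exogenous and y in exogenous:
                continue
            cond = sorted(
                (set(dag.parents(x)) | set(dag.parents(y))) - {x, y}, key=order.__getitem__
            )
            if nx.has_path(g, x, y):
                response = y
            elif nx.has_path(g, y, x):
                response = x
            else:
                px, py = len(dag.parents(x)), len(dag.parents(y))
                if px != py:
                    response = x if px > py else y
                else:
                    response = y  # declared later
            claims.append(
                IndependenceClaim(x=x, y=y, conditioning_set=tuple(cond), response_node=response)
            )
    return claims


# ---------------------------------------------------------------------------
# component fitting


def _fit_regression(
    response: str,
    predictors: tuple[str, ...],
    data: pd.DataFrame,
    estimator: str,
    grouping: str | None,
):
    """Fit one regression; returns (result, names) with names excluding the
    intercept/grouping bookkeeping."""
    y = data[response].to_numpy(dtype=float)
    X = data[list(predictors)].to_numpy(dtype=float) if predictors else np.empty((len(y), 0))
    X = sm.add_constant(X, has_constant="add")
    names = ["intercept", *predictors]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {response} ~ {' + '.join(predictors) or '1'}: "
            "check for collinear or constant predictors"
        )
    if estimator == OLS:
        res = sm.OLS(y, X).fit()
    else:
        groups = data[grouping].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    return res, names


def _component_from_result(res, names, response, predictors, estimator) -> ComponentFit:
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    coefficients = dict(zip(names, params[: len(names)]))
    std_errors = dict(zip(names, bse[: len(names)]))
    p_values = dict(zip(names, pvals[: len(names)]))
    if estimator == OLS:
        resid_var = float(res.scale)
        re_var = None
        k = len(names) + 1
        n = int(res.nobs)
        loglik = float(res.llf)
    else:
        resid_var = float(res.scale)
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        k = len(names) + 2  # fixed effects + residual var + random-intercept var
        n = int(res.nobs)
        loglik = float(res.llf)
    return ComponentFit(
        response=response,
        predictors=tuple(predictors),
        estimator=estimator,
        coefficients=coefficients,
        std_errors=std_errors,
        p_values=p_values,
        residual_variance=resid_var,
        n=n,
        k=k,
        loglik=loglik,
        random_effect_variance=re_var,
    )


def test_claim(
    claim: IndependenceClaim,
    data: pd.DataFrame,
    estimator: str = OLS,
    grouping: str | None = None,
) -> float:
    """Test one independence claim; two-sided p-value of the partner's
    coefficient in ``response ~ conditioning_set + partner``."""
    predictors = (*claim.conditioning_set, claim.partner)
    n = len(data)
    if n <= len(claim.conditioning_set) + 2:
        raise ValueError(f"too few observations ({n}) to test claim {claim.label()}")
    res, names = _fit_regression(claim.response_node, predictors, data, estimator, grouping)
    pvals = dict(zip(names, np.asarray(res.pvalues, dtype=float)[: len(names)]))
    return float(pvals[claim.partner])


# ---------------------------------------------------------------------------
# Fisher's C and information criteria


def fisher_c(p_values) -> tuple[float, int, float]:
    """Combine claim p-values into (C, df, p).

    C = -2 Σ ln p_i, chi-square with df = 2 * (number of claims) under the
    hypothesized graph.  An empty claim list gives (0, 0, 1).  Non-positive
    p-values are floored at the smallest positive double, with a warning.
    """
    p_values = list(p_values)
    if not p_values:
        return 0.0, 0, 1.0
    floored = []
    for p in p_values:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value out of range: {p}")
        if p <= 0:
            warnings.warn(f"p-value of 0 floored at {P_FLOOR:g} in Fisher's C", RuntimeWarning)
            p = P_FLOOR
        floored.append(p)
    c = -2.0 * float(np.sum(np.log(floored)))
    df = 2 * len(floored)
    p = float(stats.chi2.sf(c, df))
    return c, df, p


def information_criteria(c: float, k: int, n: int) -> tuple[float, float]:
    """C-based criteria: BIC = C + K ln n and CIC = C + 2K."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    if c < 0:
        raise ValueError("Fisher's C must be >= 0")
    return c + k * math.log(n), c + 2.0 * k


# ---------------------------------------------------------------------------
# the full piecewise fit


def fit_psem(dag: DagSpec, equations: list[EquationSpec], data: pd.DataFrame) -> PsemFit:
    """Fit every component regression, test the basis set, and assemble the
    Fisher's C test and information criteria.

    Every endogenous node must be covered by exactly one equation whose
    predictors are its DAG parents.  All fits use the same complete-case
    rows over the DAG's variables so criteria are comparable.
    """
    responses = [eq.response for eq in equations]
    if sorted(responses) != sorted(dag.endogenous):
        raise ValueError(
            f"equations must cover endogenous nodes {sorted(dag.endogenous)} exactly once, "
            f"got responses {sorted(responses)}"
        )
    for eq in equations:
        if set(eq.predictors) != set(dag.parents(eq.response)):
            raise ValueError(
                f"equation for {eq.response} has predictors {sorted(eq.predictors)} "
                f"but DAG parents are {sorted(dag.parents(eq.response))}"
            )

    missing_cols = [v for v in dag.nodes if v not in data.columns]
    if missing_cols:
        raise ValueError(f"data missing model variables: {missing_cols}")
    groupings = {eq.grouping for eq in equations if eq.grouping}
    used_cols = list(dag.nodes) + sorted(groupings)
    frame = data[used_cols].dropna()
    n = len(frame)

    fit_warnings: list[str] = []
    components = []
    for eq in equations:
        res, names = _fit_regression(eq.response, eq.predictors, frame, eq.estimator, eq.grouping)
        components.append(
            _component_from_result(res, names, eq.response, eq.predictors, eq.estimator)
        )
    if len({c.n for c in components}) != 1:
        raise ValueError("component sample sizes differ; fits must share observations")

    clustered = any(eq.estimator == RANDOM_INTERCEPT for eq in equations)
    claim_estimator = RANDOM_INTERCEPT if clustered else OLS
    claim_grouping = next(iter(groupings)) if clustered else None

    claims = basis_set(dag)
    for cl in claims:
        cl.p_value = test_claim(cl, frame, claim_estimator, claim_grouping)
        if cl.p_value <= 0:
            fit_warnings.append(f"claim {cl.label()}: p-value floored at {P_FLOOR:g}")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        c, df, c_p = fisher_c([cl.p_value for cl in claims])
        fit_warnings.extend(str(w.message) for w in caught)

    K = sum(comp.k for comp in components)
    bic, cic = information_criteria(c, K, n)
    bic_components = float(sum(comp.bic for comp in components))

    return PsemFit(
        dag=dag,
        components=components,
        claims=claims,
        fisher_c=c,
        df=df,
        c_p_value=c_p,
        K=K,
        n=n,
        bic=bic,
        cic=cic,
        bic_components=bic_components,
        warnings=fit_warnings,
    )
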