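"""Standardized path coefficients and effect decompositions.

After the d-sep fit test accepts a path structure, each endogenous node's
structural equation is parameterized by the appropriate mixed model on
standardized data, so every edge carries a standardized partial regression
coefficient.  Indirect effects are products of the linear coefficients
along directed paths; the total effect of a source on a target is the
direct coefficient (zero if no direct edge) plus the sum of all indirect
products.  Quadratic edges contribute their linear coefficient to
products; the squared-term contribution is carried alongside as a
separately labelled component, never multiplied in.  Categorical control
edges (e.g. year) are excluded from product paths: a standardized product
through a dummy contrast is not interpretable as a mediated effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .dag import CATEGORICAL, PathDAG
from .dsep import _response_family, resolve_table
from .mixedfit import (
    CategoricalTerm,
    CoefficientEstimate,
    FitResult,
    InteractionTerm,
    LinearTerm,
    ModelSpec,
    QuadraticTerm,
    fit_mixed,
)

ALPHA = 0.05


@dataclass
class EdgeCoefficient:
    source: str
    target: str
    form: str
    linear: CoefficientEstimate | None      # None for pure categorical edges
    quadratic: CoefficientEstimate | None = None
    dummies: list[CoefficientEstimate] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        if self.linear is not None:
            return self.linear.p < ALPHA
        return any(c.p < ALPHA for c in self.dummies)


class PathCoefficients:
    """Map edge (source, target) → fitted standardized coefficients."""

    def __init__(self):
        self._edges: dict[tuple[str, str], EdgeCoefficient] = {}
        self.fits: dict[str, FitResult] = {}
        self.errors: dict[str, Exception] = {}

    def add(self, coef: EdgeCoefficient):
        self._edges[(coef.source, coef.target)] = coef

    def get(self, source: str, target: str) -> EdgeCoefficient:
        try:
            return self._edges[(source, target)]
        except KeyError:
            raise KeyError(f"no coefficient for edge {source!r} -> {target!r}") from None

    def __contains__(self, pair):
        return tuple(pair) in self._edges

    def items(self):
        return self._edges.items()

    @classmethod
    def from_values(cls, values: dict[tuple[str, str], float] | pd.DataFrame):
        """Build from plain linear coefficient values (e.g. a published table)."""
        out = cls()
        if isinstance(values, pd.DataFrame):
            values = {
                (str(r["source"]), str(r["target"])): float(r["beta"])
                for _, r in values.iterrows()
            }
        for (src, tgt), beta in values.items():
            out.add(
                EdgeCoefficient(
                    source=src, target=tgt, form="linear",
                    linear=CoefficientEstimate(src, float(beta), 0.0, 0.0, 0.0, 0.0),
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (src, tgt), ec in sorted(self._edges.items()):
            if ec.linear is not None:
                rows.append(
                    {"source": src, "target": tgt, "component": "linear",
                     "beta": ec.linear.beta, "se": ec.linear.se, "df": ec.linear.df,
                     "stat": ec.linear.stat, "p": ec.linear.p}
                )
            if ec.quadratic is not None:
                rows.append(
                    {"source": src, "target": tgt, "component": "quadratic",
                     "beta": ec.quadratic.beta, "se": ec.quadratic.se,
                     "df": ec.quadratic.df, "stat": ec.quadratic.stat,
                     "p": ec.quadratic.p}
                )
            for c in ec.dummies:
                rows.append(
                    {"source": src, "target": tgt, "component": c.term,
                     "beta": c.beta, "se": c.se, "df": c.df, "stat": c.stat, "p": c.p}
                )
        return pd.DataFrame(rows)


def structural_model(dag: PathDAG, response: str) -> ModelSpec:
    """The structural equation for one endogenous node."""
    node = dag.node(response)
    terms = []
    for parent in sorted(dag.parents(response)):
        pnode = dag.node(parent)
        edge = dag.direct_edge(parent, response)
        if pnode.family == CATEGORICAL:
            terms.append(CategoricalTerm(parent))
        elif edge.form == "quadratic":
            terms.append(QuadraticTerm(parent))
        else:
            terms.append(LinearTerm(parent))
    for edge in dag.interaction_edges(response):
        terms.append(InteractionTerm(edge.source, edge.partner))
    return ModelSpec(
        response=response, fixed_terms=terms,
        family=_response_family(dag, response), random_nesting=node.grouping,
    )


def fit_structural_equations(dag: PathDAG, table) -> PathCoefficients:
    """Fit one mixed model per endogenous node; collect coefficients per edge.

    Data should already be standardized so the coefficients are on the
    standardized scale.  Fit failures on one equation are recorded and do
    not stop the others.
    """
    dag.require_valid()
    out = PathCoefficients()
    for name in dag.topological_order():
        parents = dag.parents(name)
        if not parents:
            continue
        spec = structural_model(dag, name)
        try:
            fit = fit_mixed(spec, resolve_table(dag, name, table))
        except Exception as err:  # propagate per-node, continue others
            out.errors[name] = err
            warnings.warn(f"structural equation for {name!r} failed: {err}", stacklevel=2)
            continue
        out.fits[name] = fit
        for parent in sorted(parents):
            pnode = dag.node(parent)
            edge = dag.direct_edge(parent, name)
            if pnode.family == CATEGORICAL:
                dummies = [
                    c for c in fit.coefficients if c.term.startswith(f"{parent}[")
                ]
                out.add(EdgeCoefficient(parent, name, "categorical", None, None, dummies))
            elif edge.form == "quadratic":
                out.add(
                    EdgeCoefficient(
                        parent, name, "quadratic",
                        linear=fit.coefficient(parent),
                        quadratic=fit.coefficient(f"{parent}^2"),
                    )
                )
            else:
                out.add(EdgeCoefficient(parent, name, "linear", fit.coefficient(parent)))
        for edge in dag.interaction_edges(name):
            label = f"{edge.source}:{edge.partner}"
            out.add(
                EdgeCoefficient(
                    f"{edge.source}:{edge.partner}", name, "interaction",
                    linear=fit.coefficient(label),
                )
            )
    return out


def enumerate_paths(dag: PathDAG, source: str, target: str) -> list[list[str]]:
    """All simple directed paths source → target, lexicographically ordered.

    Paths passing through categorical (control) nodes are excluded.
    """
    dag.node(source)
    dag.node(target)
    g = dag.to_networkx()
    drop = {
        n for n, node in dag.nodes.items()
        if node.family == CATEGORICAL and n not in (source, target)
    }
    g.remove_nodes_from(drop)
    if source not in g or target not in g:
        return []
    paths = [list(p) for p in nx.all_simple_paths(g, source, target)]
    paths.sort()
    return paths


@dataclass
class IndirectComponent:
    path: list[str]
    product: float                      # product of linear coefficients
    quadratic_note: str | None = None   # labelled squared-term component
    all_significant: bool = True


@dataclass
class EffectDecomposition:
    source: str
    target: str
    direct: float
    direct_significant: bool | None
    indirect_paths: list[IndirectComponent]
    total: float

    def rounded(self, ndigits: int = 2):
        return {
            "direct": round(self.direct, ndigits),
            "indirect": [
                (" -> ".join(c.path), round(c.product, ndigits))
                for c in self.indirect_paths
            ],
            "total": round(self.total, ndigits),
        }


def indirect_effect(path: list[str], coefficients: PathCoefficients) -> IndirectComponent:
    """Product of linear coefficients along a directed path of >= 2 edges.

    Squared-term coefficients of quadratic edges are reported as a
    labelled side note, never folded into the product.
    """
    if len(path) < 3:
        raise ValueError("an indirect path needs at least two edges")
    product = 1.0
    quad_notes = []
    all_sig = True
    for a, b in zip(path[:-1], path[1:]):
        try:
            ec = coefficients.get(a, b)
        except KeyError:
            raise KeyError(f"missing coefficient for edge {a!r} -> {b!r}") from None
        if ec.linear is None:
            raise ValueError(f"edge {a!r} -> {b!r} has no linear coefficient")
        product *= ec.linear.beta
        all_sig = all_sig and ec.significant
        if ec.quadratic is not None:
            quad_notes.append(f"{a}^2 -> {b}: {ec.quadratic.beta:+.2f}")
    return IndirectComponent(
        path=list(path), product=product,
        quadratic_note="; ".join(quad_notes) or None, all_significant=all_sig,
    )


def total_effect(
    source: str,
    target: str,
    dag: PathDAG,
    coefficients: PathCoefficients,
    significant_only: bool = False,
) -> EffectDecomposition:
    """Direct coefficient plus the sum of all indirect path products."""
    direct = 0.0
    direct_sig = None
    if dag.direct_edge(source, target) is not None:
        ec = coefficients.get(source, target)
        if ec.linear is None:
            raise ValueError(f"direct edge {source!r} -> {target!r} is categorical")
        direct_sig = ec.significant
        if not significant_only or direct_sig:
            direct = ec.linear.beta
    components = []
    for path in enumerate_paths(dag, source, target):
        if len(path) < 3:
            continue
        comp = indirect_effect(path, coefficients)
        if significant_only and not comp.all_significant:
            continue
        components.append(comp)
    total = direct + sum(c.product for c in components)
    return EffectDecomposition(
        source=source, target=target, direct=direct,
        direct_significant=direct_sig, indirect_paths=components, total=total,
    )
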