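"""Acyclic path-model representation and d-separation structure.

A path model is a directed acyclic graph whose nodes are study variables
(each with a response family and a nesting of random intercepts) and whose
edges are the hypothesized causal links.  Model fit in the piecewise
(multi-level) path framework is evaluated through the *minimum basis set*:
one conditional-independence claim per non-adjacent pair of variables, the
conditioning set being the union of the two variables' parents.  Each claim
is later turned into a mixed-model regression test and the resulting
p-values combined into Fisher's C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import yaml

GAUSSIAN = "gaussian"
BINOMIAL = "binomial"
ORDINAL = "ordinal-as-numeric"
CATEGORICAL = "categorical-exogenous"

_FAMILIES = {GAUSSIAN, BINOMIAL, ORDINAL, CATEGORICAL}
_FORMS = {"linear", "quadratic", "interaction"}

# accepted spellings in YAML configs
_FAMILY_ALIASES = {
    "gaussian": GAUSSIAN,
    "normal": GAUSSIAN,
    "binomial": BINOMIAL,
    "binomial-logit": BINOMIAL,
    "ordinal": ORDINAL,
    "ordinal-as-numeric": ORDINAL,
    "categorical": CATEGORICAL,
    "categorical-exogenous": CATEGORICAL,
}
_FORM_ALIASES = {
    "linear": "linear",
    "quadratic": "quadratic",
    "interaction": "interaction",
    "residualized-interaction": "interaction",
}


class DagError(ValueError):
    """Structural problem with a path model."""


class CycleError(DagError):
    """The directed graph contains a cycle."""

    def __init__(self, cycle_nodes):
        self.cycle_nodes = list(cycle_nodes)
        super().__init__(f"cycle detected among nodes: {sorted(self.cycle_nodes)}")


@dataclass(frozen=True)
class PathNode:
    """A study variable.

    ``grouping`` lists the random-intercept nesting for the variable's
    structural equation, outermost level first (e.g. ``("nest",
    "individual")`` for repeated captures of juveniles within natal nests).
    """

    name: str
    family: str = GAUSSIAN
    grouping: tuple[str, ...] = ()
    table: str | None = None  # which study table the variable lives in

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise DagError(f"unknown family {self.family!r} for node {self.name!r}")
        object.__setattr__(self, "grouping", tuple(self.grouping))


@dataclass(frozen=True)
class PathEdge:
    """A directed causal link.

    Forms:

    * ``linear`` — one fixed-effect term (source).
    * ``quadratic`` — linear and squared term entered together.
    * ``interaction`` — a residualized two-way interaction between
      ``source`` and ``partner``; both must already be parents of the
      target through their own edges.
    """

    source: str
    target: str
    form: str = "linear"
    partner: str | None = None

    def __post_init__(self):
        if self.form not in _FORMS:
            raise DagError(f"unknown edge form {self.form!r}")
        if self.source == self.target:
            raise DagError(f"self-loop on {self.source!r}")
        if self.form == "interaction":
            if not self.partner:
                raise DagError("interaction edge requires a partner variable")
            if self.partner in (self.source, self.target):
                raise DagError("interaction partner must differ from source and target")
        elif self.partner is not None:
            raise DagError("partner only meaningful for interaction edges")

    @property
    def key(self):
        if self.form == "interaction":
            pair = tuple(sorted((self.source, self.partner)))
            return ("interaction", pair, self.target)
        return ("direct", self.source, self.target)


@dataclass(frozen=True)
class IndependenceClaim:
    """A d-separation claim ``x ⟂ y | conditioning``.

    ``response`` is the member of the pair that is modelled as the response
    when the claim is turned into a regression test (the later of the two
    in topological order).
    """

    x: str
    y: str
    conditioning: frozenset[str]
    response: str

    def __post_init__(self):
        object.__setattr__(self, "conditioning", frozenset(self.conditioning))
        if self.response not in (self.x, self.y):
            raise DagError("response must be one of the claim's pair")

    @property
    def predictor(self) -> str:
        """The member of the pair whose coefficient is tested."""
        return self.y if self.response == self.x else self.x

    def describe(self) -> str:
        cond = ", ".join(sorted(self.conditioning)) or "∅"
        return f"{self.x} ⟂ {self.y} | {{{cond}}}"


@dataclass
class ValidationReport:
    ok: bool
    order: list[str] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)


class PathDAG:
    """A validated acyclic path model."""

    def __init__(self, nodes, edges, free_covariance=()):
        self.nodes: dict[str, PathNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise DagError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node
        self.edges: list[PathEdge] = []
        seen = set()
        for edge in edges:
            if edge.key in seen:
                raise DagError(f"duplicate edge {edge.source!r}->{edge.target!r}")
            seen.add(edge.key)
            self.edges.append(edge)
        self.free_covariance = {frozenset(p) for p in free_covariance}
        for pair in self.free_covariance:
            if len(pair) != 2:
                raise DagError("free_covariance entries must be pairs")

    # -- structure ---------------------------------------------------------

    def node(self, name: str) -> PathNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise DagError(f"unknown node {name!r}") from None

    def parents(self, name: str) -> set[str]:
        """Parents through direct (linear/quadratic) edges."""
        self.node(name)
        return {
            e.source for e in self.edges if e.target == name and e.form != "interaction"
        }

    def direct_edge(self, source: str, target: str) -> PathEdge | None:
        for e in self.edges:
            if e.form != "interaction" and e.source == source and e.target == target:
                return e
        return None

    def interaction_edges(self, target: str) -> list[PathEdge]:
        return [e for e in self.edges if e.target == target and e.form == "interaction"]

    def adjacent(self, a: str, b: str) -> bool:
        """Whether any edge (any form) links a and b directly."""
        for e in self.edges:
            ends = {e.source, e.target}
            if e.form == "interaction":
                ends = {e.source, e.partner, e.target}
            if a in ends and b in ends and {a, b} <= ends:
                # interaction partners are not adjacent to each other through
                # the interaction edge alone; they are through their own edges
                if e.form == "interaction" and {a, b} == {e.source, e.partner}:
                    continue
                return True
        return False

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.form != "interaction":
                g.add_edge(e.source, e.target)
        return g

    def topological_order(self) -> list[str]:
        """Deterministic topological order.

        Ties are broken by random-effect nesting depth, then name, so that
        finer-grained (observation-level) variables sort after the
        coarser-level variables they are measured alongside; the claim
        response (the later member of a pair) then sits at the level where
        the repeated measurements live.
        """
        g = self.to_networkx()
        return list(
            nx.lexicographical_topological_sort(
                g, key=lambda n: (len(self.nodes[n].grouping), n)
            )
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> ValidationReport:
        violations = []
        for e in self.edges:
            refs = [e.source, e.target] + ([e.partner] if e.partner else [])
            for name in refs:
                if name not in self.nodes:
                    violations.append(f"dangling endpoint: edge references undeclared node {name!r}")
            if e.form != "interaction" and e.target in self.nodes:
                if self.nodes[e.target].family == CATEGORICAL:
                    violations.append(
                        f"categorical-exogenous node {e.target!r} may not be a response"
                    )
        for e in self.edges:
            if e.form == "interaction" and all(
                n in self.nodes for n in (e.source, e.partner, e.target)
            ):
                for parent in (e.source, e.partner):
                    if self.direct_edge(parent, e.target) is None:
                        violations.append(
                            f"interaction edge on {e.target!r} references {parent!r}, "
                            "which is not a parent through its own edge"
                        )
        if violations:
            return ValidationReport(False, [], violations)
        g = self.to_networkx()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            nodes_in_cycle = sorted({u for u, v in cycle} | {v for u, v in cycle})
            return ValidationReport(
                False, [], [f"cycle detected among nodes: {nodes_in_cycle}"]
            )
        return ValidationReport(True, self.topological_order(), [])

    def require_valid(self):
        report = self.validate()
        if not report.ok:
            for v in report.violations:
                if v.startswith("cycle"):
                    g = self.to_networkx()
                    cyc = nx.find_cycle(g)
                    raise CycleError({u for u, _ in cyc})
            raise DagError("; ".join(report.violations))
        return report


def validate_dag(dag: PathDAG) -> ValidationReport:
    return dag.validate()


def d_separated(dag: PathDAG, x: str, y: str, z) -> bool:
    """d-separation of x and y given the set z.

    True iff every undirected path between x and y is blocked: a chain or
    fork is blocked when its middle node is conditioned on, a collider is
    blocked unless it or one of its descendants is conditioned on.
    """
    z = set(z)
    for name in {x, y} | z:
        dag.node(name)
    if x == y:
        raise DagError("x and y must differ")
    if x in z or y in z:
        raise DagError("conditioning set must exclude x and y")
    return nx.is_d_separator(dag.to_networkx(), {x}, {y}, z)


def basis_set(dag: PathDAG) -> list[IndependenceClaim]:
    """Minimum basis set of independence claims (union-of-parents rule).

    One claim per unordered non-adjacent pair, conditioned on the union of
    the parents of both members; pairs listed under ``free_covariance`` are
    exempt.  Deterministically ordered by topological position of the
    response, then lexicographically.
    """
    dag.require_valid()
    order = dag.topological_order()
    pos = {name: i for i, name in enumerate(order)}
    claims = []
    names = sorted(dag.nodes)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if dag.adjacent(a, b):
                continue
            if frozenset((a, b)) in dag.free_covariance:
                continue
            cond = (dag.parents(a) | dag.parents(b)) - {a, b}
            later = a if pos[a] > pos[b] else b
            other = b if later == a else a
            if dag.nodes[later].family == CATEGORICAL:
                later, other = other, later
            if dag.nodes[later].family == CATEGORICAL:
                raise DagError(
                    f"claim between two categorical-exogenous nodes ({a!r}, {b!r}) "
                    "cannot be tested; declare it under free_covariance"
                )
            claims.append(
                IndependenceClaim(x=other, y=later, conditioning=cond, response=later)
            )
    claims.sort(key=lambda c: (pos[c.response], c.x, c.y))
    return claims


# -- YAML configuration ----------------------------------------------------


def dag_from_dict(cfg: dict) -> PathDAG:
    nodes = []
    for spec in cfg.get("nodes", []):
        family = _FAMILY_ALIASES.get(str(spec.get("family", "gaussian")).lower())
        if family is None:
            raise DagError(f"unknown family {spec.get('family')!r}")
        nodes.append(
            PathNode(
                name=str(spec["name"]),
                family=family,
                grouping=tuple(spec.get("grouping") or ()),
                table=spec.get("table"),
            )
        )
    edges = []
    for spec in cfg.get("edges", []):
        form = _FORM_ALIASES.get(str(spec.get("form", "linear")).lower())
        if form is None:
            raise DagError(f"unknown edge form {spec.get('form')!r}")
        edges.append(
            PathEdge(
                source=str(spec["from"]),
                target=str(spec["to"]),
                form=form,
                partner=spec.get("with"),
            )
        )
    free = [tuple(p) for p in cfg.get("free_covariance", [])]
    dag = PathDAG(nodes, edges, free_covariance=free)
    dag.require_valid()
    return dag


def dag_to_dict(dag: PathDAG) -> dict:
    nodes = []
    for node in dag.nodes.values():
        entry = {"name": node.name, "family": node.family}
        if node.grouping:
            entry["grouping"] = list(node.grouping)
        if node.table:
            entry["table"] = node.table
        nodes.append(entry)
    edges = []
    for e in dag.edges:
        entry = {"from": e.source, "to": e.target, "form": e.form}
        if e.partner:
            entry["with"] = e.partner
        edges.append(entry)
    out = {"nodes": nodes, "edges": edges}
    if dag.free_covariance:
        out["free_covariance"] = [sorted(p) for p in sorted(dag.free_covariance, key=sorted)]
    return out


def load_model(path) -> PathDAG:
    """Load a path model from a YAML file (``nodes:``/``edges:`` lists)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return dag_from_dict(cfg.get("model", cfg))


def save_model(dag: PathDAG, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dag_to_dict(dag), fh, sort_keys=False)


def default_model() -> PathDAG:
    """The shipped sparrow path model (packaged YAML)."""
    from importlib import resources

    with resources.files("gmlpath.config").joinpath("sparrow_model.yaml").open() as fh:
        return dag_from_dict(yaml.safe_load(fh))
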