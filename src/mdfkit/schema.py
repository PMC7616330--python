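"""Document object model for serialized computational-graph models.

A :class:`Model` holds one or more :class:`Graph` objects.  A graph is a
set of :class:`Node` objects — each bundling input ports, parameters,
function calls and output ports — connected by directed :class:`Edge`
objects from output ports to input ports.  A node may instead wrap a
subgraph, giving hierarchically structured models; cycles at the node level
are legal (they model recurrent dynamics) and are flagged informationally
by validation, which then requires initial values on the ports that feed
them.

``validate_model`` is report-based: it never raises, it returns every
violation it finds, and an empty report is the definition of
well-formedness.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from . import expressions as xp
from .functions import FunctionRegistry, standard_registry

__all__ = [
    "Model", "Graph", "Node", "InputPort", "OutputPort", "Parameter",
    "FunctionCall", "Edge", "ValidationIssue", "ValidationReport",
    "validate_model", "detect_cycles", "flatten_hierarchy", "FlattenError",
]

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")
# Dots are reserved for hierarchy namespacing: a dotted id is a sequence of
# plain identifiers produced by flattening.
_DOTTED_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*(\.[A-Za-z_][A-Za-z0-9_]*)*\Z")


def is_identifier(s: str, *, dotted: bool = False) -> bool:
    if not isinstance(s, str):
        return False
    return bool((_DOTTED_RE if dotted else _IDENT_RE).match(s))


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(eq=False)
class InputPort:
    id: str
    shape: Optional[tuple[int, ...]] = None
    reduce: str = "error"  # "error" | "sum" for multiple incoming edges
    metadata: dict = field(default_factory=dict)


@dataclass(eq=False)
class OutputPort:
    id: str
    value: str = ""  # expression over node-local ids
    default_initial_value: object | None = None  # required if feeding a cycle
    metadata: dict = field(default_factory=dict)


@dataclass(eq=False)
class Parameter:
    """A node parameter: a constant, a computed value, or a state variable.

    A parameter is *stateful* when it carries value across executions:
    either it has a ``time_derivative`` (an ODE state advanced by the
    engine's integrator) or its value expression references its own id
    (an update rule such as ``count + 1``).  Stateful parameters must
    declare ``default_initial_value``.
    """

    id: str
    value: object | None = None  # number, array (nested lists), or expression string
    default_initial_value: object | None = None
    time_derivative: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    @property
    def stateful(self) -> bool:
        if self.time_derivative is not None:
            return True
        if isinstance(self.value, str):
            try:
                return self.id in xp.free_identifiers(self.value)
            except xp.ExpressionSyntaxError:
                return False
        return False


@dataclass(eq=False)
class FunctionCall:
    id: str
    function: str  # name resolving in the function ontology
    args: dict[str, object] = field(default_factory=dict)  # param name -> expression/number
    metadata: dict = field(default_factory=dict)


@dataclass(eq=False)
class Edge:
    id: str
    sender: str
    sender_port: str
    receiver: str
    receiver_port: str
    weight: float = 1.0
    metadata: dict = field(default_factory=dict)


@dataclass(eq=False)
class Node:
    id: str
    input_ports: list[InputPort] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    functions: list[FunctionCall] = field(default_factory=list)
    output_ports: list[OutputPort] = field(default_factory=list)
    subgraph: Optional["Graph"] = None
    metadata: dict = field(default_factory=dict)

    def get_parameter(self, pid: str) -> Parameter:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def local_ids(self) -> list[str]:
        out = [p.id for p in self.input_ports]
        out += [p.id for p in self.parameters]
        out += [f.id for f in self.functions]
        return out


@dataclass(eq=False)
class Graph:
    id: str
    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    conditions: object | None = None  # ConditionSet; typed in scheduler module
    metadata: dict = field(default_factory=dict)

    def get_node(self, nid: str) -> Node:
        for n in self.nodes:
            if n.id == nid:
                return n
        raise KeyError(nid)

    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]


@dataclass(eq=False)
class Model:
    id: str
    graphs: list[Graph] = field(default_factory=list)
    format_version: str = "MDF v0.1"
    metadata: dict = field(default_factory=dict)

    def get_graph(self, gid: str) -> Graph:
        for g in self.graphs:
            if g.id == gid:
                return g
        raise KeyError(gid)

    @property
    def graph(self) -> Graph:
        """The sole graph of a single-graph model."""
        if len(self.graphs) != 1:
            raise ValueError(f"model {self.id!r} has {len(self.graphs)} graphs")
        return self.graphs[0]


# --------------------------------------------------------------------------
# Validation report
# --------------------------------------------------------------------------

SEVERITIES = ("error", "warning", "info")


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # error | warning | info
    location: str  # slash path, e.g. "graph g/node A/edge e1"
    message: str

    def __str__(self) -> str:
        return f"{self.severity}: {self.location}: {self.message}"


class ValidationReport:
    def __init__(self, issues: Iterable[ValidationIssue] = ()):
        self.issues: list[ValidationIssue] = list(issues)

    def add(self, severity: str, location: str, message: str) -> None:
        assert severity in SEVERITIES
        self.issues.append(ValidationIssue(severity, location, message))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def ok(self) -> bool:
        """True iff no *errors*; warnings and info entries do not block."""
        return not self.errors

    def __iter__(self):
        return iter(self.issues)

    def __len__(self):
        return len(self.issues)

    def __str__(self) -> str:
        if not self.issues:
            return "valid: no issues"
        return "\n".join(str(i) for i in self.issues)


class InvalidModelError(ValueError):
    """Raised by operations that require a well-formed model."""

    def __init__(self, message: str, report: ValidationReport):
        super().__init__(f"{message}\n{report}")
        self.report = report


# --------------------------------------------------------------------------
# Cycle detection
# --------------------------------------------------------------------------

def node_digraph(graph: Graph) -> nx.DiGraph:
    """Node-level directed dependency graph implied by the edges."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.node_ids())
    for e in graph.edges:
        g.add_edge(e.sender, e.receiver)
    return g


def detect_cycles(graph: Graph) -> list[list[str]]:
    """Every elementary circuit of the node-level digraph.

    Each cycle is rotated to start at its lexicographically smallest node
    id, and cycles are returned sorted, so the output is deterministic.
    """
    dg = node_digraph(graph)
    cycles = []
    for cyc in nx.simple_cycles(dg):
        k = cyc.index(min(cyc))
        cycles.append(cyc[k:] + cyc[:k])
    cycles.sort()
    return cycles


def cycle_edges(graph: Graph) -> set[tuple[str, str]]:
    """(sender, receiver) pairs that lie on at least one elementary circuit.

    An edge lies on a circuit iff both endpoints are in the same strongly
    connected component (with self-loops handled directly).
    """
    dg = node_digraph(graph)
    comp: dict[str, int] = {}
    for i, scc in enumerate(nx.strongly_connected_components(dg)):
        for n in scc:
            comp[n] = i
    out = set()
    for e in graph.edges:
        if e.sender == e.receiver or (
            e.sender in comp and e.receiver in comp
            and comp[e.sender] == comp[e.receiver]
            and len([n for n, c in comp.items() if c == comp[e.sender]]) > 1
        ):
            out.add((e.sender, e.receiver))
    return out


# --------------------------------------------------------------------------
# validate_model
# --------------------------------------------------------------------------

def _check_unique(ids: list[str], what: str, loc: str, rep: ValidationReport) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            rep.add("error", loc, f"duplicate {what} id {i!r}")
        seen.add(i)


def _check_expr(source, loc: str, rep: ValidationReport) -> Optional[xp.Expression]:
    if not isinstance(source, str):
        return None
    try:
        return xp.parse(source)
    except xp.ExpressionSyntaxError as err:
        rep.add("error", loc, f"expression does not parse: {err}")
        return None


def _validate_node(node: Node, loc: str, rep: ValidationReport,
                   registry: FunctionRegistry) -> None:
    if not is_identifier(node.id, dotted=True):
        rep.add("error", loc, f"invalid node id {node.id!r}")
    _check_unique(node.local_ids() + [p.id for p in node.output_ports],
                  "port/parameter/function", loc, rep)
    if node.subgraph is not None and (node.parameters or node.functions):
        rep.add("error", loc,
                "a node has either parameters/functions or a subgraph, not both")
    local = set(node.local_ids())

    for port in node.input_ports:
        ploc = f"{loc}/input_port {port.id}"
        if not is_identifier(port.id):
            rep.add("error", ploc, f"invalid port id {port.id!r}")
        if port.reduce not in ("error", "sum"):
            rep.add("error", ploc, f"unknown reduce policy {port.reduce!r}")
        if port.shape is not None and any(s <= 0 for s in port.shape):
            rep.add("error", ploc, f"shape entries must be positive: {port.shape}")

    # Non-stateful parameters must form an acyclic intra-node reference
    # graph; stateful parameters read previous values and so break cycles.
    dep = nx.DiGraph()
    for p in node.parameters:
        ploc = f"{loc}/parameter {p.id}"
        if not is_identifier(p.id):
            rep.add("error", ploc, f"invalid parameter id {p.id!r}")
        if p.stateful and p.default_initial_value is None:
            rep.add("error", ploc, "stateful parameter needs default_initial_value")
        if p.time_derivative is not None:
            _check_expr(p.time_derivative, ploc, rep)
        expr = _check_expr(p.value, ploc, rep)
        if expr is not None and not p.stateful:
            dep.add_node(p.id)
            for ref in xp.free_identifiers(expr):
                dep.add_edge(ref, p.id)
    nonstateful = {p.id for p in node.parameters if not p.stateful}
    sub = dep.subgraph(nonstateful & set(dep.nodes))
    for cyc in nx.simple_cycles(nx.DiGraph(sub)):
        rep.add("error", loc,
                f"non-stateful parameters form a reference cycle: {sorted(cyc)}")

    for fc in node.functions:
        floc = f"{loc}/function {fc.id}"
        if not is_identifier(fc.id):
            rep.add("error", floc, f"invalid function-call id {fc.id!r}")
        if fc.function not in registry:
            rep.add("error", floc, f"function {fc.function!r} not in ontology")
        else:
            fdef = registry.lookup(fc.function)
            for spec in fdef.arg_spec:
                if spec.required and spec.name not in fc.args:
                    rep.add("error", floc,
                            f"missing required argument {spec.name!r} of {fc.function!r}")
            for name in fc.args:
                if not any(s.name == name for s in fdef.arg_spec):
                    rep.add("error", floc,
                            f"unknown argument {name!r} of {fc.function!r}")
        for aname, aval in fc.args.items():
            _check_expr(aval, f"{floc}/arg {aname}", rep)

    reserved = {"dt", "t"}
    for port in node.output_ports:
        ploc = f"{loc}/output_port {port.id}"
        if not is_identifier(port.id):
            rep.add("error", ploc, f"invalid port id {port.id!r}")
        if node.subgraph is not None:
            # Boundary alias onto the like-named inner port; no expression.
            if port.value:
                rep.add("error", ploc,
                        "boundary ports of a subgraph node carry no expression")
            continue
        expr = _check_expr(port.value, ploc, rep)
        if expr is not None:
            for ref in xp.free_identifiers(expr):
                if ref not in local and ref not in reserved:
                    rep.add("error", ploc,
                            f"references {ref!r}, not defined in this node")


def _validate_graph(graph: Graph, loc: str, rep: ValidationReport,
                    registry: FunctionRegistry) -> None:
    if not is_identifier(graph.id):
        rep.add("error", loc, f"invalid graph id {graph.id!r}")
    _check_unique(graph.node_ids(), "node", loc, rep)

    nodes_by_id = {n.id: n for n in graph.nodes}
    for node in graph.nodes:
        _validate_node(node, f"{loc}/node {node.id}", rep, registry)
        if node.subgraph is not None:
            _validate_graph(node.subgraph, f"{loc}/node {node.id}/subgraph",
                            rep, registry)

    incoming: dict[tuple[str, str], list[Edge]] = {}
    seen_pairs: set[tuple[str, str, str, str]] = set()
    resolved = True
    for e in graph.edges:
        eloc = f"{loc}/edge {e.id}"
        ok = True
        for role, nid, pid, ports in (
            ("sender", e.sender, e.sender_port, "output_ports"),
            ("receiver", e.receiver, e.receiver_port, "input_ports"),
        ):
            node = nodes_by_id.get(nid)
            if node is None:
                rep.add("error", eloc, f"{role} node {nid!r} does not exist")
                ok = False
            elif pid not in [p.id for p in getattr(node, ports)]:
                rep.add("error", eloc,
                        f"{role} port {nid!r}.{pid!r} does not exist")
                ok = False
        if not ok:
            resolved = False
            continue
        key = (e.sender, e.sender_port, e.receiver, e.receiver_port)
        if key in seen_pairs:
            rep.add("error", eloc, f"duplicate edge for port pair {key}")
        seen_pairs.add(key)
        incoming.setdefault((e.receiver, e.receiver_port), []).append(e)

    for (nid, pid), edges in incoming.items():
        if len(edges) > 1:
            port = next(p for p in nodes_by_id[nid].input_ports if p.id == pid)
            if port.reduce != "sum":
                rep.add("error", f"{loc}/node {nid}/input_port {pid}",
                        f"{len(edges)} incoming edges but reduce policy is "
                        "'error'; declare reduce='sum' for fan-in")

    if resolved:
        cycles = detect_cycles(graph)
        if cycles:
            rep.add("info", loc,
                    f"cycle detected: {len(cycles)} elementary circuit(s): "
                    + "; ".join("->".join(c) for c in cycles))
            on_cycle = cycle_edges(graph)
            for e in graph.edges:
                if (e.sender, e.receiver) in on_cycle:
                    port = next(p for p in nodes_by_id[e.sender].output_ports
                                if p.id == e.sender_port)
                    if port.default_initial_value is None:
                        rep.add("error",
                                f"{loc}/node {e.sender}/output_port {port.id}",
                                "feeds a cycle but has no default_initial_value")


def validate_model(model: Model, registry: FunctionRegistry | None = None
                   ) -> ValidationReport:
    """Check every structural invariant; return all violations found.

    Pure and idempotent; an empty report means the model is well-formed.
    Cycle presence is reported at severity ``info`` — cycles are a feature,
    but they oblige initial values on the ports that feed them.
    """
    registry = registry if registry is not None else standard_registry()
    rep = ValidationReport()
    if not is_identifier(model.id):
        rep.add("error", f"model {model.id}", f"invalid model id {model.id!r}")
    if not model.format_version:
        rep.add("error", f"model {model.id}", "format_version missing")
    _check_unique([g.id for g in model.graphs], "graph", f"model {model.id}", rep)
    for g in model.graphs:
        _validate_graph(g, f"graph {g.id}", rep, registry)
        if g.conditions is not None:
            _validate_conditions(g, f"graph {g.id}", rep)
    return rep


def _validate_conditions(graph: Graph, loc: str, rep: ValidationReport) -> None:
    # Imported lazily: scheduler depends on schema for graph access.
    from .scheduler import ConditionSet, condition_references

    cs = graph.conditions
    if not isinstance(cs, ConditionSet):
        rep.add("error", loc, f"conditions must be a ConditionSet, got {type(cs)}")
        return
    node_ids = set(graph.node_ids())
    for nid, cond in cs.node_specific.items():
        if nid not in node_ids:
            rep.add("error", f"{loc}/conditions",
                    f"condition attached to unknown node {nid!r}")
        for ref in condition_references(cond):
            if ref not in node_ids:
                rep.add("error", f"{loc}/conditions/node {nid}",
                        f"condition references unknown node {ref!r}")
    if cs.termination is not None:
        for ref in condition_references(cs.termination):
            if ref not in node_ids:
                rep.add("error", f"{loc}/conditions/termination",
                        f"condition references unknown node {ref!r}")


# --------------------------------------------------------------------------
# Hierarchy flattening
# --------------------------------------------------------------------------

class FlattenError(ValueError):
    pass


def _flatten_graph(graph: Graph) -> Graph:
    from .scheduler import ConditionSet

    # Bottom-up: flatten each node's subgraph first.
    nodes: list[Node] = []
    edges: list[Edge] = list(graph.edges)
    node_specific: dict[str, object] = {}
    termination = None
    if isinstance(graph.conditions, ConditionSet):
        node_specific = dict(graph.conditions.node_specific)
        termination = graph.conditions.termination

    # Maps (wrapper node id, boundary port id) -> (inner node id, port id)
    in_bound: dict[tuple[str, str], tuple[str, str]] = {}
    out_bound: dict[tuple[str, str], tuple[str, str]] = {}

    for node in graph.nodes:
        if node.subgraph is None:
            nodes.append(node)
            continue
        inner = _flatten_graph(node.subgraph)
        prefix = node.id + "."
        # Boundary convention: each boundary port of the wrapper maps onto
        # the unique inner node exposing a like-named port.
        for port in node.input_ports:
            owners = [n.id for n in inner.nodes
                      if port.id in [p.id for p in n.input_ports]]
            if len(owners) != 1:
                raise FlattenError(
                    f"node {node.id!r}: boundary input port {port.id!r} must "
                    f"match exactly one inner port, found {len(owners)}")
            in_bound[(node.id, port.id)] = (prefix + owners[0], port.id)
        for port in node.output_ports:
            owners = [n.id for n in inner.nodes
                      if port.id in [p.id for p in n.output_ports]]
            if len(owners) != 1:
                raise FlattenError(
                    f"node {node.id!r}: boundary output port {port.id!r} must "
                    f"match exactly one inner port, found {len(owners)}")
            out_bound[(node.id, port.id)] = (prefix + owners[0], port.id)

        inner_ids = []
        for n in inner.nodes:
            n.id = prefix + n.id
            nodes.append(n)
            inner_ids.append(n.id)
        for e in inner.edges:
            e.id = prefix + e.id
            e.sender = prefix + e.sender
            e.receiver = prefix + e.receiver
            edges.append(e)
        if isinstance(inner.conditions, ConditionSet):
            from .scheduler import namespace_condition
            for nid, cond in inner.conditions.node_specific.items():
                node_specific[prefix + nid] = namespace_condition(cond, prefix)
        # A condition attached to the wrapper applies to each flattened child.
        if node.id in node_specific:
            cond = node_specific.pop(node.id)
            for nid in inner_ids:
                node_specific.setdefault(nid, cond)

    flat_ids = {n.id for n in nodes}
    for e in edges:
        if e.sender not in flat_ids and (e.sender, e.sender_port) in out_bound:
            e.sender, e.sender_port = out_bound[(e.sender, e.sender_port)]
        if e.receiver not in flat_ids and (e.receiver, e.receiver_port) in in_bound:
            e.receiver, e.receiver_port = in_bound[(e.receiver, e.receiver_port)]

    # Scheduler references to a former wrapper node cannot be rewired
    # meaningfully; surface the problem instead of guessing.
    from .scheduler import condition_references
    for nid, cond in node_specific.items():
        for ref in condition_references(cond):
            if ref not in flat_ids:
                raise FlattenError(
                    f"condition on {nid!r} references {ref!r}, which was "
                    "flattened away; attach conditions to leaf nodes")

    conditions = graph.conditions
    if node_specific or termination is not None:
        conditions = ConditionSet(node_specific=node_specific,
                                  termination=termination)
    return Graph(id=graph.id, nodes=nodes, edges=edges,
                 conditions=conditions, metadata=dict(graph.metadata))


def flatten_hierarchy(model: Model) -> Model:
    """Replace every subgraph node by its namespaced contents.

    Child ids are prefixed ``"parentid."`` and boundary edges are rewired
    through the wrapper's like-named ports.  Execution semantics are
    preserved: the engine runs hierarchical models by flattening them, so
    the flattened form *is* the semantics.  Idempotent on flat models.
    """
    from .serialization import copy_model

    rep = validate_model(model)
    if not rep.ok:
        raise InvalidModelError(f"cannot flatten invalid model {model.id!r}", rep)
    model = copy_model(model)
    return Model(
        id=model.id,
        graphs=[_flatten_graph(g) for g in model.graphs],
        format_version=model.format_version,
        metadata=dict(model.metadata),
    )
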