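"""Condition-based scheduling: which nodes run, pass by pass.

A *pass* is one scheduler iteration in which every node whose condition is
satisfied executes once.  Conditions are declarative predicates over the
scheduler state (call counts, the simulation clock, last committed
parameter values), composable with and/or/not.  This vocabulary spans the
three control-flow needs of a general graph format: arbitrary execution
order, nodes running on different timescales (``every_n_calls``), and
cyclic graphs (which simply execute every pass reading previous-pass
values).

``every_n_calls`` uses per-dependent consumption bookkeeping rather than a
raw modulus: each n-th call of the dependency banks one firing for the
dependent, and the firing is consumed when the dependent actually runs.  A
dependent that is itself gated therefore never misses a firing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Optional

import networkx as nx

from .schema import Graph

__all__ = [
    "Condition", "ConditionSet", "SchedulerState", "ExecutionTrace",
    "is_satisfied", "next_execution_set", "run_schedule",
    "always", "never", "every_n_calls", "after_n_calls", "before_n_calls",
    "threshold", "time_interval", "all_of", "any_of", "not_", "all_have_run",
]

_COMPARATORS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}

_TYPES = ("always", "never", "every_n_calls", "after_n_calls",
          "before_n_calls", "threshold", "time_interval", "and", "or",
          "not", "all_have_run")


@dataclass(frozen=True)
class Condition:
    """A declarative execution predicate: ``type`` plus typed ``args``.

    Construct through the module-level factories (:func:`always`,
    :func:`every_n_calls`, ...) which validate the arguments.
    """

    type: str
    args: tuple[tuple[str, object], ...] = ()

    def __post_init__(self):
        if self.type not in _TYPES:
            raise ValueError(f"unknown condition type {self.type!r}")

    def arg(self, name: str):
        return dict(self.args)[name]

    def to_tree(self) -> dict:
        args = {}
        for k, v in self.args:
            if isinstance(v, Condition):
                args[k] = v.to_tree()
            elif isinstance(v, tuple) and all(isinstance(c, Condition) for c in v):
                args[k] = [c.to_tree() for c in v]
            else:
                args[k] = v
        return {"type": self.type, "args": args}

    @staticmethod
    def from_tree(tree: Mapping) -> "Condition":
        ctype = tree["type"]
        raw = dict(tree.get("args", {}))
        if ctype in ("and", "or"):
            return Condition(ctype, (("terms", tuple(
                Condition.from_tree(t) for t in raw["terms"])),))
        if ctype == "not":
            return Condition("not", (("inner", Condition.from_tree(raw["inner"])),))
        return Condition(ctype, tuple(sorted(raw.items())))


def always() -> Condition:
    return Condition("always")


def never() -> Condition:
    return Condition("never")


def _n_calls(ctype: str, dependency: str, n: int) -> Condition:
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"{ctype}: n must be an integer >= 1, got {n!r}")
    return Condition(ctype, (("dependency", dependency), ("n", n)))


def every_n_calls(dependency: str, n: int) -> Condition:
    """Fire once for each n calls of ``dependency`` (banked, not modular)."""
    return _n_calls("every_n_calls", dependency, n)


def after_n_calls(dependency: str, n: int) -> Condition:
    """Satisfied once ``dependency`` has been called at least n times."""
    return _n_calls("after_n_calls", dependency, n)


def before_n_calls(dependency: str, n: int) -> Condition:
    """Satisfied while ``dependency`` has been called fewer than n times."""
    return _n_calls("before_n_calls", dependency, n)


def threshold(node: str, parameter: str, comparator: str, value: float) -> Condition:
    """Compare a parameter's last *committed* value against a constant."""
    if comparator not in _COMPARATORS:
        raise ValueError(f"unknown comparator {comparator!r}")
    return Condition("threshold", (("comparator", comparator), ("node", node),
                                   ("parameter", parameter), ("value", value)))


def time_interval(start: float, end: float) -> Condition:
    """Satisfied while start <= clock <= end (model time units)."""
    if end < start:
        raise ValueError(f"time_interval: end {end} < start {start}")
    return Condition("time_interval", (("end", end), ("start", start)))


def all_of(*terms: Condition) -> Condition:
    if not terms:
        raise ValueError("and-condition needs at least one term")
    return Condition("and", (("terms", tuple(terms)),))


def any_of(*terms: Condition) -> Condition:
    if not terms:
        raise ValueError("or-condition needs at least one term")
    return Condition("or", (("terms", tuple(terms)),))


def not_(inner: Condition) -> Condition:
    return Condition("not", (("inner", inner),))


def all_have_run() -> Condition:
    """Termination default: every node in the graph has executed."""
    return Condition("all_have_run")


def condition_references(cond: Condition) -> list[str]:
    """Node ids a condition refers to (for validation and flattening)."""
    out: list[str] = []
    for _, v in cond.args:
        if isinstance(v, Condition):
            out.extend(condition_references(v))
        elif isinstance(v, tuple) and all(isinstance(c, Condition) for c in v):
            for c in v:
                out.extend(condition_references(c))
    if cond.type in ("every_n_calls", "after_n_calls", "before_n_calls"):
        out.append(cond.arg("dependency"))
    elif cond.type == "threshold":
        out.append(cond.arg("node"))
    return out


def namespace_condition(cond: Condition, prefix: str) -> Condition:
    """Prefix every node reference (used when flattening subgraphs)."""
    args = []
    for k, v in cond.args:
        if isinstance(v, Condition):
            v = namespace_condition(v, prefix)
        elif isinstance(v, tuple) and all(isinstance(c, Condition) for c in v):
            v = tuple(namespace_condition(c, prefix) for c in v)
        elif k in ("dependency", "node"):
            v = prefix + v
        args.append((k, v))
    return Condition(cond.type, tuple(args))


@dataclass
class ConditionSet:
    """Per-node conditions plus the run's termination condition.

    Nodes absent from ``node_specific`` default to :func:`always`;
    ``termination`` defaults to :func:`all_have_run`.
    """

    node_specific: dict[str, Condition] = field(default_factory=dict)
    termination: Optional[Condition] = None

    def condition_for(self, node_id: str) -> Condition:
        return self.node_specific.get(node_id, always())

    @property
    def effective_termination(self) -> Condition:
        return self.termination if self.termination is not None else all_have_run()

    def to_tree(self) -> dict:
        tree: dict = {}
        if self.node_specific:
            tree["node_specific"] = {
                nid: c.to_tree() for nid, c in self.node_specific.items()
            }
        if self.termination is not None:
            tree["termination"] = self.termination.to_tree()
        return tree

    @staticmethod
    def from_tree(tree: Mapping) -> "ConditionSet":
        return ConditionSet(
            node_specific={
                nid: Condition.from_tree(t)
                for nid, t in tree.get("node_specific", {}).items()
            },
            termination=(Condition.from_tree(tree["termination"])
                         if "termination" in tree else None),
        )


# --------------------------------------------------------------------------
# Scheduler state and predicate evaluation
# --------------------------------------------------------------------------

@dataclass
class SchedulerState:
    """Mutable bookkeeping the scheduler reads (and the runner advances)."""

    pass_index: int = 0
    call_counts: dict[str, int] = field(default_factory=dict)
    clock: float = 0.0
    # (node, parameter) -> last committed value; read by threshold conditions
    last_values: Mapping[tuple[str, str], object] = field(default_factory=dict)
    # (dependent node, condition path) -> firings consumed, for every_n_calls
    consumed: dict[tuple[str, str], int] = field(default_factory=dict)

    def calls(self, node_id: str) -> int:
        return self.call_counts.get(node_id, 0)


def _every_n_leaves(cond: Condition, path: str = "") -> Iterator[tuple[str, Condition]]:
    if cond.type == "every_n_calls":
        yield path, cond
    for k, v in cond.args:
        if isinstance(v, Condition):
            yield from _every_n_leaves(v, f"{path}/{k}")
        elif isinstance(v, tuple) and all(isinstance(c, Condition) for c in v):
            for i, c in enumerate(v):
                yield from _every_n_leaves(c, f"{path}/{k}[{i}]")


def is_satisfied(cond: Condition, state: SchedulerState,
                 dependent: str | None = None,
                 graph_nodes: list[str] | None = None) -> int:
    """Evaluate a condition against the state; pure, returns 0 or 1.

    ``dependent`` identifies the node the condition gates (needed for
    every_n_calls consumption lookup); ``graph_nodes`` supplies the node
    population for ``all_have_run``.
    """
    t = cond.type
    if t == "always":
        return 1
    if t == "never":
        return 0
    if t == "every_n_calls":
        dep, n = cond.arg("dependency"), cond.arg("n")
        banked = state.calls(dep) // n
        used = state.consumed.get((dependent or "", _path_of(cond)), 0)
        return int(banked > used)
    if t == "after_n_calls":
        return int(state.calls(cond.arg("dependency")) >= cond.arg("n"))
    if t == "before_n_calls":
        return int(state.calls(cond.arg("dependency")) < cond.arg("n"))
    if t == "threshold":
        key = (cond.arg("node"), cond.arg("parameter"))
        try:
            val = state.last_values[key]
        except KeyError:
            raise KeyError(
                f"threshold condition reads {key[0]}.{key[1]}, which has no "
                "committed value") from None
        return int(bool(_COMPARATORS[cond.arg("comparator")](val, cond.arg("value"))))
    if t == "time_interval":
        return int(cond.arg("start") <= state.clock <= cond.arg("end"))
    if t == "and":
        return int(all(is_satisfied(c, state, dependent, graph_nodes)
                       for c in cond.arg("terms")))
    if t == "or":
        return int(any(is_satisfied(c, state, dependent, graph_nodes)
                       for c in cond.arg("terms")))
    if t == "not":
        return 1 - is_satisfied(cond.arg("inner"), state, dependent, graph_nodes)
    if t == "all_have_run":
        if graph_nodes is None:
            raise ValueError("all_have_run needs the graph's node list")
        return int(all(state.calls(n) >= 1 for n in graph_nodes))
    raise ValueError(f"unknown condition type {t!r}")  # pragma: no cover


def _path_of(cond: Condition) -> str:
    # Stable structural key for consumption bookkeeping: the serialized form.
    return repr(cond.to_tree())


def _consume_firings(cond: Condition, state: SchedulerState, dependent: str) -> None:
    """After ``dependent`` executed, bank-consume its satisfied every_n leaves."""
    for _, leaf in _every_n_leaves(cond):
        if is_satisfied(leaf, state, dependent):
            key = (dependent, _path_of(leaf))
            state.consumed[key] = state.consumed.get(key, 0) + 1


# --------------------------------------------------------------------------
# Pass construction and the run loop
# --------------------------------------------------------------------------

def consideration_order(graph: Graph) -> list[str]:
    """Static dependency order of all nodes in a graph.

    Strongly connected components are condensed and ordered topologically
    (stable Kahn keyed by earliest declaration index); within a component
    (a cycle, whose members read previous-pass values) nodes keep
    declaration order.  For a DAG this is exactly a topological sort with
    declaration-order tie-breaking.
    """
    node_ids = graph.node_ids()
    decl = {nid: i for i, nid in enumerate(node_ids)}
    dg = nx.DiGraph()
    dg.add_nodes_from(node_ids)
    for e in graph.edges:
        if e.sender != e.receiver:
            dg.add_edge(e.sender, e.receiver)

    sccs = [sorted(c, key=decl.__getitem__)
            for c in nx.strongly_connected_components(dg)]
    comp_of = {n: i for i, c in enumerate(sccs) for n in c}
    cond_g = nx.DiGraph()
    cond_g.add_nodes_from(range(len(sccs)))
    for u, v in dg.edges:
        if comp_of[u] != comp_of[v]:
            cond_g.add_edge(comp_of[u], comp_of[v])

    indeg = {c: cond_g.in_degree(c) for c in cond_g.nodes}
    ready = sorted((c for c in cond_g.nodes if indeg[c] == 0),
                   key=lambda c: decl[sccs[c][0]])
    order: list[str] = []
    while ready:
        c = ready.pop(0)
        order.extend(sccs[c])
        for nxt in cond_g.successors(c):
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                ready.append(nxt)
        ready.sort(key=lambda c: decl[sccs[c][0]])
    return order


def _mark_executed(cond: Condition, state: SchedulerState, nid: str) -> None:
    """Advance bookkeeping for one execution of ``nid`` under ``cond``."""
    state.call_counts[nid] = state.calls(nid) + 1
    _consume_firings(cond, state, nid)


def next_execution_set(graph: Graph, condition_set: ConditionSet,
                       state: SchedulerState) -> list[str]:
    """Ordered node ids to execute this pass.  Does not mutate ``state``.

    Nodes are considered once each, in :func:`consideration_order`; a
    node's condition is evaluated at its turn, so call-count conditions see
    executions of upstream nodes earlier in the same pass (this is what
    lets ``every_n_calls(fast, k)`` fire in the same pass as the fast
    node's k-th call).  Value-based (threshold) conditions read the values
    committed before the pass started.  Mutually cyclic nodes execute in
    declaration order, reading previous-pass values.
    """
    sim = SchedulerState(
        pass_index=state.pass_index,
        call_counts=dict(state.call_counts),
        clock=state.clock,
        last_values=state.last_values,
        consumed=dict(state.consumed),
    )
    node_ids = graph.node_ids()
    chosen: list[str] = []
    for nid in consideration_order(graph):
        cond = condition_set.condition_for(nid)
        if is_satisfied(cond, sim, dependent=nid, graph_nodes=node_ids):
            chosen.append(nid)
            _mark_executed(cond, sim, nid)
    return chosen


@dataclass
class ExecutionTrace:
    """Ordered record of node executions: (pass index, node id) pairs."""

    entries: list[tuple[int, str]] = field(default_factory=list)
    clocks: list[float] = field(default_factory=list)
    outcome: str = "terminated"  # terminated | budget_exhausted | error

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("pass,node,clock\n")
        for (p, nid), clk in zip(self.entries, self.clocks):
            buf.write(f"{p},{nid},{clk!r}\n")
        return buf.getvalue()


class ExecutorFailure(RuntimeError):
    """An executor callback raised; the partial trace is attached."""

    def __init__(self, node_id: str, cause: BaseException, trace: ExecutionTrace):
        super().__init__(f"executor failed at node {node_id!r}: {cause}")
        self.node_id = node_id
        self.cause = cause
        self.trace = trace


def run_schedule(graph: Graph, condition_set: ConditionSet,
                 executor: Callable[[str, SchedulerState], None] | None = None,
                 max_passes: int = 1000,
                 state: SchedulerState | None = None,
                 after_pass: Callable[[SchedulerState], None] | None = None,
                 ) -> ExecutionTrace:
    """Drive passes until the termination condition holds or the budget ends.

    ``executor`` is invoked once per scheduled node per pass; ``after_pass``
    (used by the engine to advance simulated time) runs after each pass,
    before the termination check.  The two outcomes — ``terminated`` and
    ``budget_exhausted`` — are distinguished on the returned trace.
    """
    if max_passes < 1:
        raise ValueError("max_passes must be >= 1")
    state = state if state is not None else SchedulerState()
    trace = ExecutionTrace()
    node_ids = graph.node_ids()
    term = condition_set.effective_termination
    for _ in range(max_passes):
        for nid in next_execution_set(graph, condition_set, state):
            if executor is not None:
                try:
                    executor(nid, state)
                except Exception as err:
                    trace.outcome = "error"
                    raise ExecutorFailure(nid, err, trace) from err
            trace.entries.append((state.pass_index, nid))
            trace.clocks.append(state.clock)
            _mark_executed(condition_set.condition_for(nid), state, nid)
        if after_pass is not None:
            after_pass(state)
        state.pass_index += 1
        if is_satisfied(term, state, graph_nodes=node_ids):
            trace.outcome = "terminated"
            return trace
    trace.outcome = "budget_exhausted"
    return trace
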