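"""Reference execution engine.

Executes one graph pass by pass under the scheduler: each pass evaluates
the scheduled nodes (input ports, then parameters and function calls in
intra-node dependency order, then output ports, with stateful updates
committed atomically at node completion), propagates committed output-port
values along weighted edges, and then — for timed runs — advances every
ODE state parameter by one forward-Euler step and the clock by ``dt``.

Semantics choices that matter:

* Values crossing a cycle are the values committed on a previous pass;
  cycle-feeding output ports therefore require ``default_initial_value``.
* Stateful slots read their previous committed value during evaluation,
  which is what breaks intra-node self-reference.
* Forward Euler with a simultaneous (pre-step) read of all derivatives is
  the sole integrator: reference semantics stay simple and auditable.
* One scheduler pass per time step; condition-gated nodes on slower
  schedules are how multiple timescales coexist with integration.
* All randomness flows from the run-level seeded generator.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import expressions as xp
from .functions import FunctionRegistry, standard_registry
from .schema import (
    Graph, InvalidModelError, Model, Node, flatten_hierarchy, validate_model,
)
from .scheduler import (
    ConditionSet, ExecutionTrace, SchedulerState, never, run_schedule,
)

__all__ = [
    "ExecutionState", "RunResult", "EngineError", "NonFiniteError",
    "evaluate_node", "step_time", "run",
]


class EngineError(RuntimeError):
    pass


class NonFiniteError(EngineError):
    """State left the finite domain more times than the warning limit allows."""


@dataclass
class ExecutionState:
    """Mutable numerical state of a run.

    ``values`` maps ``(node id, slot id)`` — ports and parameters share one
    per-node namespace — to the last committed value.
    """

    values: dict[tuple[str, str], object] = field(default_factory=dict)
    clock: float = 0.0
    dt: float | None = None
    rng: np.random.Generator | None = None
    warnings: Counter = field(default_factory=Counter)
    warning_limit: int = 100

    def warn(self, kind: str) -> None:
        self.warnings[kind] += 1

    def check_finite_budget(self) -> None:
        if self.warnings["nonfinite"] > self.warning_limit:
            raise NonFiniteError(
                f"non-finite state values exceeded the warning limit "
                f"({self.warning_limit})")


def _initial_state(graph: Graph, *, dt=None, seed=None,
                   warning_limit: int = 100) -> ExecutionState:
    state = ExecutionState(dt=dt, rng=np.random.default_rng(seed),
                           warning_limit=warning_limit)
    for node in graph.nodes:
        for p in node.parameters:
            if p.stateful:
                state.values[(node.id, p.id)] = p.default_initial_value
        for port in node.output_ports:
            if port.default_initial_value is not None:
                state.values[(node.id, port.id)] = port.default_initial_value
    return state


def _builtins(state: ExecutionState) -> dict[str, object]:
    b: dict[str, object] = {"t": state.clock}
    if state.dt is not None:
        b["dt"] = state.dt
    return b


def _eval(source, bindings, registry, state: ExecutionState, where: str):
    """Evaluate an expression string (or pass a literal through)."""
    if not isinstance(source, str):
        return source
    try:
        return xp.evaluate(source, bindings, registry,
                           on_warning=state.warn, rng=state.rng)
    except xp.ExpressionError as err:
        raise EngineError(f"{where}: {err}") from err


def gather_incoming(graph: Graph, node: Node, state: ExecutionState
                    ) -> dict[str, object]:
    """Committed upstream values for each input port, weighted and reduced."""
    nodes_by_id = {n.id: n for n in graph.nodes}
    incoming: dict[str, object] = {}
    for port in node.input_ports:
        contributions = []
        for e in graph.edges:
            if e.receiver != node.id or e.receiver_port != port.id:
                continue
            key = (e.sender, e.sender_port)
            if key in state.values:
                val = state.values[key]
            else:
                sender_port = next(
                    p for p in nodes_by_id[e.sender].output_ports
                    if p.id == e.sender_port)
                if sender_port.default_initial_value is not None:
                    val = sender_port.default_initial_value
                else:
                    state.warn("uninitialized_edge")
                    val = 0.0
            contributions.append(np.asarray(val, dtype=float) * e.weight)
        if not contributions:
            state.warn("unconnected_input")
            incoming[port.id] = 0.0
        elif len(contributions) == 1:
            incoming[port.id] = xp._as_result(contributions[0])
        else:
            # Validation guarantees reduce == "sum" when fan-in exists.
            incoming[port.id] = xp._as_result(sum(contributions))
    return incoming


def _node_evaluation_order(node: Node) -> list[tuple[str, object]]:
    """Intra-node slot order: topological over free-identifier references.

    Returns ("param"|"update"|"function", object) items.  Stateful
    parameters are *read* from previous values, so only the computation of
    new values participates in the ordering; a reference cycle among
    non-stateful slots is an error.
    """
    stateful = {p.id for p in node.parameters if p.stateful}
    items: dict[str, tuple[str, object]] = {}
    deps: dict[str, set[str]] = {}

    for p in node.parameters:
        kind = "update" if p.stateful else "param"
        items[p.id] = (kind, p)
        refs = set()
        if isinstance(p.value, str):
            refs = set(xp.free_identifiers(p.value))
        deps[p.id] = refs
    for f in node.functions:
        items[f.id] = ("function", f)
        refs = set()
        for v in f.args.values():
            if isinstance(v, str):
                refs |= set(xp.free_identifiers(v))
        deps[f.id] = refs

    # Edges only toward slots computed this pass; stateful reads resolve
    # to previous values and so impose no ordering.
    computed = {sid for sid in items if items[sid][0] != "update"}
    order: list[str] = []
    pending = {sid: {r for r in deps[sid] if r in computed and r != sid}
               for sid in items}
    declared = list(items)
    while pending:
        ready = [sid for sid in declared if sid in pending and not pending[sid]]
        if not ready:
            cyc = sorted(pending)
            raise EngineError(
                f"node {node.id!r}: unresolvable reference cycle among "
                f"non-stateful slots {cyc}")
        for sid in ready:
            order.append(sid)
            del pending[sid]
            for other in pending:
                pending[other].discard(sid)
    # Stateful reads come from previous values, so an update may safely run
    # before slots that mention the stateful id; order is already total.
    return [items[sid] for sid in order]


def evaluate_node(node: Node, incoming: Mapping[str, object],
                  state: ExecutionState,
                  registry: FunctionRegistry | None = None
                  ) -> dict[str, object]:
    """Execute one node; returns output-port values.

    Evaluation order: input ports are bound first, then parameters and
    function calls in intra-node dependency order, then output ports.
    Stateful parameters read their previous committed value throughout and
    their new values — along with output-port values and last input-port
    values — are committed to ``state`` atomically at node completion.
    """
    registry = registry if registry is not None else standard_registry()
    where = f"node {node.id}"
    bindings = dict(incoming)
    bindings.update(_builtins(state))
    for p in node.parameters:
        if p.stateful:
            bindings[p.id] = state.values.get((node.id, p.id),
                                              p.default_initial_value)

    staged: dict[str, object] = {}
    for kind, item in _node_evaluation_order(node):
        if kind == "param":
            bindings[item.id] = _eval(item.value, bindings, registry, state,
                                      f"{where}, parameter {item.id}")
        elif kind == "update":
            if item.value is not None:
                staged[item.id] = _eval(item.value, bindings, registry, state,
                                        f"{where}, parameter {item.id}")
        else:  # function call
            args = [
                _eval(v, bindings, registry, state,
                      f"{where}, function {item.id}, arg {k}")
                for k, v in item.args.items()
            ]
            kwargs = dict(zip(item.args.keys(), args))
            try:
                bindings[item.id] = registry.call(item.function, (), kwargs,
                                                  rng=state.rng)
            except (TypeError, ValueError, xp.ExpressionError) as err:
                raise EngineError(
                    f"{where}, function {item.id}: {err}") from err

    # Output ports see the node's state as committed at completion: the
    # freshly computed stateful updates, not the pre-execution values.
    bindings.update(staged)
    outputs: dict[str, object] = {}
    for port in node.output_ports:
        outputs[port.id] = _eval(port.value, bindings, registry, state,
                                 f"{where}, output_port {port.id}")

    # Atomic commit: stateful updates, last inputs, outputs.
    for pid, val in staged.items():
        state.values[(node.id, pid)] = val
    for pid, val in incoming.items():
        state.values[(node.id, pid)] = val
    for pid, val in outputs.items():
        state.values[(node.id, pid)] = val
    return outputs


def step_time(graph: Graph, state: ExecutionState,
              registry: FunctionRegistry | None = None) -> ExecutionState:
    """Advance every ODE state parameter by one forward-Euler step.

    All derivative evaluations read pre-step committed values (simultaneous
    update), then the clock advances by ``dt``.  Non-finite results count
    against the warning budget and raise once it is exhausted.
    """
    if state.dt is None or state.dt <= 0:
        raise EngineError("step_time requires dt > 0")
    registry = registry if registry is not None else standard_registry()
    staged: dict[tuple[str, str], object] = {}
    for node in graph.nodes:
        ode_params = [p for p in node.parameters if p.time_derivative is not None]
        if not ode_params:
            continue
        bindings = dict(_builtins(state))
        for pid in [p.id for p in node.parameters] + [p.id for p in node.input_ports]:
            if (node.id, pid) in state.values:
                bindings[pid] = state.values[(node.id, pid)]
        for p in node.parameters:
            if not p.stateful and not isinstance(p.value, str) and p.value is not None:
                bindings.setdefault(p.id, p.value)
            elif not p.stateful and isinstance(p.value, str):
                bindings[p.id] = _eval(p.value, bindings, registry, state,
                                       f"node {node.id}, parameter {p.id}")
        for p in ode_params:
            deriv = _eval(p.time_derivative, bindings, registry, state,
                          f"node {node.id}, parameter {p.id} (time_derivative)")
            new = np.asarray(bindings[p.id], dtype=float) + state.dt * np.asarray(
                deriv, dtype=float)
            new = xp._as_result(new)
            if not np.all(np.isfinite(np.asarray(new, dtype=float))):
                state.warn("nonfinite")
            staged[(node.id, p.id)] = new
    state.values.update(staged)
    state.clock += state.dt
    state.check_finite_budget()
    return state


# --------------------------------------------------------------------------
# run
# --------------------------------------------------------------------------

def _normalize_slot(slot) -> tuple[str, str]:
    if isinstance(slot, str):
        node, _, sid = slot.partition(":")
        if not sid:
            raise ValueError(
                f"record slot {slot!r} must be 'node_id:slot_id'")
        return node, sid
    node, sid = slot
    return str(node), str(sid)


@dataclass
class RunResult:
    """Everything a run produced: trace, recorded series, final state."""

    trace: ExecutionTrace
    recorded: dict[tuple[str, str], np.ndarray]
    times: dict[tuple[str, str], np.ndarray]
    outcome: str  # terminated | budget_exhausted | error
    state: ExecutionState
    warnings: Counter

    def value(self, node_id: str, slot_id: str):
        """Last committed value of a port or parameter."""
        return self.state.values[(node_id, slot_id)]

    def series(self, node_id: str, slot_id: str) -> np.ndarray:
        return self.recorded[(node_id, slot_id)]

    def to_csv(self) -> str:
        """Recorded series as CSV: leading clock column, one column per slot."""
        slots = list(self.recorded)
        rows: dict[float, dict[tuple[str, str], object]] = {}
        order: list[float] = []
        for slot in slots:
            for t, v in zip(self.times[slot], self.recorded[slot]):
                t = float(t)
                if t not in rows:
                    rows[t] = {}
                    order.append(t)
                rows[t][slot] = v
        buf = io.StringIO()
        buf.write("clock," + ",".join(f"{n}:{s}" for n, s in slots) + "\n")
        for t in order:
            cells = []
            for slot in slots:
                v = rows[t].get(slot, "")
                if isinstance(v, np.ndarray):
                    v = "\"" + repr(v.tolist()) + "\""
                elif v != "":
                    v = repr(float(v)) if isinstance(v, float) else repr(v)
                cells.append(str(v))
            buf.write(repr(t) + "," + ",".join(cells) + "\n")
        return buf.getvalue()


def run(model: Model, *, dt: float | None = None, duration: float | None = None,
        max_passes: int | None = None, seed: int | None = 0,
        record: Sequence = (), registry: FunctionRegistry | None = None,
        warning_limit: int = 100) -> RunResult:
    """Execute a model: couple the scheduler with node evaluation and time.

    Exactly one of ``duration`` (with ``dt``) or ``max_passes`` must be
    given.  Each pass executes the scheduled node set, then — for timed
    runs — advances ODE state and the clock by ``dt``.  ``record`` lists
    ``"node_id:slot_id"`` slots (or tuples) whose committed values are
    captured at the end of every pass in which the owning node executed.
    A fixed ``seed`` makes stochastic models bit-reproducible.
    """
    if (duration is None) == (max_passes is None):
        raise ValueError("exactly one of duration or max_passes is required")
    if duration is not None:
        if dt is None or dt <= 0:
            raise ValueError("duration runs require dt > 0")
        n_passes = max(1, int(round(duration / dt)))
    else:
        if max_passes < 1:
            raise ValueError("max_passes must be >= 1")
        n_passes = max_passes

    registry = registry if registry is not None else standard_registry()
    report = validate_model(model, registry)
    if not report.ok:
        raise InvalidModelError(f"cannot run invalid model {model.id!r}", report)
    if any(n.subgraph is not None for g in model.graphs for n in g.nodes):
        model = flatten_hierarchy(model)
    graph = model.graph

    condition_set = graph.conditions if isinstance(graph.conditions, ConditionSet) \
        else ConditionSet()
    if duration is not None and condition_set.termination is None:
        # A timed run is bounded by its duration, not by all_have_run.
        condition_set = ConditionSet(node_specific=condition_set.node_specific,
                                     termination=never())

    state = _initial_state(graph, dt=dt, seed=seed, warning_limit=warning_limit)
    slots = [_normalize_slot(s) for s in record]
    recorded: dict[tuple[str, str], list] = {s: [] for s in slots}
    times: dict[tuple[str, str], list] = {s: [] for s in slots}
    executed_this_pass: set[str] = set()
    timestep_due = dt is not None

    def executor(nid: str, sstate: SchedulerState) -> None:
        node = graph.get_node(nid)
        incoming = gather_incoming(graph, node, state)
        evaluate_node(node, incoming, state, registry)
        executed_this_pass.add(nid)

    def after_pass(sstate: SchedulerState) -> None:
        if timestep_due:
            step_time(graph, state, registry)
            sstate.clock = state.clock
        for slot in slots:
            if slot[0] in executed_this_pass:
                recorded[slot].append(state.values.get(slot))
                times[slot].append(state.clock)
        executed_this_pass.clear()

    sched_state = SchedulerState(last_values=state.values)
    trace = run_schedule(graph, condition_set, executor,
                         max_passes=n_passes, state=sched_state,
                         after_pass=after_pass)

    outcome = trace.outcome
    if duration is not None and outcome == "budget_exhausted":
        outcome = "terminated"  # the duration is the budget, fully used

    return RunResult(
        trace=trace,
        recorded={s: np.asarray(v) for s, v in recorded.items()},
        times={s: np.asarray(v, dtype=float) for s, v in times.items()},
        outcome=outcome,
        state=state,
        warnings=state.warnings,
    )
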