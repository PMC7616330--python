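"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops, brute-force
enumeration, a from-the-definition scheduler replay — and shares no code
with the package paths it checks.
"""

from __future__ import annotations

import itertools
import math


# --------------------------------------------------------------------------
# Naive tensor-operator oracles (pure-Python nested lists, explicit loops)
# --------------------------------------------------------------------------

def _map1(f, x):
    if isinstance(x, list):
        return [_map1(f, v) for v in x]
    return f(x)


def _map2(f, a, b):
    a_list, b_list = isinstance(a, list), isinstance(b, list)
    if a_list and b_list:
        return [_map2(f, x, y) for x, y in zip(a, b)]
    if a_list:
        return [_map2(f, x, b) for x in a]
    if b_list:
        return [_map2(f, a, y) for y in b]
    return f(a, b)


def _flatten(x):
    if isinstance(x, list):
        out = []
        for v in x:
            out.extend(_flatten(v))
        return out
    return [x]


def _shape(x):
    shape = []
    while isinstance(x, list):
        shape.append(len(x))
        x = x[0]
    return shape


def _sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def naive_matmul(a, b):
    n, k = len(a), len(a[0])
    m = len(b[0])
    out = [[0.0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            s = 0.0
            for kk in range(k):
                s += a[i][kk] * b[kk][j]
            out[i][j] = s
    return out


def naive_softmax_1d(x):
    mx = max(x)
    exps = [math.exp(v - mx) for v in x]
    total = sum(exps)
    return [e / total for e in exps]


def naive_softmax_last_axis(x):
    if isinstance(x[0], list):
        return [naive_softmax_last_axis(row) for row in x]
    return naive_softmax_1d(x)


def naive_transpose_2d(a):
    return [[a[i][j] for i in range(len(a))] for j in range(len(a[0]))]


def naive_reduce_all(x, kind):
    flat = _flatten(x)
    if kind == "sum":
        return sum(flat)
    if kind == "mean":
        return sum(flat) / len(flat)
    if kind == "max":
        out = flat[0]
        for v in flat[1:]:
            if v > out:
                out = v
        return out
    raise ValueError(kind)


ELEMENTWISE_UNARY = {
    "neg": lambda v: -v,
    "abs": abs,
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "sin": math.sin,
    "cos": math.cos,
    "tanh": math.tanh,
    "sigmoid": _sigmoid,
    "relu": lambda v: v if v > 0 else 0.0,
}

ELEMENTWISE_BINARY = {
    "add": lambda a, b: a + b,
    "sub": lambda a, b: a - b,
    "mul": lambda a, b: a * b,
    "div": lambda a, b: a / b,
    "pow": lambda a, b: a ** b,
}


def elementwise_unary(name, x):
    return _map1(ELEMENTWISE_UNARY[name], x)


def elementwise_binary(name, a, b):
    return _map2(ELEMENTWISE_BINARY[name], a, b)


def naive_clip(x, lo, hi):
    return _map1(lambda v: lo if v < lo else (hi if v > hi else v), x)


def naive_concat_axis0(a, b):
    return list(a) + list(b)


def naive_reshape(x, shape):
    flat = _flatten(x)

    def build(dims, it):
        if not dims:
            return next(it)
        return [build(dims[1:], it) for _ in range(dims[0])]

    return build(list(shape), iter(flat))


# --------------------------------------------------------------------------
# Graph oracles
# --------------------------------------------------------------------------

def brute_force_cycles(node_ids, edge_pairs):
    """All elementary circuits by exhaustive path enumeration.

    Each circuit is reported rotated to start at its smallest node id;
    the list is sorted.  Exponential — for tiny graphs only.
    """
    edges = set(edge_pairs)
    cycles = set()
    for n in node_ids:
        if (n, n) in edges:
            cycles.add((n,))
    for length in range(2, len(node_ids) + 1):
        for combo in itertools.combinations(sorted(node_ids), length):
            first = combo[0]
            for rest in itertools.permutations(combo[1:]):
                path = (first,) + rest
                if all((path[i], path[(i + 1) % length]) in edges
                       for i in range(length)):
                    cycles.add(path)
    return sorted(list(c) for c in cycles)


def kahn_topological_sort(node_ids, edge_pairs):
    """Kahn's algorithm with declaration-order tie-breaking."""
    decl = {n: i for i, n in enumerate(node_ids)}
    indeg = {n: 0 for n in node_ids}
    succ = {n: [] for n in node_ids}
    for u, v in edge_pairs:
        if u != v:
            succ[u].append(v)
            indeg[v] += 1
    ready = sorted([n for n in node_ids if indeg[n] == 0], key=decl.get)
    order = []
    while ready:
        n = ready.pop(0)
        order.append(n)
        for v in succ[n]:
            indeg[v] -= 1
            if indeg[v] == 0:
                ready.append(v)
        ready.sort(key=decl.get)
    if len(order) != len(node_ids):
        raise ValueError("graph is cyclic")
    return order


# --------------------------------------------------------------------------
# Scheduler trace-replay oracle
# --------------------------------------------------------------------------

def _oracle_order(node_ids, edge_pairs):
    """Dependency order: condensed SCCs topologically, declaration ties."""
    decl = {n: i for i, n in enumerate(node_ids)}
    # Tarjan-free SCC via repeated reachability (tiny graphs).
    succ = {n: set() for n in node_ids}
    for u, v in edge_pairs:
        if u != v:
            succ[u].add(v)

    def reach(start):
        seen, stack = set(), [start]
        while stack:
            n = stack.pop()
            for v in succ[n]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    fwd = {n: reach(n) for n in node_ids}
    comp = {}
    comps = []
    for n in node_ids:
        if n in comp:
            continue
        members = sorted(
            [m for m in node_ids if m == n
             or (m in fwd[n] and n in fwd[m])], key=decl.get)
        for m in members:
            comp[m] = len(comps)
        comps.append(members)
    cedges = {(comp[u], comp[v]) for u, v in edge_pairs
              if comp[u] != comp[v]}
    corder = kahn_topological_sort(list(range(len(comps))), cedges)
    out = []
    for c in corder:
        out.extend(comps[c])
    return out


def replay_schedule(node_ids, edge_pairs, conditions, termination,
                    max_passes):
    """From-the-definition replay of the pass semantics.

    ``conditions``/``termination`` are plain dict trees
    ``{"type": ..., "args": {...}}``.  Returns (trace, outcome).
    """
    order = _oracle_order(node_ids, edge_pairs)
    calls = {n: 0 for n in node_ids}
    consumed = {}

    def sat(tree, me):
        t, a = tree["type"], tree.get("args", {})
        if t == "always":
            return True
        if t == "never":
            return False
        if t == "every_n_calls":
            key = (me, repr(tree))
            return calls[a["dependency"]] // a["n"] > consumed.get(key, 0)
        if t == "after_n_calls":
            return calls[a["dependency"]] >= a["n"]
        if t == "before_n_calls":
            return calls[a["dependency"]] < a["n"]
        if t == "and":
            return all(sat(x, me) for x in a["terms"])
        if t == "or":
            return any(sat(x, me) for x in a["terms"])
        if t == "not":
            return not sat(a["inner"], me)
        if t == "all_have_run":
            return all(calls[n] >= 1 for n in node_ids)
        raise ValueError(t)

    def consume(tree, me):
        t, a = tree["type"], tree.get("args", {})
        if t == "every_n_calls" and sat(tree, me):
            key = (me, repr(tree))
            consumed[key] = consumed.get(key, 0) + 1
        for sub in a.get("terms", []):
            consume(sub, me)
        if "inner" in a:
            consume(a["inner"], me)

    trace = []
    for pass_ix in range(max_passes):
        for nid in order:
            tree = conditions.get(nid, {"type": "always"})
            if sat(tree, nid):
                trace.append((pass_ix, nid))
                calls[nid] += 1
                consume(tree, nid)
        if sat(termination, None):
            return trace, "terminated"
    return trace, "budget_exhausted"


# --------------------------------------------------------------------------
# Single-pass topological evaluation oracle for stateless DAG models
# --------------------------------------------------------------------------

def single_pass_eval(graph, registry):
    """Evaluate a stateless DAG graph once, in Kahn order.

    Independent of the engine's scheduling/propagation machinery: values
    move through a plain dict keyed by (node, port).  Uses the expression
    evaluator and registry directly (both verified elsewhere against naive
    oracles).
    """
    from mdfkit import expressions as xp

    order = kahn_topological_sort(
        graph.node_ids(), [(e.sender, e.receiver) for e in graph.edges])
    values = {}
    for nid in order:
        node = graph.get_node(nid)
        env = {}
        for port in node.input_ports:
            acc = None
            for e in graph.edges:
                if e.receiver == nid and e.receiver_port == port.id:
                    v = values[(e.sender, e.sender_port)]
                    contrib = [x * e.weight for x in v] if isinstance(v, list) \
                        else v * e.weight
                    if acc is None:
                        acc = contrib
                    elif isinstance(acc, list):
                        acc = [a + c for a, c in zip(acc, contrib)]
                    else:
                        acc += contrib
            env[port.id] = 0.0 if acc is None else acc
        # parameters in dependency order (repeat until all resolve)
        pending = list(node.parameters)
        while pending:
            progressed = False
            for p in list(pending):
                if not isinstance(p.value, str):
                    env[p.id] = p.value
                    pending.remove(p)
                    progressed = True
                    continue
                refs = xp.free_identifiers(p.value)
                if all(r in env for r in refs):
                    env[p.id] = xp.evaluate(p.value, env, registry)
                    pending.remove(p)
                    progressed = True
            if not progressed:
                raise ValueError(f"unresolvable parameters in node {nid}")
        for fc in node.functions:
            kwargs = {}
            for k, v in fc.args.items():
                kwargs[k] = xp.evaluate(v, env, registry) \
                    if isinstance(v, str) else v
            env[fc.id] = registry.call(fc.function, (), kwargs)
        for port in node.output_ports:
            values[(nid, port.id)] = xp.evaluate(port.value, env, registry)
    return values
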