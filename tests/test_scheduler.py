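"""Condition predicates and pass-level scheduling vs replay oracles."""

import random

import pytest

from mdfkit import (
    Condition, ConditionSet, Edge, Graph, InputPort, Model, Node, OutputPort,
    SchedulerState, after_n_calls, all_have_run, all_of, always, any_of,
    before_n_calls, every_n_calls, is_satisfied, never, next_execution_set,
    not_, run_schedule, threshold, time_interval,
)
from mdfkit.scheduler import ExecutorFailure, consideration_order

import oracles


def _graph(ids, pairs, conditions=None, termination=None):
    nodes = [Node(id=n, input_ports=[InputPort(id="in1", reduce="sum")],
                  output_ports=[OutputPort(id="out", value="in1",
                                           default_initial_value=0.0)])
             for n in ids]
    edges = [Edge(id=f"e{i}", sender=a, sender_port="out",
                  receiver=b, receiver_port="in1")
             for i, (a, b) in enumerate(pairs)]
    cs = ConditionSet(node_specific=conditions or {}, termination=termination)
    return Graph(id="g", nodes=nodes, edges=edges, conditions=cs), cs


def _random_state(rng, ids):
    return SchedulerState(
        pass_index=rng.randint(0, 5),
        call_counts={n: rng.randint(0, 6) for n in ids},
        clock=rng.uniform(0, 10),
    )


class TestConditionPredicates:
    def test_always_and_never(self):
        s = SchedulerState()
        assert is_satisfied(always(), s) == 1
        assert is_satisfied(never(), s) == 0

    def test_double_negation_over_random_states(self):
        rng = random.Random(7)
        ids = ["A", "B"]
        conds = [always(), never(), after_n_calls("A", 2),
                 before_n_calls("B", 3), time_interval(1.0, 5.0),
                 all_of(after_n_calls("A", 1), before_n_calls("B", 5))]
        for _ in range(100):
            s = _random_state(rng, ids)
            for c in conds:
                assert is_satisfied(not_(not_(c)), s) == is_satisfied(c, s)

    def test_condition_algebra_identities(self):
        rng = random.Random(8)
        ids = ["A", "B"]
        conds = [after_n_calls("A", 2), before_n_calls("B", 3),
                 time_interval(0.0, 4.0)]
        for _ in range(100):
            s = _random_state(rng, ids)
            for c in conds:
                assert is_satisfied(all_of(c, always()), s) == is_satisfied(c, s)
                assert is_satisfied(any_of(c, never()), s) == is_satisfied(c, s)
            a, b = conds[0], conds[1]
            # De Morgan
            assert is_satisfied(not_(all_of(a, b)), s) == \
                is_satisfied(any_of(not_(a), not_(b)), s)
            assert is_satisfied(not_(any_of(a, b)), s) == \
                is_satisfied(all_of(not_(a), not_(b)), s)

    def test_threshold_reads_committed_values(self):
        s = SchedulerState(last_values={("N", "p"): 2.5})
        assert is_satisfied(threshold("N", "p", ">", 2.0), s) == 1
        assert is_satisfied(threshold("N", "p", "<=", 2.0), s) == 0

    def test_threshold_on_missing_value_is_an_error(self):
        with pytest.raises(KeyError, match="N.p"):
            is_satisfied(threshold("N", "p", ">", 0.0), SchedulerState())

    def test_invalid_constructions_rejected(self):
        with pytest.raises(ValueError):
            every_n_calls("A", 0)
        with pytest.raises(ValueError):
            threshold("A", "p", "~", 1.0)
        with pytest.raises(ValueError):
            all_of()
        with pytest.raises(ValueError):
            time_interval(5.0, 1.0)

    def test_condition_tree_round_trip(self):
        c = all_of(every_n_calls("A", 2),
                   not_(any_of(never(), threshold("B", "p", ">=", 1.5))))
        assert Condition.from_tree(c.to_tree()) == c


class TestEveryNCallsConsumption:
    def _trace_nodes(self, trace):
        return [nid for _, nid in trace]

    def test_fires_once_per_n_dependency_calls(self):
        # A runs twice then stops; B banked exactly one firing
        g, cs = _graph(["A", "B"], [("A", "B")],
                       conditions={"A": before_n_calls("A", 2),
                                   "B": every_n_calls("A", 2)},
                       termination=never())
        trace = run_schedule(g, cs, max_passes=4)
        assert self._trace_nodes(trace).count("B") == 1

        g, cs = _graph(["A", "B"], [("A", "B")],
                       conditions={"A": before_n_calls("A", 4),
                                   "B": every_n_calls("A", 2)},
                       termination=never())
        trace = run_schedule(g, cs, max_passes=6)
        assert self._trace_nodes(trace).count("B") == 2

    def test_slow_node_runs_in_the_pass_of_the_nth_fast_call(self):
        g, cs = _graph(["A", "B"], [("A", "B")],
                       conditions={"B": every_n_calls("A", 2)},
                       termination=never())
        trace = run_schedule(g, cs, max_passes=4)
        assert list(trace) == [(0, "A"), (1, "A"), (1, "B"),
                               (2, "A"), (3, "A"), (3, "B")]

    def test_gated_dependent_never_misses_banked_firings(self):
        # B is additionally gated off until A has run 4 times; the two
        # firings banked meanwhile are consumed on consecutive passes.
        g, cs = _graph(["A", "B"], [("A", "B")],
                       conditions={"B": all_of(every_n_calls("A", 2),
                                               after_n_calls("A", 4))},
                       termination=never())
        trace = run_schedule(g, cs, max_passes=6)
        b_passes = [p for p, nid in trace if nid == "B"]
        assert b_passes == [3, 4, 5]  # banked 2 by pass 3, third at pass 5

    def test_executes_floor_calls_over_n_times(self):
        rng = random.Random(17)
        for _ in range(20):
            n = rng.randint(1, 4)
            passes = rng.randint(1, 12)
            g, cs = _graph(["A", "B"], [("A", "B")],
                           conditions={"B": every_n_calls("A", n)},
                           termination=never())
            trace = run_schedule(g, cs, max_passes=passes)
            a_calls = self._trace_nodes(trace).count("A")
            assert self._trace_nodes(trace).count("B") == a_calls // n


class TestExecutionOrder:
    def test_chain_with_always_runs_in_topological_order(self):
        g, cs = _graph(["A", "B", "C"], [("A", "B"), ("B", "C")])
        state = SchedulerState()
        assert next_execution_set(g, cs, state) == ["A", "B", "C"]

    def test_dag_order_equals_kahn_oracle_on_random_dags(self):
        rng = random.Random(23)
        for _ in range(30):
            ids = [f"n{i}" for i in range(rng.randint(2, 7))]
            pairs = sorted({(ids[i], ids[j])
                            for i in range(len(ids))
                            for j in range(i + 1, len(ids))
                            if rng.random() < 0.4})
            g, cs = _graph(ids, pairs)
            got = next_execution_set(g, cs, SchedulerState())
            assert got == oracles.kahn_topological_sort(ids, pairs)

    def test_cyclic_candidates_run_in_declaration_order(self):
        g, cs = _graph(["B", "A"], [("B", "A"), ("A", "B")])
        assert consideration_order(g) == ["B", "A"]


class TestRunSchedule:
    def test_single_node_default_termination(self):
        g, cs = _graph(["A"], [])
        trace = run_schedule(g, cs, max_passes=10)
        assert list(trace) == [(0, "A")] and trace.outcome == "terminated"

    def test_never_satisfied_termination_exhausts_budget(self):
        g, cs = _graph(["A"], [], termination=never())
        trace = run_schedule(g, cs, max_passes=5)
        assert trace.outcome == "budget_exhausted" and len(trace) == 5

    def test_two_node_cycle_three_passes_gives_six_executions(self):
        g, cs = _graph(["A", "B"], [("A", "B"), ("B", "A")],
                       termination=never())
        trace = run_schedule(g, cs, max_passes=3)
        assert len(trace) == 6

    def test_termination_after_third_call_stops_that_pass(self):
        g, cs = _graph(["A", "B", "C"], [("A", "B"), ("B", "C")],
                       termination=after_n_calls("C", 3))
        trace = run_schedule(g, cs, max_passes=100)
        assert trace.outcome == "terminated"
        assert [nid for _, nid in trace].count("C") == 3

    def test_executor_failure_attaches_partial_trace(self):
        g, cs = _graph(["A", "B"], [("A", "B")])

        def boom(nid, state):
            if nid == "B":
                raise RuntimeError("kaput")

        with pytest.raises(ExecutorFailure) as exc:
            run_schedule(g, cs, boom, max_passes=3)
        assert [nid for _, nid in exc.value.trace] == ["A"]

    def test_trace_csv_has_pass_node_clock_columns(self):
        g, cs = _graph(["A"], [])
        csv = run_schedule(g, cs, max_passes=3).to_csv()
        assert csv.splitlines()[0] == "pass,node,clock"
        assert csv.splitlines()[1].startswith("0,A,")


# --------------------------------------------------------------------------
# Randomized agreement with the from-the-definition replay oracle
# --------------------------------------------------------------------------

def _random_condition(rng, ids, depth=2):
    choice = rng.random()
    if depth == 0 or choice < 0.35:
        kind = rng.choice(["always", "never", "every", "after", "before"])
        dep = rng.choice(ids)
        n = rng.randint(1, 3)
        return {"always": always(), "never": never(),
                "every": every_n_calls(dep, n),
                "after": after_n_calls(dep, n),
                "before": before_n_calls(dep, n)}[kind]
    if choice < 0.55:
        return not_(_random_condition(rng, ids, depth - 1))
    combine = all_of if choice < 0.8 else any_of
    return combine(*[_random_condition(rng, ids, depth - 1)
                     for _ in range(rng.randint(1, 2))])


def test_traces_match_replay_oracle_over_randomized_condition_sets():
    rng = random.Random(20240920)
    for trial in range(50):
        ids = [f"n{i}" for i in range(rng.randint(2, 5))]
        pairs = sorted({(rng.choice(ids), rng.choice(ids))
                        for _ in range(rng.randint(0, 6))
                        if True})
        pairs = [(a, b) for a, b in pairs if a != b]
        conditions = {n: _random_condition(rng, ids)
                      for n in ids if rng.random() < 0.8}
        termination = rng.choice(
            [never(), after_n_calls(rng.choice(ids), rng.randint(1, 5)),
             all_have_run()])
        g, cs = _graph(ids, pairs, conditions=conditions,
                       termination=termination)
        trace = run_schedule(g, cs, max_passes=10)
        want, want_outcome = oracles.replay_schedule(
            ids, pairs,
            {n: c.to_tree() for n, c in conditions.items()},
            termination.to_tree(), max_passes=10)
        assert list(trace) == want, f"trial {trial}"
        assert trace.outcome == want_outcome, f"trial {trial}"


def test_identical_inputs_give_identical_traces():
    g, cs = _graph(["A", "B", "C"], [("A", "B")],
                   conditions={"B": every_n_calls("A", 2)},
                   termination=after_n_calls("C", 7))
    t1 = run_schedule(g, cs, max_passes=20)
    g2, cs2 = _graph(["A", "B", "C"], [("A", "B")],
                     conditions={"B": every_n_calls("A", 2)},
                     termination=after_n_calls("C", 7))
    t2 = run_schedule(g2, cs2, max_passes=20)
    assert list(t1) == list(t2) and t1.outcome == t2.outcome
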