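"""Execution engine: node evaluation, Euler integration, full runs."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mdfkit import (
    Edge, Graph, InputPort, Model, Node, OutputPort, Parameter,
    evaluate_node, flatten_hierarchy, make_fixture, run, step_time,
)
from mdfkit.engine import EngineError, ExecutionState
from mdfkit.functions import fitzhugh_nagumo_derivatives
from mdfkit.scheduler import ConditionSet, never
from mdfkit import expressions as xp


class TestEvaluateNode:
    def test_parameter_then_output_chain(self):
        node = Node(id="N",
                    input_ports=[InputPort(id="in1")],
                    parameters=[Parameter(id="p", value="2*in1")],
                    output_ports=[OutputPort(id="out", value="p + 1")])
        out = evaluate_node(node, {"in1": 3.0}, ExecutionState())
        assert out == {"out": 7.0}

    def test_self_referential_parameter_counts(self):
        node = Node(id="N",
                    parameters=[Parameter(id="c", value="c + 1",
                                          default_initial_value=0)],
                    output_ports=[OutputPort(id="out", value="c")])
        state = ExecutionState()
        state.values[("N", "c")] = 0
        seen = []
        for _ in range(3):
            seen.append(evaluate_node(node, {}, state)["out"])
        assert seen == [1, 2, 3]

    def test_nonstateful_mutual_reference_is_an_error(self):
        node = Node(id="N",
                    parameters=[Parameter(id="p", value="q + 1"),
                                Parameter(id="q", value="p + 1")],
                    output_ports=[OutputPort(id="out", value="p")])
        with pytest.raises(EngineError, match="cycle"):
            evaluate_node(node, {}, ExecutionState())

    def test_parameters_resolve_in_dependency_not_declaration_order(self):
        node = Node(id="N",
                    parameters=[Parameter(id="b", value="a * 2"),
                                Parameter(id="a", value=5.0)],
                    output_ports=[OutputPort(id="out", value="b")])
        assert evaluate_node(node, {}, ExecutionState())["out"] == 10.0


class TestStepTime:
    def _decay(self, v0=1.0):
        node = Node(id="N", parameters=[
            Parameter(id="v", default_initial_value=v0, time_derivative="-v")])
        return Model(id="m", graphs=[Graph(id="g", nodes=[node])])

    def test_single_euler_step(self):
        m = self._decay()
        g = m.graph
        state = ExecutionState(dt=0.1)
        state.values[("N", "v")] = 1.0
        step_time(g, state)
        assert state.values[("N", "v")] == pytest.approx(0.9)
        assert state.clock == pytest.approx(0.1)

    def test_exponential_decay_to_t1_with_fine_step(self):
        r = run(self._decay(), dt=1e-4, duration=1.0, record=["N:v"])
        assert abs(r.series("N", "v")[-1] - math.exp(-1)) < 1e-3

    def test_order_one_convergence_halving_ratio(self):
        errors = []
        for dt in (1e-2, 5e-3, 2.5e-3):
            r = run(self._decay(), dt=dt, duration=1.0, record=["N:v"])
            errors.append(abs(r.series("N", "v")[-1] - math.exp(-1)))
        for coarse, fine in zip(errors, errors[1:]):
            assert 0.4 <= fine / coarse <= 0.6

    def test_derivatives_read_prestep_values_simultaneously(self):
        # dv/dt = w, dw/dt = -v from (1, 0): one Euler step must give
        # (1, -dt), not the sequential (1, -dt(1+...)) Gauss-Seidel update.
        node = Node(id="N", parameters=[
            Parameter(id="v", default_initial_value=1.0, time_derivative="w"),
            Parameter(id="w", default_initial_value=0.0, time_derivative="-v")])
        g = Graph(id="g", nodes=[node])
        state = ExecutionState(dt=0.5)
        state.values[("N", "v")] = 1.0
        state.values[("N", "w")] = 0.0
        step_time(g, state)
        assert state.values[("N", "v")] == pytest.approx(1.0)
        assert state.values[("N", "w")] == pytest.approx(-0.5)

    def test_fhn_trajectory_matches_adaptive_oracle_and_oscillates(self):
        m = make_fixture("fhn_neuron", I_ext=0.5)
        r = run(m, dt=0.01, duration=60.0, record=["fhn:V"])
        V = r.series("fhn", "V")
        t = r.times[("fhn", "V")]

        def rhs(_t, y):
            dv, dw = fitzhugh_nagumo_derivatives(y[0], y[1], I_ext=0.5)
            return [float(dv), float(dw)]

        sol = solve_ivp(rhs, [0.0, float(t[-1]) + 1e-9], [0.0, 0.0],
                        t_eval=t, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(V - sol.y[0])) < 0.05
        # relaxation oscillation: suprathreshold excursions recur
        crossings = np.sum((V[:-1] < 1.0) & (V[1:] >= 1.0))
        assert crossings >= 2


class TestRun:
    def test_feedforward_chain_computes_composition(self):
        r = run(make_fixture("ffn_abc"), max_passes=10)
        assert r.value("C", "out") == pytest.approx(7.0)
        assert r.outcome == "terminated"
        assert len(r.trace) == 3  # one pass

    def test_requires_exactly_one_budget(self):
        m = make_fixture("ffn_abc")
        with pytest.raises(ValueError):
            run(m)
        with pytest.raises(ValueError):
            run(m, duration=1.0, dt=0.1, max_passes=5)

    def test_ddm_noise_free_ramp(self):
        m = make_fixture("ddm_accumulator", drift_rate=1.0, noise_coeff=0.0)
        r = run(m, dt=0.1, duration=1.0, record=["ddm:x"], seed=3)
        np.testing.assert_allclose(r.series("ddm", "x"),
                                   np.arange(1, 11) * 0.1, atol=1e-12)

    def test_seeded_runs_are_bit_identical(self):
        m = make_fixture("ddm_accumulator")
        r1 = run(m, dt=0.1, duration=1.0, record=["ddm:x"], seed=42)
        r2 = run(m, dt=0.1, duration=1.0, record=["ddm:x"], seed=42)
        assert r1.series("ddm", "x").tobytes() == r2.series("ddm", "x").tobytes()
        assert r1.to_csv() == r2.to_csv()

    def test_different_seeds_differ(self):
        m = make_fixture("ddm_accumulator")
        r1 = run(m, dt=0.1, duration=1.0, record=["ddm:x"], seed=1)
        r2 = run(m, dt=0.1, duration=1.0, record=["ddm:x"], seed=2)
        assert not np.array_equal(r1.series("ddm", "x"), r2.series("ddm", "x"))

    def test_dag_fixture_equals_single_pass_topological_oracle(self):
        """Independent oracle: evaluate each node once in topological order
        using the expression evaluator directly."""
        m = make_fixture("ffn_abc")
        g = m.graph
        from mdfkit.functions import standard_registry
        import oracles
        order = oracles.kahn_topological_sort(
            g.node_ids(), [(e.sender, e.receiver) for e in g.edges])
        values = {}
        for nid in order:
            node = g.get_node(nid)
            env = {}
            for e in g.edges:
                if e.receiver == nid:
                    env[e.receiver_port] = values[(e.sender, e.sender_port)] \
                        * e.weight
            for p in node.parameters:
                env[p.id] = xp.evaluate(p.value, env, standard_registry()) \
                    if isinstance(p.value, str) else p.value
            for port in node.output_ports:
                values[(nid, port.id)] = xp.evaluate(port.value, env,
                                                     standard_registry())
        r = run(m, max_passes=5)
        for key, want in values.items():
            assert r.state.values[key] == want  # exact, tolerance 0

    def test_hierarchical_model_equals_its_flattened_form(self):
        m = make_fixture("nested_model", depth=2)
        r_nested = run(m, max_passes=10)
        r_flat = run(flatten_hierarchy(m), max_passes=10)
        assert r_nested.value("post", "out") == r_flat.value("post", "out")

    def test_edge_weight_scales_linear_output(self):
        def build(w):
            a = Node(id="A", parameters=[Parameter(id="x", value=3.0)],
                     output_ports=[OutputPort(id="out", value="x")])
            b = Node(id="B", input_ports=[InputPort(id="in1")],
                     output_ports=[OutputPort(id="out", value="in1 * 5")])
            g = Graph(id="g", nodes=[a, b], edges=[
                Edge(id="e", sender="A", sender_port="out",
                     receiver="B", receiver_port="in1", weight=w)])
            return Model(id="m", graphs=[g])

        base = run(build(1.0), max_passes=3).value("B", "out")
        scaled = run(build(2.5), max_passes=3).value("B", "out")
        assert scaled == pytest.approx(2.5 * base)

    def test_fan_in_with_sum_reduce(self):
        a = Node(id="A", parameters=[Parameter(id="x", value=2.0)],
                 output_ports=[OutputPort(id="out", value="x")])
        b = Node(id="B", parameters=[Parameter(id="x", value=3.0)],
                 output_ports=[OutputPort(id="out", value="x")])
        c = Node(id="C", input_ports=[InputPort(id="in1", reduce="sum")],
                 output_ports=[OutputPort(id="out", value="in1")])
        g = Graph(id="g", nodes=[a, b, c], edges=[
            Edge(id="e1", sender="A", sender_port="out",
                 receiver="C", receiver_port="in1"),
            Edge(id="e2", sender="B", sender_port="out",
                 receiver="C", receiver_port="in1", weight=2.0)])
        r = run(Model(id="m", graphs=[g]), max_passes=3)
        assert r.value("C", "out") == pytest.approx(2.0 + 6.0)

    def test_unconnected_input_reads_zero_with_warning(self):
        n = Node(id="N", input_ports=[InputPort(id="in1")],
                 output_ports=[OutputPort(id="out", value="in1 + 1")])
        r = run(Model(id="m", graphs=[Graph(id="g", nodes=[n])]), max_passes=2)
        assert r.value("N", "out") == 1.0
        assert r.warnings["unconnected_input"] >= 1

    def test_cyclic_pair_reads_previous_pass_values(self):
        m = make_fixture("cyclic_pair", gain=1.0)
        m.graph.conditions = ConditionSet(termination=never())
        r = run(m, max_passes=4, record=["A:out", "B:out"])
        # A: in_b + 1 with in_b from the previous pass; B echoes A.
        np.testing.assert_allclose(r.series("A", "out"), [1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(r.series("B", "out"), [1.0, 2.0, 3.0, 4.0])

    def test_nonfinite_state_raises_after_warning_budget(self):
        node = Node(id="N", parameters=[
            Parameter(id="v", default_initial_value=1.0,
                      time_derivative="v * v * 1e6")])
        m = Model(id="m", graphs=[Graph(id="g", nodes=[node])])
        from mdfkit.engine import NonFiniteError
        with pytest.raises(NonFiniteError):
            run(m, dt=10.0, duration=1000.0, warning_limit=3)

    def test_csv_export_shape(self):
        m = make_fixture("ddm_accumulator", drift_rate=1.0, noise_coeff=0.0)
        csv = run(m, dt=0.5, duration=1.0, record=["ddm:x"], seed=0).to_csv()
        lines = csv.strip().splitlines()
        assert lines[0] == "clock,ddm:x"
        assert len(lines) == 3  # header + 2 passes


def test_multiple_timescales_via_conditions():
    """A slow node gated every_n_calls(fast, 2) accumulates every other
    fast output — the condition system realizes two timescales."""
    m = make_fixture("condition_demo")
    r = run(m, max_passes=50, record=["slow:total"])
    assert r.outcome == "terminated"
    # fast output at its 2nd, 4th, ... call is 2, 4, ...; partial sums:
    np.testing.assert_allclose(r.series("slow", "total"),
                               [2.0, 6.0, 12.0, 20.0, 30.0])
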