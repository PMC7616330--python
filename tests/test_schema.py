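"""Document object model: validation, cycle detection, flattening."""

import random

import pytest

from mdfkit import (
    Edge, Graph, InputPort, Model, Node, OutputPort, Parameter,
    detect_cycles, flatten_hierarchy, make_fixture, models_equal,
    validate_model,
)
from mdfkit.schema import FlattenError, cycle_edges

import oracles


def _chain(ids, with_defaults=False):
    nodes = []
    edges = []
    for nid in ids:
        nodes.append(Node(
            id=nid, input_ports=[InputPort(id="in1")],
            output_ports=[OutputPort(
                id="out", value="in1 + 1",
                default_initial_value=0.0 if with_defaults else None)]))
    for a, b in zip(ids, ids[1:]):
        edges.append(Edge(id=f"{a}{b}", sender=a, sender_port="out",
                          receiver=b, receiver_port="in1"))
    return Graph(id="g", nodes=nodes, edges=edges)


class TestValidateModel:
    def test_empty_model_with_one_empty_graph_is_valid(self):
        report = validate_model(Model(id="m", graphs=[Graph(id="g")]))
        assert len(report) == 0 and report.ok

    def test_edge_to_nonexistent_node_is_one_error_at_that_edge(self):
        g = Graph(id="g", nodes=[Node(id="A", output_ports=[
            OutputPort(id="out", value="1")])],
            edges=[Edge(id="bad", sender="A", sender_port="out",
                        receiver="X", receiver_port="in1")])
        report = validate_model(Model(id="m", graphs=[g]))
        errors = report.errors
        assert len(errors) == 1
        assert "edge bad" in errors[0].location and "X" in errors[0].message

    def test_two_node_cycle_with_initial_values_is_info_not_error(self):
        g = _chain(["A", "B"], with_defaults=True)
        g.edges.append(Edge(id="back", sender="B", sender_port="out",
                            receiver="A", receiver_port="in1"))
        report = validate_model(Model(id="m", graphs=[g]))
        assert report.ok
        infos = [i for i in report if i.severity == "info"]
        assert len(infos) == 1 and "cycle" in infos[0].message

    def test_cycle_feeding_port_without_initial_value_is_an_error(self):
        g = _chain(["A", "B"])
        g.edges.append(Edge(id="back", sender="B", sender_port="out",
                            receiver="A", receiver_port="in1"))
        report = validate_model(Model(id="m", graphs=[g]))
        assert not report.ok
        assert any("default_initial_value" in e.message for e in report.errors)

    def test_duplicate_node_ids_rejected(self):
        g = Graph(id="g", nodes=[Node(id="A"), Node(id="A")])
        report = validate_model(Model(id="m", graphs=[g]))
        assert any("duplicate node id" in e.message for e in report.errors)

    def test_stateful_parameter_requires_initial_value(self):
        node = Node(id="A", parameters=[Parameter(id="c", value="c + 1")])
        report = validate_model(Model(id="m", graphs=[Graph(id="g", nodes=[node])]))
        assert any("default_initial_value" in e.message for e in report.errors)

    def test_nonstateful_parameter_reference_cycle_rejected(self):
        node = Node(id="A", parameters=[Parameter(id="p", value="q + 1"),
                                        Parameter(id="q", value="p + 1")])
        report = validate_model(Model(id="m", graphs=[Graph(id="g", nodes=[node])]))
        assert any("reference cycle" in e.message for e in report.errors)

    def test_fan_in_requires_sum_reduce_policy(self):
        g = Graph(id="g", nodes=[
            Node(id="A", output_ports=[OutputPort(id="out", value="1")]),
            Node(id="B", output_ports=[OutputPort(id="out", value="2")]),
            Node(id="C", input_ports=[InputPort(id="in1")],
                 output_ports=[OutputPort(id="out", value="in1")]),
        ], edges=[
            Edge(id="e1", sender="A", sender_port="out",
                 receiver="C", receiver_port="in1"),
            Edge(id="e2", sender="B", sender_port="out",
                 receiver="C", receiver_port="in1"),
        ])
        report = validate_model(Model(id="m", graphs=[g]))
        assert any("reduce" in e.message for e in report.errors)
        g.nodes[2].input_ports[0].reduce = "sum"
        assert validate_model(Model(id="m", graphs=[g])).ok

    def test_output_port_referencing_foreign_id_rejected(self):
        node = Node(id="A", output_ports=[OutputPort(id="out", value="ghost + 1")])
        report = validate_model(Model(id="m", graphs=[Graph(id="g", nodes=[node])]))
        assert any("ghost" in e.message for e in report.errors)

    def test_unknown_function_and_missing_arg_rejected(self):
        from mdfkit.schema import FunctionCall
        node = Node(id="A",
                    functions=[FunctionCall(id="f", function="conv2d"),
                               FunctionCall(id="g", function="add",
                                            args={"a": "1"})],
                    output_ports=[OutputPort(id="out", value="f")])
        report = validate_model(Model(id="m", graphs=[Graph(id="g", nodes=[node])]))
        msgs = [e.message for e in report.errors]
        assert any("conv2d" in m for m in msgs)
        assert any("missing required argument 'b'" in m for m in msgs)

    def test_validation_is_idempotent(self, fixture_model):
        first = [str(i) for i in validate_model(fixture_model)]
        second = [str(i) for i in validate_model(fixture_model)]
        assert first == second


class TestDetectCycles:
    def test_chain_has_no_cycles(self):
        assert detect_cycles(_chain(["A", "B", "C"])) == []

    def test_two_node_cycle(self):
        g = _chain(["A", "B"], with_defaults=True)
        g.edges.append(Edge(id="back", sender="B", sender_port="out",
                            receiver="A", receiver_port="in1"))
        assert detect_cycles(g) == [["A", "B"]]

    def test_complete_digraph_on_three_nodes_has_five_circuits(self):
        ids = ["A", "B", "C"]
        nodes = [Node(id=n, input_ports=[InputPort(id="in1", reduce="sum")],
                      output_ports=[OutputPort(id="out", value="in1",
                                               default_initial_value=0.0)])
                 for n in ids]
        edges = [Edge(id=f"{a}{b}", sender=a, sender_port="out",
                      receiver=b, receiver_port="in1")
                 for a in ids for b in ids if a != b]
        g = Graph(id="g", nodes=nodes, edges=edges)
        got = detect_cycles(g)
        want = oracles.brute_force_cycles(ids, [(e.sender, e.receiver)
                                                for e in edges])
        assert got == want
        assert len(got) == 5

    def test_matches_brute_force_on_random_digraphs(self):
        rng = random.Random(99)
        for _ in range(30):
            ids = [f"n{i}" for i in range(rng.randint(2, 6))]
            pairs = sorted({(rng.choice(ids), rng.choice(ids))
                            for _ in range(rng.randint(1, 10))})
            nodes = [Node(id=n, input_ports=[InputPort(id="in1", reduce="sum")],
                          output_ports=[OutputPort(id="out", value="in1",
                                                   default_initial_value=0.0)])
                     for n in ids]
            edges = [Edge(id=f"e{i}", sender=a, sender_port="out",
                          receiver=b, receiver_port="in1")
                     for i, (a, b) in enumerate(pairs)]
            g = Graph(id="g", nodes=nodes, edges=edges)
            assert detect_cycles(g) == oracles.brute_force_cycles(ids, pairs)

    def test_cycle_edges_marks_only_edges_on_circuits(self):
        g = _chain(["A", "B", "C"], with_defaults=True)
        g.edges.append(Edge(id="back", sender="B", sender_port="out",
                            receiver="A", receiver_port="in1"))
        assert cycle_edges(g) == {("A", "B"), ("B", "A")}


class TestFlattenHierarchy:
    def test_flat_model_is_unchanged(self):
        m = make_fixture("ffn_abc")
        assert models_equal(flatten_hierarchy(m), m)

    def test_single_wrapper_namespaces_inner_node_and_rewires(self):
        m = make_fixture("nested_model")
        flat = flatten_hierarchy(m)
        ids = flat.graph.node_ids()
        assert "P.Q" in ids and "P" not in ids
        receivers = {(e.receiver, e.receiver_port) for e in flat.graph.edges}
        senders = {(e.sender, e.sender_port) for e in flat.graph.edges}
        assert ("P.Q", "in1") in receivers and ("P.Q", "out") in senders
        assert validate_model(flat).ok

    def test_two_level_nesting_produces_dotted_path(self):
        flat = flatten_hierarchy(make_fixture("nested_model", depth=2))
        assert "P.W1.Q" in flat.graph.node_ids()

    def test_flattening_is_idempotent(self):
        m = make_fixture("nested_model", depth=2)
        once = flatten_hierarchy(m)
        twice = flatten_hierarchy(once)
        assert models_equal(once, twice)

    def test_ambiguous_boundary_port_is_an_error(self):
        inner = Graph(id="inner", nodes=[
            Node(id="Q1", input_ports=[InputPort(id="in1")],
                 output_ports=[OutputPort(id="out", value="in1")]),
            Node(id="Q2", input_ports=[InputPort(id="in1")],
                 output_ports=[OutputPort(id="o2", value="in1")]),
        ])
        wrapper = Node(id="P", input_ports=[InputPort(id="in1")],
                       output_ports=[OutputPort(id="out")], subgraph=inner)
        m = Model(id="m", graphs=[Graph(id="g", nodes=[wrapper])])
        with pytest.raises(FlattenError, match="in1"):
            flatten_hierarchy(m)
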