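"""Structural visualization (Graphviz DOT) and a flat tensor-graph bridge.

The tensor-graph dialect is a minimal single-assignment JSON form —
named graph inputs, a list of ops drawn from the core operator set, named
outputs — of the kind ML exchange formats use.  Import turns each op into
a node with one function call; export accepts only the fragment whose
semantics the dialect can carry (acyclic, unconditioned, stateless,
core-set functions) and fails loudly on anything else: silent semantic
drift is precisely what a standardized interchange format exists to
prevent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .functions import CORE_OPERATOR_NAMES, standard_registry
from .schema import (
    Edge, FunctionCall, Graph, InvalidModelError, Model, Node, InputPort,
    OutputPort, Parameter, detect_cycles, validate_model,
)
from .scheduler import ConditionSet
from . import expressions as xp

__all__ = [
    "to_dot", "TensorGraphDoc", "TensorOp",
    "import_tensor_graph", "export_tensor_graph", "ExportError",
]


# --------------------------------------------------------------------------
# DOT export
# --------------------------------------------------------------------------

def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _record_label(node: Node) -> str:
    def esc(s: str) -> str:
        for ch in "\\{}|<>\"":
            s = s.replace(ch, "\\" + ch)
        return s

    parts = [esc(node.id)]
    if node.input_ports:
        parts.append("in: " + ", ".join(esc(p.id) for p in node.input_ports))
    if node.parameters:
        parts.append("params: " + ", ".join(
            esc(f"{p.id}{'*' if p.stateful else ''}") for p in node.parameters))
    if node.functions:
        parts.append("fn: " + ", ".join(
            esc(f"{f.id}={f.function}") for f in node.functions))
    if node.output_ports:
        parts.append("out: " + ", ".join(
            esc(f"{p.id}={p.value}") for p in node.output_ports))
    if node.subgraph is not None:
        parts.append(f"subgraph: {esc(node.subgraph.id)}")
    return "{" + " | ".join(parts) + "}"


def to_dot(model: Model, detail: str = "nodes_only") -> str:
    """Render the model's graphs as deterministic Graphviz DOT text.

    ``nodes_only`` draws one DOT node per model node and one DOT edge per
    model edge; ``full`` uses record-shaped nodes listing ports,
    parameters and functions.  Ids are emitted sorted, so identical models
    produce identical text.
    """
    if detail not in ("nodes_only", "full"):
        raise ValueError(f"unknown detail level {detail!r}")
    report = validate_model(model)
    if not report.ok:
        raise InvalidModelError(f"cannot render invalid model {model.id!r}", report)

    lines = [f"digraph {_dot_quote(model.id)} {{"]
    if detail == "full":
        lines.append("  node [shape=record];")
    for graph in sorted(model.graphs, key=lambda g: g.id):
        indent = "  "
        if len(model.graphs) > 1:
            lines.append(f"  subgraph {_dot_quote('cluster_' + graph.id)} {{")
            lines.append(f"    label={_dot_quote(graph.id)};")
            indent = "    "
        for node in sorted(graph.nodes, key=lambda n: n.id):
            if detail == "full":
                lines.append(
                    f"{indent}{_dot_quote(node.id)} "
                    f"[label={_dot_quote(_record_label(node))}];")
            else:
                lines.append(f"{indent}{_dot_quote(node.id)};")
        for e in sorted(graph.edges,
                        key=lambda e: (e.sender, e.receiver, e.id)):
            attrs = f" [label={_dot_quote(e.sender_port + '->' + e.receiver_port)}]" \
                if detail == "full" else ""
            lines.append(f"{indent}{_dot_quote(e.sender)} -> "
                         f"{_dot_quote(e.receiver)}{attrs};")
        if len(model.graphs) > 1:
            lines.append("  }")
    lines.append("}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Tensor-graph dialect
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TensorOp:
    op: str  # name from the core operator set
    inputs: tuple[str, ...]  # value names
    output: str  # value name (single assignment)
    attributes: Mapping[str, object] = field(default_factory=dict)


@dataclass
class TensorGraphDoc:
    """A flat single-assignment tensor graph: inputs → ops → outputs."""

    inputs: dict[str, dict] = field(default_factory=dict)  # name -> spec
    outputs: list[str] = field(default_factory=list)
    ops: list[TensorOp] = field(default_factory=list)

    def validate(self) -> None:
        defined = set(self.inputs)
        for op in self.ops:
            if op.op not in CORE_OPERATOR_NAMES:
                raise ValueError(f"unknown op name {op.op!r}")
            for name in op.inputs:
                if name not in defined:
                    raise ValueError(
                        f"op {op.op!r}: value {name!r} used before assignment")
            if op.output in defined:
                raise ValueError(f"multiple assignment of value {op.output!r}")
            defined.add(op.output)
        for name in self.outputs:
            if name not in defined:
                raise ValueError(f"graph output {name!r} is never assigned")

    def to_json(self) -> str:
        return json.dumps({
            "inputs": self.inputs,
            "ops": [
                {"op": o.op, "inputs": list(o.inputs), "output": o.output,
                 **({"attributes": dict(o.attributes)} if o.attributes else {})}
                for o in self.ops
            ],
            "outputs": self.outputs,
        }, indent=2)

    @staticmethod
    def from_json(text: str) -> "TensorGraphDoc":
        raw = json.loads(text)
        doc = TensorGraphDoc(
            inputs={k: dict(v) for k, v in raw.get("inputs", {}).items()},
            outputs=list(raw.get("outputs", [])),
            ops=[TensorOp(op=o["op"], inputs=tuple(o["inputs"]),
                          output=o["output"],
                          attributes=o.get("attributes", {}))
                 for o in raw.get("ops", [])],
        )
        doc.validate()
        return doc


def import_tensor_graph(doc: TensorGraphDoc, model_id: str = "tensor_model"
                        ) -> Model:
    """Build a model from a tensor-graph document.

    Each graph input becomes a parameter-fed source node (parameter
    ``value``, output port ``out``); each op becomes a node with one
    function call; value names become edges.  The result validates clean.
    """
    doc.validate()
    nodes: list[Node] = []
    edges: list[Edge] = []
    producer: dict[str, str] = {}  # value name -> node id

    for name, spec in doc.inputs.items():
        nodes.append(Node(
            id=name,
            parameters=[Parameter(id="value", value=spec.get("value", 0.0))],
            output_ports=[OutputPort(id="out", value="value")],
        ))
        producer[name] = name

    for i, op in enumerate(doc.ops):
        nid = f"op{i}_{op.op}"
        in_ports = [InputPort(id=f"in{j}") for j in range(len(op.inputs))]
        fdef = standard_registry().lookup(op.op)
        args: dict[str, object] = {}
        for spec, port in zip(fdef.arg_spec, in_ports):
            args[spec.name] = port.id
        for key, val in op.attributes.items():
            args[key] = val
        nodes.append(Node(
            id=nid,
            input_ports=in_ports,
            functions=[FunctionCall(id="f", function=op.op, args=args)],
            output_ports=[OutputPort(id="out", value="f")],
        ))
        for j, value_name in enumerate(op.inputs):
            edges.append(Edge(
                id=f"e{len(edges)}",
                sender=producer[value_name], sender_port="out",
                receiver=nid, receiver_port=f"in{j}",
            ))
        producer[op.output] = nid

    model = Model(id=model_id, graphs=[Graph(id="g", nodes=nodes, edges=edges)])
    model.metadata["tensor_graph_outputs"] = {
        name: producer[name] for name in doc.outputs}
    report = validate_model(model)
    if not report.ok:  # pragma: no cover - construction rule guarantees validity
        raise InvalidModelError("tensor-graph import produced an invalid model",
                                report)
    return model


class ExportError(ValueError):
    """The model steps outside the exportable tensor-graph fragment."""


def _exportable_op_node(node: Node) -> FunctionCall:
    """Check the op-node shape and return its single function call."""
    if len(node.functions) != 1:
        raise ExportError(
            f"node {node.id!r}: exportable op nodes carry exactly one "
            f"function call, found {len(node.functions)}")
    fc = node.functions[0]
    if fc.function not in CORE_OPERATOR_NAMES:
        raise ExportError(
            f"node {node.id!r}: function {fc.function!r} is outside the "
            "core operator set")
    if len(node.output_ports) != 1 or node.output_ports[0].value != fc.id:
        raise ExportError(
            f"node {node.id!r}: exportable op nodes expose exactly one "
            "output port whose value is the function result")
    return fc


def export_tensor_graph(model: Model) -> TensorGraphDoc:
    """Translate the exportable fragment of a model to the dialect.

    The fragment: one acyclic graph, always/absent conditions, no stateful
    parameters or ODE states, no subgraphs, and nodes shaped as either
    parameter-fed sources or single-call core-operator applications.
    Anything else raises :class:`ExportError` naming the construct.
    """
    report = validate_model(model)
    if not report.ok:
        raise InvalidModelError(f"cannot export invalid model {model.id!r}", report)
    graph = model.graph
    if detect_cycles(graph):
        raise ExportError(f"graph {graph.id!r} is cyclic")
    cs = graph.conditions
    if isinstance(cs, ConditionSet):
        for nid, cond in cs.node_specific.items():
            if cond.type != "always":
                raise ExportError(
                    f"node {nid!r} carries a {cond.type!r} condition")
        term = cs.termination
        if term is not None and term.type != "all_have_run":
            raise ExportError(f"termination condition {term.type!r}")

    for node in graph.nodes:
        if node.subgraph is not None:
            raise ExportError(f"node {node.id!r} wraps a subgraph")
        for p in node.parameters:
            if p.stateful:
                raise ExportError(
                    f"node {node.id!r}: parameter {p.id!r} is stateful")

    doc = TensorGraphDoc()
    out_value: dict[tuple[str, str], str] = {}  # (node, port) -> value name
    incoming: dict[str, dict[str, tuple[str, str]]] = {}
    for e in graph.edges:
        if e.weight != 1:
            raise ExportError(
                f"edge {e.id!r}: weighted edges are outside the fragment")
        incoming.setdefault(e.receiver, {})[e.receiver_port] = (
            e.sender, e.sender_port)

    from .scheduler import consideration_order

    for nid in consideration_order(graph):
        node = graph.get_node(nid)
        if not node.input_ports:
            # Source node: a single constant-valued parameter and an output
            # port exposing it.
            if (len(node.parameters) != 1 or node.functions
                    or len(node.output_ports) != 1):
                raise ExportError(
                    f"node {nid!r}: source nodes carry exactly one parameter "
                    "and one output port")
            p = node.parameters[0]
            if isinstance(p.value, str) and xp.free_identifiers(p.value):
                raise ExportError(
                    f"node {nid!r}: source parameter {p.id!r} must be constant")
            if node.output_ports[0].value != p.id:
                raise ExportError(
                    f"node {nid!r}: source output port must expose the "
                    f"parameter {p.id!r} directly")
            doc.inputs[nid] = {"value": p.value}
            out_value[(nid, node.output_ports[0].id)] = nid
            continue
        fc = _exportable_op_node(node)
        fdef = standard_registry().lookup(fc.function)
        port_args: list[str] = []
        attributes: dict[str, object] = {}
        port_ids = {p.id for p in node.input_ports}
        for spec in fdef.arg_spec:
            if spec.name not in fc.args:
                continue
            val = fc.args[spec.name]
            if isinstance(val, str) and val in port_ids:
                port_args.append(val)
            else:
                attributes[spec.name] = val
        if len(port_args) != len(node.input_ports):
            raise ExportError(
                f"node {nid!r}: every input port must feed one function "
                "argument directly")
        value_names = []
        for pid in port_args:
            try:
                src = incoming[nid][pid]
            except KeyError:
                raise ExportError(
                    f"node {nid!r}: input port {pid!r} is unconnected") from None
            value_names.append(out_value[src])
        vname = f"{nid}_out"
        doc.ops.append(TensorOp(op=fc.function, inputs=tuple(value_names),
                                output=vname, attributes=attributes))
        out_value[(nid, node.output_ports[0].id)] = vname

    declared = model.metadata.get("tensor_graph_outputs")
    if isinstance(declared, dict) and declared:
        doc.outputs = [
            pnid if not graph.get_node(pnid).input_ports else f"{pnid}_out"
            for pnid in declared.values()
        ]
    else:
        # Terminal ports (feeding no edge) are the graph outputs.
        fed = {(e.sender, e.sender_port) for e in graph.edges}
        doc.outputs = [v for key, v in out_value.items() if key not in fed]
    doc.validate()
    return doc
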