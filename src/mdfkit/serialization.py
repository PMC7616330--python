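"""Reading and writing model documents in JSON, YAML and binary form.

All three encodings carry the identical document tree; the binary encoding
is the MessagePack framing of that same tree.  Writing is canonical and
deterministic: map keys appear in schema-defined order, collections are
maps keyed by id (diff-friendly, order recovered from key order), optional
fields at their defaults are omitted, and floats render in the shortest
form that round-trips exactly.

Forward compatibility on read: unknown keys are preserved into the nearest
``metadata`` map with a warning instead of being rejected.

JSON cannot represent non-finite floats; they are written as the strings
``"NaN"`` / ``"Infinity"`` / ``"-Infinity"`` and restored on read (outside
metadata, which is left untouched).  YAML and binary carry them natively.
"""

from __future__ import annotations

import json
import math
import warnings as _warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import _binary
from .schema import (
    Edge, FunctionCall, Graph, InputPort, InvalidModelError, Model, Node,
    OutputPort, Parameter, validate_model,
)

__all__ = [
    "SerializedDocument", "write", "read", "convert", "write_file",
    "to_tree", "model_from_tree", "copy_model", "models_equal",
    "DocumentSyntaxError", "SchemaViolationError", "UnsupportedVersionError",
    "ENCODINGS", "extension_for", "encoding_for_path",
]

ENCODINGS = ("json", "yaml", "binary")
_EXTENSIONS = {"json": ".json", "yaml": ".yaml", "binary": ".mdf.bin"}
_SUPPORTED_FORMAT_PREFIX = "MDF v0"


class DocumentSyntaxError(ValueError):
    """Payload is not syntactically valid in its encoding."""

    def __init__(self, message: str, offset: int | None = None):
        loc = "" if offset is None else f" (at offset {offset})"
        super().__init__(message + loc)
        self.offset = offset


class SchemaViolationError(ValueError):
    """A known key holds a value of the wrong kind."""


class UnsupportedVersionError(ValueError):
    pass


@dataclass(frozen=True)
class SerializedDocument:
    encoding: str  # json | yaml | binary
    payload: bytes
    schema_version: str = "MDF v0.1"

    @property
    def text(self) -> str:
        if self.encoding == "binary":
            raise ValueError("binary documents have no text form")
        return self.payload.decode("utf-8")


def extension_for(encoding: str) -> str:
    return _EXTENSIONS[encoding]


def encoding_for_path(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".json"):
        return "json"
    if name.endswith((".yaml", ".yml")):
        return "yaml"
    if name.endswith((".mdf.bin", ".bin", ".msgpack")):
        return "binary"
    raise ValueError(f"cannot infer encoding from path {name!r}")


# --------------------------------------------------------------------------
# Model -> tree
# --------------------------------------------------------------------------

def _scalar(v):
    if isinstance(v, np.generic):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (list, tuple)):
        return [_scalar(x) for x in v]
    return v


def _maybe(tree: dict, key: str, value) -> None:
    if value is None:
        return
    if isinstance(value, (dict, list)) and not value:
        return
    tree[key] = value


def _input_port_tree(p: InputPort) -> dict:
    t: dict = {}
    if p.shape is not None:
        t["shape"] = [int(s) for s in p.shape]
    if p.reduce != "error":
        t["reduce"] = p.reduce
    _maybe(t, "metadata", dict(p.metadata))
    return t


def _output_port_tree(p: OutputPort) -> dict:
    t: dict = {"value": p.value}
    _maybe(t, "default_initial_value", _scalar(p.default_initial_value))
    _maybe(t, "metadata", dict(p.metadata))
    return t


def _parameter_tree(p: Parameter) -> dict:
    t: dict = {}
    _maybe(t, "value", _scalar(p.value))
    _maybe(t, "default_initial_value", _scalar(p.default_initial_value))
    _maybe(t, "time_derivative", p.time_derivative)
    _maybe(t, "metadata", dict(p.metadata))
    return t


def _function_tree(f: FunctionCall) -> dict:
    t: dict = {"function": f.function}
    _maybe(t, "args", {k: _scalar(v) for k, v in f.args.items()})
    _maybe(t, "metadata", dict(f.metadata))
    return t


def _edge_tree(e: Edge) -> dict:
    t: dict = {
        "sender": e.sender,
        "sender_port": e.sender_port,
        "receiver": e.receiver,
        "receiver_port": e.receiver_port,
    }
    if e.weight != 1:
        t["weight"] = _scalar(e.weight)
    _maybe(t, "metadata", dict(e.metadata))
    return t


def _node_tree(n: Node) -> dict:
    t: dict = {}
    _maybe(t, "input_ports", {p.id: _input_port_tree(p) for p in n.input_ports})
    _maybe(t, "parameters", {p.id: _parameter_tree(p) for p in n.parameters})
    _maybe(t, "functions", {f.id: _function_tree(f) for f in n.functions})
    _maybe(t, "output_ports", {p.id: _output_port_tree(p) for p in n.output_ports})
    if n.subgraph is not None:
        # Embedded subgraphs carry their id explicitly (top-level graphs
        # are keyed by id in the graphs map instead).
        t["subgraph"] = {"id": n.subgraph.id, **_graph_tree(n.subgraph)}
    _maybe(t, "metadata", dict(n.metadata))
    return t


def _graph_tree(g: Graph) -> dict:
    t: dict = {}
    _maybe(t, "nodes", {n.id: _node_tree(n) for n in g.nodes})
    _maybe(t, "edges", {e.id: _edge_tree(e) for e in g.edges})
    if g.conditions is not None:
        _maybe(t, "conditions", g.conditions.to_tree())
    _maybe(t, "metadata", dict(g.metadata))
    return t


def to_tree(model: Model) -> dict:
    """Canonical document tree: ``{model_id: {format, graphs, metadata}}``."""
    body: dict = {"format": model.format_version}
    _maybe(body, "graphs", {g.id: _graph_tree(g) for g in model.graphs})
    _maybe(body, "metadata", dict(model.metadata))
    return {model.id: body}


# --------------------------------------------------------------------------
# tree -> Model
# --------------------------------------------------------------------------

class _Reader:
    def __init__(self):
        self.warnings: list[str] = []

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        _warnings.warn(msg, UserWarning, stacklevel=4)

    def expect_map(self, v, what: str) -> dict:
        if not isinstance(v, dict):
            raise SchemaViolationError(f"{what} must be a map, got {type(v).__name__}")
        return v

    def expect_str(self, v, what: str) -> str:
        if not isinstance(v, str):
            raise SchemaViolationError(
                f"{what} must be a string, got {type(v).__name__}")
        return v

    def split(self, tree: dict, known: tuple[str, ...], where: str) -> tuple[dict, dict]:
        tree = self.expect_map(tree, where)
        metadata = dict(self.expect_map(tree.get("metadata", {}), f"{where}.metadata"))
        rest = {}
        for key, val in tree.items():
            if key == "metadata":
                continue
            if key in known:
                rest[key] = val
            else:
                self.warn(f"{where}: unknown key {key!r} preserved in metadata")
                metadata[key] = val
        return rest, metadata

    def input_port(self, pid: str, tree, where: str) -> InputPort:
        rest, meta = self.split(tree, ("shape", "reduce"), where)
        shape = rest.get("shape")
        if shape is not None:
            if not isinstance(shape, list) or not all(
                    isinstance(s, int) and not isinstance(s, bool) for s in shape):
                raise SchemaViolationError(f"{where}.shape must be a list of integers")
            shape = tuple(shape)
        reduce_ = rest.get("reduce", "error")
        return InputPort(id=pid, shape=shape,
                         reduce=self.expect_str(reduce_, f"{where}.reduce"),
                         metadata=meta)

    def output_port(self, pid: str, tree, where: str) -> OutputPort:
        rest, meta = self.split(tree, ("value", "default_initial_value"), where)
        return OutputPort(
            id=pid,
            value=self.expect_str(rest.get("value", ""), f"{where}.value"),
            default_initial_value=rest.get("default_initial_value"),
            metadata=meta,
        )

    def parameter(self, pid: str, tree, where: str) -> Parameter:
        rest, meta = self.split(
            tree, ("value", "default_initial_value", "time_derivative"), where)
        td = rest.get("time_derivative")
        if td is not None:
            td = self.expect_str(td, f"{where}.time_derivative")
        return Parameter(
            id=pid, value=rest.get("value"),
            default_initial_value=rest.get("default_initial_value"),
            time_derivative=td, metadata=meta,
        )

    def function(self, fid: str, tree, where: str) -> FunctionCall:
        rest, meta = self.split(tree, ("function", "args"), where)
        return FunctionCall(
            id=fid,
            function=self.expect_str(rest.get("function", ""), f"{where}.function"),
            args=dict(self.expect_map(rest.get("args", {}), f"{where}.args")),
            metadata=meta,
        )

    def edge(self, eid: str, tree, where: str) -> Edge:
        rest, meta = self.split(
            tree, ("sender", "sender_port", "receiver", "receiver_port", "weight"),
            where)
        weight = rest.get("weight", 1)
        if not isinstance(weight, (int, float)) or isinstance(weight, bool):
            raise SchemaViolationError(f"{where}.weight must be a number")
        return Edge(
            id=eid,
            sender=self.expect_str(rest.get("sender", ""), f"{where}.sender"),
            sender_port=self.expect_str(rest.get("sender_port", ""),
                                        f"{where}.sender_port"),
            receiver=self.expect_str(rest.get("receiver", ""), f"{where}.receiver"),
            receiver_port=self.expect_str(rest.get("receiver_port", ""),
                                          f"{where}.receiver_port"),
            weight=weight, metadata=meta,
        )

    def node(self, nid: str, tree, where: str) -> Node:
        rest, meta = self.split(
            tree, ("input_ports", "parameters", "functions", "output_ports",
                   "subgraph"), where)
        sub = rest.get("subgraph")
        return Node(
            id=nid,
            input_ports=[
                self.input_port(pid, t, f"{where}.input_ports.{pid}")
                for pid, t in self.expect_map(
                    rest.get("input_ports", {}), f"{where}.input_ports").items()],
            parameters=[
                self.parameter(pid, t, f"{where}.parameters.{pid}")
                for pid, t in self.expect_map(
                    rest.get("parameters", {}), f"{where}.parameters").items()],
            functions=[
                self.function(fid, t, f"{where}.functions.{fid}")
                for fid, t in self.expect_map(
                    rest.get("functions", {}), f"{where}.functions").items()],
            output_ports=[
                self.output_port(pid, t, f"{where}.output_ports.{pid}")
                for pid, t in self.expect_map(
                    rest.get("output_ports", {}), f"{where}.output_ports").items()],
            subgraph=(self.graph(f"{nid}_subgraph", sub, f"{where}.subgraph")
                      if sub is not None else None),
            metadata=meta,
        )

    def graph(self, gid: str, tree, where: str) -> Graph:
        from .scheduler import ConditionSet

        rest, meta = self.split(tree, ("id", "nodes", "edges", "conditions"), where)
        gid = self.expect_str(rest.get("id", gid), f"{where}.id")
        conditions = None
        if "conditions" in rest:
            try:
                conditions = ConditionSet.from_tree(
                    self.expect_map(rest["conditions"], f"{where}.conditions"))
            except (KeyError, TypeError, ValueError) as err:
                raise SchemaViolationError(
                    f"{where}.conditions is malformed: {err}") from err
        return Graph(
            id=gid,
            nodes=[self.node(nid, t, f"{where}.nodes.{nid}")
                   for nid, t in self.expect_map(
                       rest.get("nodes", {}), f"{where}.nodes").items()],
            edges=[self.edge(eid, t, f"{where}.edges.{eid}")
                   for eid, t in self.expect_map(
                       rest.get("edges", {}), f"{where}.edges").items()],
            conditions=conditions, metadata=meta,
        )

    def model(self, tree) -> Model:
        tree = self.expect_map(tree, "document")
        if len(tree) != 1:
            raise SchemaViolationError(
                f"document must hold exactly one model entry, found {len(tree)}")
        model_id, body = next(iter(tree.items()))
        rest, meta = self.split(body, ("format", "graphs"), f"model {model_id}")
        fmt = rest.get("format", "MDF v0.1")
        fmt = self.expect_str(fmt, "format")
        if not fmt.startswith(_SUPPORTED_FORMAT_PREFIX):
            raise UnsupportedVersionError(
                f"unsupported schema version {fmt!r} "
                f"(this reader supports {_SUPPORTED_FORMAT_PREFIX}.x)")
        return Model(
            id=model_id,
            graphs=[self.graph(gid, t, f"graph {gid}")
                    for gid, t in self.expect_map(
                        rest.get("graphs", {}), "graphs").items()],
            format_version=fmt, metadata=meta,
        )


def model_from_tree(tree: dict) -> Model:
    return _Reader().model(tree)


# --------------------------------------------------------------------------
# Non-finite float handling for JSON
# --------------------------------------------------------------------------

_NONFINITE = {"NaN": math.nan, "Infinity": math.inf, "-Infinity": -math.inf}


def _jsonify(obj, in_metadata: bool = False):
    if isinstance(obj, float) and not math.isfinite(obj):
        if math.isnan(obj):
            return "NaN"
        return "Infinity" if obj > 0 else "-Infinity"
    if isinstance(obj, dict):
        return {k: _jsonify(v, in_metadata or k == "metadata")
                for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonify(v, in_metadata) for v in obj]
    return obj


def _dejsonify(obj, in_metadata: bool = False):
    if isinstance(obj, str) and not in_metadata and obj in _NONFINITE:
        return _NONFINITE[obj]
    if isinstance(obj, dict):
        return {k: _dejsonify(v, in_metadata or k == "metadata")
                for k, v in obj.items()}
    if isinstance(obj, list):
        return [_dejsonify(v, in_metadata) for v in obj]
    return obj


# --------------------------------------------------------------------------
# write / read / convert
# --------------------------------------------------------------------------

def _encode_tree(tree: dict, encoding: str) -> bytes:
    if encoding == "json":
        return (json.dumps(_jsonify(tree), indent=2, allow_nan=False) + "\n").encode()
    if encoding == "yaml":
        return yaml.safe_dump(tree, sort_keys=False,
                              default_flow_style=False).encode()
    if encoding == "binary":
        return _binary.encode(tree)
    raise ValueError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")


def _decode_payload(payload: bytes, encoding: str) -> dict:
    if encoding == "json":
        try:
            tree = json.loads(payload.decode("utf-8"))
        except json.JSONDecodeError as err:
            raise DocumentSyntaxError(f"JSON syntax error: {err.msg}",
                                      offset=err.pos) from None
        except UnicodeDecodeError as err:
            raise DocumentSyntaxError(f"invalid UTF-8: {err}") from None
        return _dejsonify(tree)
    if encoding == "yaml":
        try:
            return yaml.safe_load(payload.decode("utf-8"))
        except yaml.YAMLError as err:
            offset = None
            mark = getattr(err, "problem_mark", None)
            if mark is not None:
                offset = mark.index
            raise DocumentSyntaxError(f"YAML syntax error: {err}",
                                      offset=offset) from None
    if encoding == "binary":
        try:
            return _binary.decode(payload)
        except _binary.BinaryDecodeError as err:
            raise DocumentSyntaxError(f"binary syntax error: {err}") from None
    raise ValueError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")


def write(model: Model, encoding: str = "json") -> SerializedDocument:
    """Serialize a validated model; refuses invalid models.

    Output is deterministic: writing the same model twice yields
    byte-identical payloads.
    """
    report = validate_model(model)
    if not report.ok:
        raise InvalidModelError(f"refusing to write invalid model {model.id!r}",
                                report)
    return SerializedDocument(
        encoding=encoding,
        payload=_encode_tree(to_tree(model), encoding),
        schema_version=model.format_version,
    )


def write_file(model: Model, path: str | Path, encoding: str | None = None) -> Path:
    path = Path(path)
    encoding = encoding or encoding_for_path(path)
    path.write_bytes(write(model, encoding).payload)
    return path


def read(source: SerializedDocument | str | Path, *, validate: bool = True) -> Model:
    """Read a model from a document or file path.

    Unknown keys land in the nearest metadata map with a warning; missing
    optional fields take their schema defaults.  With ``validate=True``
    (default) the result must be well-formed or :class:`InvalidModelError`
    is raised.
    """
    if isinstance(source, SerializedDocument):
        encoding, payload = source.encoding, source.payload
    else:
        path = Path(source)
        encoding = encoding_for_path(path)
        payload = path.read_bytes()
    tree = _decode_payload(payload, encoding)
    model = model_from_tree(tree)
    if validate:
        report = validate_model(model)
        if not report.ok:
            raise InvalidModelError(f"document decodes to an invalid model", report)
    return model


def convert(path_in: str | Path, encoding_out: str,
            path_out: str | Path | None = None) -> Path:
    """Re-encode a document file; lossless across all encoding pairs."""
    model = read(path_in)
    if path_out is None:
        name = Path(path_in).name
        for ext in (".mdf.bin", ".json", ".yaml", ".yml", ".bin", ".msgpack"):
            if name.endswith(ext):
                name = name[: -len(ext)]
                break
        path_out = Path(path_in).with_name(name + extension_for(encoding_out))
    return write_file(model, path_out, encoding_out)


# --------------------------------------------------------------------------
# Structural equality and copying
# --------------------------------------------------------------------------

def copy_model(model: Model) -> Model:
    """Deep copy through the canonical tree (shares nothing with the input)."""
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return model_from_tree(to_tree(model))


def _tree_eq(a, b) -> bool:
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(_tree_eq(a[k], b[k]) for k in a)
    if isinstance(a, list) and isinstance(b, list):
        return len(a) == len(b) and all(_tree_eq(x, y) for x, y in zip(a, b))
    if isinstance(a, float) and isinstance(b, float):
        return (math.isnan(a) and math.isnan(b)) or a == b
    return type(a) is type(b) and a == b


def models_equal(a: Model, b: Model) -> bool:
    """Structural equality: identical canonical document trees.

    NaN compares equal to NaN; ints and floats of equal value but
    different kind do *not* compare equal (1 is not 1.0 on the wire).
    """
    return _tree_eq(to_tree(a), to_tree(b))
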