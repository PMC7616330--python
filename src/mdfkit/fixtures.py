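"""Programmatic generators for the demo/test model zoo.

Every fixture is generated, never stored: the schema stays the single
source of truth and fixtures cannot drift from it.  The zoo spans the
model classes the format is meant to carry — a stateless arithmetic chain,
a biophysical oscillator (FitzHugh–Nagumo), a stochastic accumulator
(drift-diffusion), multi-timescale conditioned execution, a cyclic pair, a
hierarchical model, and a tensor MLP imported from the tensor-graph
dialect.  Generation is deterministic given its parameters.
"""

from __future__ import annotations

from .interchange import TensorGraphDoc, TensorOp, import_tensor_graph
from .schema import (
    Edge, FunctionCall, Graph, InputPort, InvalidModelError, Model, Node,
    OutputPort, Parameter, validate_model,
)
from .scheduler import ConditionSet, after_n_calls, every_n_calls

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = (
    "ffn_abc", "fhn_neuron", "ddm_accumulator", "condition_demo",
    "cyclic_pair", "nested_model", "tensor_mlp",
)


def _ffn_abc(x: float = 4.0) -> Model:
    """Three-node arithmetic chain: A computes x+1, B doubles, C subtracts 3."""
    a = Node(id="A",
             parameters=[Parameter(id="x", value=x)],
             output_ports=[OutputPort(id="out", value="x + 1")])
    b = Node(id="B", input_ports=[InputPort(id="in1")],
             output_ports=[OutputPort(id="out", value="in1 * 2")])
    c = Node(id="C", input_ports=[InputPort(id="in1")],
             output_ports=[OutputPort(id="out", value="in1 - 3")])
    g = Graph(id="g", nodes=[a, b, c], edges=[
        Edge(id="ab", sender="A", sender_port="out",
             receiver="B", receiver_port="in1"),
        Edge(id="bc", sender="B", sender_port="out",
             receiver="C", receiver_port="in1"),
    ])
    return Model(id="ffn_abc", graphs=[g])


def _fhn_neuron(a: float = 0.7, b: float = 0.8, tau: float = 12.5,
                I_ext: float = 0.0, V0: float = 0.0, W0: float = 0.0) -> Model:
    """Single FitzHugh–Nagumo node with V and W as ODE state parameters."""
    node = Node(
        id="fhn",
        parameters=[
            Parameter(id="a", value=a),
            Parameter(id="b", value=b),
            Parameter(id="tau", value=tau),
            Parameter(id="I_ext", value=I_ext),
            Parameter(id="V", default_initial_value=V0,
                      time_derivative="fitzhugh_nagumo_dv(V, W, I_ext)"),
            Parameter(id="W", default_initial_value=W0,
                      time_derivative="fitzhugh_nagumo_dw(V, W, a, b, tau)"),
        ],
        output_ports=[OutputPort(id="V_out", value="V"),
                      OutputPort(id="W_out", value="W")],
    )
    return Model(id="fhn_neuron", graphs=[Graph(id="g", nodes=[node])])


def _ddm_accumulator(drift_rate: float = 0.5, noise_coeff: float = 1.0,
                     x0: float = 0.0, n_paths: int | None = None) -> Model:
    """Drift-diffusion accumulator: Euler–Maruyama self-update per pass.

    With ``n_paths`` the state becomes a vector of that many independent
    accumulators sharing drift and noise coefficients — the standard way to
    study the ensemble statistics of the decision variable.
    """
    if n_paths is None:
        init, noise = x0, "standard_normal()"
    else:
        init, noise = [x0] * int(n_paths), f"standard_normal({int(n_paths)})"
    node = Node(
        id="ddm",
        parameters=[
            Parameter(id="drift_rate", value=drift_rate),
            Parameter(id="noise_coeff", value=noise_coeff),
            Parameter(
                id="x", default_initial_value=init,
                value=f"drift_diffusion_step(x, drift_rate, noise_coeff, dt, "
                      f"{noise})"),
        ],
        output_ports=[OutputPort(id="out", value="x")],
    )
    return Model(id="ddm_accumulator", graphs=[Graph(id="g", nodes=[node])])


def _condition_demo(n: int = 2, stop_after: int = 10) -> Model:
    """Fast/slow timescales: `slow` integrates every n-th `fast` output."""
    fast = Node(
        id="fast",
        parameters=[Parameter(id="count", value="count + 1",
                              default_initial_value=0)],
        output_ports=[OutputPort(id="out", value="count")],
    )
    slow = Node(
        id="slow",
        input_ports=[InputPort(id="in1")],
        parameters=[Parameter(id="total", value="total + in1",
                              default_initial_value=0)],
        output_ports=[OutputPort(id="out", value="total")],
    )
    g = Graph(
        id="g",
        nodes=[fast, slow],
        edges=[Edge(id="fs", sender="fast", sender_port="out",
                    receiver="slow", receiver_port="in1")],
        conditions=ConditionSet(
            node_specific={"slow": every_n_calls("fast", n)},
            termination=after_n_calls("fast", stop_after),
        ),
    )
    return Model(id="condition_demo", graphs=[g])


def _cyclic_pair(gain: float = 0.5) -> Model:
    """Two mutually connected nodes; cycle values cross with one-pass delay."""
    a = Node(id="A", input_ports=[InputPort(id="in_b")],
             output_ports=[OutputPort(id="out", value="in_b + 1",
                                      default_initial_value=0.0)])
    b = Node(id="B", input_ports=[InputPort(id="in_a")],
             parameters=[Parameter(id="gain", value=gain)],
             output_ports=[OutputPort(id="out", value="in_a * gain",
                                      default_initial_value=0.0)])
    g = Graph(id="g", nodes=[a, b], edges=[
        Edge(id="ab", sender="A", sender_port="out",
             receiver="B", receiver_port="in_a"),
        Edge(id="ba", sender="B", sender_port="out",
             receiver="A", receiver_port="in_b"),
    ])
    return Model(id="cyclic_pair", graphs=[g])


def _nested_model(depth: int = 1, x: float = 4.0) -> Model:
    """Hierarchical model: pre -> wrapper(subgraph) -> post.

    The innermost node triples its input; each extra nesting level wraps it
    in another subgraph layer.  Flat semantics: ((x+1)*3) - 3.
    """
    inner = Node(id="Q", input_ports=[InputPort(id="in1")],
                 output_ports=[OutputPort(id="out", value="in1 * 3")])
    sub = Graph(id="inner", nodes=[inner])
    for level in range(1, depth):
        wrapper = Node(id=f"W{level}", input_ports=[InputPort(id="in1")],
                       output_ports=[OutputPort(id="out")], subgraph=sub)
        sub = Graph(id=f"level{level}", nodes=[wrapper])
    pre = Node(id="pre",
               parameters=[Parameter(id="x", value=x)],
               output_ports=[OutputPort(id="out", value="x + 1")])
    mid = Node(id="P", input_ports=[InputPort(id="in1")],
               output_ports=[OutputPort(id="out")], subgraph=sub)
    post = Node(id="post", input_ports=[InputPort(id="in1")],
                output_ports=[OutputPort(id="out", value="in1 - 3")])
    g = Graph(id="g", nodes=[pre, mid, post], edges=[
        Edge(id="e0", sender="pre", sender_port="out",
             receiver="P", receiver_port="in1"),
        Edge(id="e1", sender="P", sender_port="out",
             receiver="post", receiver_port="in1"),
    ])
    return Model(id="nested_model", graphs=[g])


def _tensor_mlp(weights=None, bias=None) -> Model:
    """One-layer perceptron via the tensor-graph dialect: relu(x @ W + b)."""
    if weights is None:
        weights = [[1.0, -2.0], [3.0, 0.5]]
    if bias is None:
        bias = [0.5, -1.0]
    doc = TensorGraphDoc(
        inputs={"x": {"value": [1.0, 2.0]},
                "W": {"value": weights},
                "b": {"value": bias}},
        ops=[
            TensorOp(op="matmul", inputs=("x", "W"), output="h"),
            TensorOp(op="add", inputs=("h", "b"), output="z"),
            TensorOp(op="relu", inputs=("z",), output="y"),
        ],
        outputs=["y"],
    )
    return import_tensor_graph(doc, model_id="tensor_mlp")


_GENERATORS = {
    "ffn_abc": _ffn_abc,
    "fhn_neuron": _fhn_neuron,
    "ddm_accumulator": _ddm_accumulator,
    "condition_demo": _condition_demo,
    "cyclic_pair": _cyclic_pair,
    "nested_model": _nested_model,
    "tensor_mlp": _tensor_mlp,
}


def make_fixture(name: str, **params) -> Model:
    """Generate a named fixture model; always returns a validated model."""
    try:
        gen = _GENERATORS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None
    model = gen(**params)
    report = validate_model(model)
    if not report.ok:
        raise InvalidModelError(f"fixture {name!r} failed validation", report)
    return model
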