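# mdfkit

A serializable **model description format** for computational models, with a
reference toolchain: validating reader/writer (JSON, YAML, binary), a
condition-based scheduler for arbitrary control flow, a function ontology of
tensor operators and domain integrators, a reference execution engine, and
structural visualization.

Computational neuroscience, cognitive science and machine learning each keep
their models in mutually unintelligible environments — NeuroML-style neuron
descriptions, production-system architectures, PyTorch graphs. `mdfkit`
implements the hub of a hub-and-spoke exchange scheme: every model becomes a
**computational graph** in which *nodes* carry out mathematical operations,
*ports* receive and provide their values, and *edges* transmit values between
ports on different nodes. The same document model spans levels of analysis,
from a biophysical oscillator to a tensor MLP:

- **Nodes** bundle input ports, parameters, function calls and output ports;
  a node may instead wrap a *subgraph* (hierarchical composition).
- **Stateful parameters** carry value across executions — either through a
  self-referential update rule (`count + 1`) or a `time_derivative`, which
  marks an ODE state variable advanced by the engine's forward-Euler
  integrator: `v ← v + dt·f(v, …)`.
- **Conditions** declaratively gate node execution per scheduler *pass*
  (`always`, `every_n_calls(node, n)`, `threshold(node, param, ≥, v)`,
  boolean combinations, …), covering arbitrary execution orders, nodes
  running on different timescales, and cyclic graphs.
- The **function ontology** is an open registry whose core set follows the
  ONNX operator definitions (`add … softmax, matmul, reduce_sum, reshape`)
  plus domain integrators: the FitzHugh–Nagumo neuron
  (`dV/dt = V − V³/3 − W + I_ext`, `dW/dt = (V + a − b·W)/τ`) and the
  Euler–Maruyama drift-diffusion step
  (`x ← x + A·dt + c·√dt·ξ`, `ξ ~ N(0,1)`).

## Worked example

```python
import mdfkit as mk

model = mk.make_fixture("ffn_abc")            # A -> B -> C: ((x+1)*2)-3
print(mk.validate_model(model))
result = mk.run(model, max_passes=10)
print("C:out =", result.value("C", "out"))

ddm = mk.make_fixture("ddm_accumulator", drift_rate=0.5, noise_coeff=1.0,
                      n_paths=10_000)
r = mk.run(ddm, dt=0.1, duration=1.0, seed=1)
x = r.value("ddm", "x")
print(f"DDM ensemble at T=1: mean={x.mean():.4f}  var={x.var(ddof=1):.4f}")
```

prints

```
valid: no issues
C:out = 7.0
DDM ensemble at T=1: mean=0.4855  var=1.0020
```

The first model is a three-node arithmetic chain: node `A` computes `x + 1`
from its parameter `x = 4`, `B` doubles it, `C` subtracts 3, giving 7. The
second runs 10,000 independent drift-diffusion accumulators for one unit of
simulated time; the ensemble mean and variance land on the closed-form
`A·T = 0.5` and `c²·T = 1.0` of driftful Brownian motion to within sampling
error.

The same models round-trip losslessly through all three encodings from the
shell:

```sh
mdfkit fixture ffn_abc m.json
mdfkit convert m.json --to yaml && mdfkit convert m.yaml --to binary
mdfkit graph m.json            # Graphviz DOT structure
mdfkit run m.json --max-passes 5 --record C:out
```

The serialized schema is documented in `src/mdfkit/schemas/mdf.schema.json`;
the model and its design choices are described in [docs/methods.md](docs/methods.md).

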