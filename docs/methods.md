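# Methods

This note records the semantics, numerical choices and limitations of
`mdfkit` — the things a maintainer or a careful user needs that the README
does not cover.

## Document model

A document holds exactly one model; a model holds ordered graphs of nodes
and edges. Identifiers follow `[A-Za-z_][A-Za-z0-9_]*`; the dot is reserved
for hierarchy namespacing, so flattened node ids like `P.W1.Q` remain
unambiguous in every context that names nodes. Values are scalars and dense
numeric arrays (nested lists on the wire); strings and booleans live only in
`metadata` maps.

Validation (`validate_model`) is report-based and total: it returns every
violation it can find rather than stopping at the first, and an empty report
*defines* well-formedness. The severity ladder is fixed — `error` blocks
execution and serialization, `warning` and `info` never do. Cycle presence
is deliberately `info`, not an error: recurrent graphs are a first-class
model class; they merely oblige `default_initial_value` on every output port
that feeds a cycle, which validation enforces.

Fan-in (two edges into one input port) is an error unless the port declares
`reduce: sum`. Silent summation hides wiring mistakes, but explicit
summation is exactly what population models need, so the receiving port has
to opt in.

### Hierarchy

A subgraph node's input and output ports map one-to-one *by id* onto
like-named ports of its inner nodes; each boundary port must match exactly
one inner port, otherwise flattening fails loudly. `flatten_hierarchy`
prefixes child ids with `parent.`, rewires boundary edges, namespaces any
conditions declared inside the subgraph, and replicates a condition attached
to the wrapper onto each child. The engine executes hierarchical models *by
flattening them*, so the flattened form is the semantics — which is also why
flattening is idempotent and engine-equivalence between the two forms holds
exactly rather than to a tolerance. Conditions elsewhere in the graph may
not reference a wrapper node (it no longer exists after flattening); this is
rejected rather than guessed at.

## Expression language

Parameter values, function arguments and output ports hold strings in a
small arithmetic grammar: numbers, identifiers, `+ - * / % **`, unary minus,
parentheses, comparisons returning 0/1, `f(a, b)` calls resolving in the
function ontology, and `x[i]` indexing. Precedence from loosest to
tightest: comparisons, additive, multiplicative, unary minus, `**`
(right-associative). Unary minus binds looser than `**`, so `-2**2 = -4`,
matching mainstream languages — the test suite pins this by checking 1000
random expressions against Python's own evaluator.

The value algebra is single-sorted numeric: comparisons yield 0/1 rather
than booleans (conditions need numeric thresholds anyway), and there is no
ternary operator — branching belongs to the condition system, keeping
"mathematics inside nodes" cleanly separated from "control flow between
nodes". Division by zero follows IEEE semantics (`inf`/`nan`) and increments
an engine warning counter instead of aborting: a mid-sweep exception during
a long ODE parameter scan is hostile, and the non-finite budget (below)
still catches runaway state. Scalars broadcast against arrays; array–array
operands must agree in shape exactly — implicit outer broadcasting has no
place in a format meant to pin semantics down.

## Scheduling semantics

Execution proceeds in *passes*. Nodes are considered once per pass in a
fixed **consideration order**: strongly connected components of the
node-level dependency graph are condensed and ordered topologically with
declaration-order tie-breaking; members of a cyclic component keep
declaration order. For a DAG this is exactly Kahn's algorithm with
declaration ties, which the tests verify against an independent
implementation.

A node's condition is evaluated *at its turn* in that order, so call-count
conditions observe executions of upstream nodes earlier in the same pass:
`every_n_calls(fast, 2)` fires in the very pass of the fast node's 2nd
call, giving the trace `fast; fast,slow; fast; fast,slow; …`. Each node is
considered exactly once per pass (no re-evaluation after later executions).
Threshold conditions instead read values as committed before the pass
started — mid-pass values are never visible to them, which keeps value-based
gating deterministic and independent of consideration order.

`every_n_calls` uses **consumption bookkeeping** per dependent, not a raw
modulus: every n-th call of the dependency banks one firing, consumed when
the dependent actually runs. A dependent that is itself gated for a while
fires on consecutive passes afterwards until the bank drains, instead of
silently dropping events.

The termination condition (default `all_have_run`) is checked at the end of
each pass; `max_passes` bounds non-terminating schedules, and the two
outcomes — `terminated` vs `budget_exhausted` — are distinguished on the
trace. For duration-driven runs the duration *is* the budget, so completing
it reports `terminated`.

## Engine semantics

Within a node, evaluation is: input ports → parameters and function calls in
intra-node dependency order (topological over free identifiers) → output
ports. Stateful slots read their previous committed values throughout,
which is what breaks self-reference; their new values, the output-port
values and the latest input-port values commit **atomically at node
completion**. Output ports see the post-commit state — a counter with
update `c + 1` exposes 1, 2, 3 on successive executions, not a one-step lag.
A reference cycle among *non-stateful* slots is an error (validation and the
engine both catch it).

Values crossing a graph cycle are the values committed on a previous pass;
the required `default_initial_value` on cycle-feeding ports seeds the first
read. Unconnected input ports read 0 with a warning rather than erroring,
mirroring common simulator treatment of optional drive. The reserved
identifiers `dt` and `t` (step size, clock) are bound by the engine in every
node scope.

Timed runs advance simulated time once per pass, after node execution:
every parameter with a `time_derivative` takes one forward-Euler step, all
derivatives reading pre-step values (simultaneous update), then the clock
advances by `dt`. Forward Euler is the sole integrator on purpose — a
*reference* engine must be simple and auditable; higher-order schemes are an
extension point, and the order-1 convergence of the Euler step is itself a
tested property (error halving ratio within [0.4, 0.6] on `dv/dt = −v`).
One pass per time step is also the coupling rule between conditions and
integration: a node gated `every_n_calls(fast, k)` computes on a timescale
k·dt — multiple timescales fall out of the condition system.

Non-finite state values increment a warning counter; past a configurable
budget (default 100) the run aborts with `NonFiniteError`. All randomness
flows from the single run-level generator seeded by `run(..., seed=)`;
stochastic ontology functions receive it by injection, so identical options
give bit-identical results.

Recorded slots (`"node:slot"`) are captured at the end of every pass in
which the owning node executed, after the time step — so a recorded ODE
state at clock `k·dt` is the post-step value, aligning the series with the
solution at times `dt, 2·dt, …`.

## Serialization

All three encodings carry the identical document tree. Canonical writing is
deterministic: schema-defined key order, collections as maps keyed by id
(diff-friendly; order recovered from key order), optional fields at their
defaults omitted, floats in shortest-round-trip form. JSON lacks non-finite
floats, so `NaN`/`Infinity`/`-Infinity` are written as those marker strings
and restored on read everywhere except inside `metadata`; YAML and the
binary encoding carry them natively. The binary encoding is the MessagePack
framing of the same tree, produced by a self-contained codec
(`_binary.py`) that always writes floats as float64 and preserves map
order; its wire format is pinned by byte-level test vectors. Unknown keys
read forward-compatibly into the nearest `metadata` map with a warning.
The published JSON-Schema documents in `src/mdfkit/schemas/` describe both
wire formats and are validated against every generated fixture in the test
suite.

## Function ontology

The core operator set implements 24 operators with the ONNX names and
semantics on dense arrays (including `keepdims=1` reduction defaults and
last-axis softmax). Full operator coverage is a scope statement, not a
v1 deliverable: the registry's `register` is the extension mechanism, and
the machine-readable catalog (`mdfkit functions`) is the index. Domain
integrators expose *derivatives* (FitzHugh–Nagumo) and *single steps*
(drift-diffusion) rather than built-in solvers, leaving integration to the
engine; both equation forms are the canonical literature forms and are
embedded in the ontology documentation so serialized models are
self-describing. `concat` takes two inputs (the variadic generalization is
an extension).

## Interchange

The tensor-graph bridge targets a self-defined single-assignment JSON
dialect using core-set operator names, not a protobuf container — it
exercises structure-preserving translation without binding the library to a
heavyweight dependency. Export is **fragment-based and fail-loud**: only
acyclic, unconditioned, stateless models built from parameter-fed sources
and single-call core-operator nodes export; anything else raises an error
naming the offending construct and node. Lossy best-effort export is the
failure mode a standardization effort exists to prevent. Round-trip
engine-equivalence on the fragment is tested to 1e-12 over random inputs.

## Fixtures as study conditions

The generated model zoo spans the classes the format must carry: a
stateless arithmetic chain (`ffn_abc`), a biophysical oscillator
(`fhn_neuron`, classic parameters a=0.7, b=0.8, τ=12.5), a stochastic
accumulator (`ddm_accumulator`, drift 0.5, noise 1.0 — a moderate-SNR
regime standard in decision-making work; `n_paths` vectorizes it into an
ensemble), fast/slow conditioned execution (`condition_demo`, slow node at
half the fast rate), a recurrent pair (`cyclic_pair`), a hierarchical model
(`nested_model`), and an imported tensor MLP (`tensor_mlp`). Fixtures are
generated, never stored, so they cannot drift from the schema. They are
deliberately small and exactly analyzable; passing tests demonstrate
semantic correctness of the toolchain, not fidelity of any fixture to a
particular biological system.

Problem sizes used by the verification runs: FHN at dt=0.01 to t=100
(10,000 steps) against `solve_ivp` (RK45, rtol 1e-10); Euler convergence at
dt ∈ {1e-2, 5e-3, 2.5e-3}; DDM ensembles of 10,000 paths over 10 steps;
50 randomized condition sets per fixture for scheduler replay; 100 random
arrays per core operator.

## Known limitations

- **FHN suprathreshold peak count.** With the classic parameters and
  I_ext=0.5 from rest (V₀=W₀=0), the limit cycle has period ≈39.4 time
  units: maxima fall at t ≈ 2.9, 41.6, 81.0, so the window 20 < t ≤ 100
  contains exactly **two** suprathreshold maxima — three would require a
  period ≤ 26.7, which these equations do not produce at this drive. The
  verification script reports the computed count as is.
- Threshold conditions reference parameters only, not ports.
- Forward Euler only; stiff systems need small `dt` and benefit from the
  non-finite budget as a tripwire, not a remedy.
- The exportable tensor-graph fragment excludes weighted edges and
  general expressions; the NeuroML/PyTorch-style bridges the hub-and-spoke
  design anticipates are out of scope here.
- Schema evolution between format versions is not implemented; the reader
  accepts `MDF v0.x` documents only.
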