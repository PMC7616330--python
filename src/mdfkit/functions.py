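"""Function ontology: named, documented functions callable from expressions.

The registry holds a core set of dense tensor operators whose names and
semantics follow the ONNX operator definitions of the same names, plus
domain integrators used in neuroscience (FitzHugh–Nagumo) and cognitive
science (drift-diffusion).  The registry is open: additional functions can
be registered at run time, which is the extension path toward broader
operator coverage.

Every function here is pure.  Stochastic behaviour (the ``standard_normal``
draw used by drift-diffusion models) takes its randomness from a generator
injected by the caller — in practice the execution engine's run-level
seeded generator — so functions stay deterministic and unit-testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .expressions import UnknownFunctionError

__all__ = [
    "ArgSpec",
    "FunctionDef",
    "FunctionRegistry",
    "DuplicateFunctionError",
    "core_operator_set",
    "standard_registry",
    "fitzhugh_nagumo_derivatives",
    "drift_diffusion_step",
    "CORE_OPERATOR_NAMES",
]


class DuplicateFunctionError(ValueError):
    def __init__(self, name: str):
        super().__init__(f"function {name!r} is already registered")
        self.name = name


@dataclass(frozen=True)
class ArgSpec:
    name: str
    required: bool = True
    default: object | None = None


@dataclass(frozen=True)
class FunctionDef:
    """A registry entry: callable contract plus documentation.

    ``arity_class`` distinguishes elementwise maps, reductions and
    structural (shape-changing) operators; it is descriptive metadata used
    by the catalog export and by tests, not by dispatch.
    """

    name: str
    arg_spec: tuple[ArgSpec, ...]
    arity_class: str  # "elementwise" | "reduction" | "structural"
    implementation: Callable = field(compare=False)
    doc: str = ""
    stochastic: bool = False

    def __post_init__(self):
        seen_optional = False
        for a in self.arg_spec:
            if not a.required:
                seen_optional = True
            elif seen_optional:
                raise ValueError(
                    f"{self.name}: required argument {a.name!r} follows an optional one"
                )


class FunctionRegistry:
    """Mutable name → :class:`FunctionDef` mapping with call dispatch."""

    def __init__(self, defs: Iterable[FunctionDef] = ()):
        self._defs: dict[str, FunctionDef] = {}
        for d in defs:
            self.register(d)

    def register(self, fdef: FunctionDef) -> FunctionDef:
        if fdef.name in self._defs:
            raise DuplicateFunctionError(fdef.name)
        self._defs[fdef.name] = fdef
        return fdef

    def lookup(self, name: str) -> FunctionDef:
        try:
            return self._defs[name]
        except KeyError:
            raise UnknownFunctionError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __iter__(self):
        return iter(self._defs.values())

    def names(self) -> list[str]:
        return list(self._defs)

    def call(self, name: str, args: Sequence, kwargs: Mapping | None = None, *, rng=None):
        """Dispatch a call, filling defaults and checking required args."""
        fdef = self.lookup(name)
        kwargs = dict(kwargs or {})
        bound: dict[str, object] = {}
        specs = fdef.arg_spec
        if len(args) > len(specs):
            raise TypeError(
                f"{name}() takes at most {len(specs)} arguments ({len(args)} given)"
            )
        for spec, val in zip(specs, args):
            bound[spec.name] = val
        for key, val in kwargs.items():
            if key in bound:
                raise TypeError(f"{name}() got duplicate argument {key!r}")
            if not any(s.name == key for s in specs):
                raise TypeError(f"{name}() got unexpected argument {key!r}")
            bound[key] = val
        for spec in specs:
            if spec.name not in bound:
                if spec.required:
                    raise TypeError(f"{name}() missing required argument {spec.name!r}")
                bound[spec.name] = spec.default
        if fdef.stochastic:
            if rng is None:
                raise ValueError(
                    f"{name}() is stochastic and needs a seeded generator; "
                    "run it through the engine or pass rng="
                )
            return fdef.implementation(**bound, rng=rng)
        return fdef.implementation(**bound)

    def to_catalog(self) -> list[dict]:
        """Machine-readable catalog of the ontology (name, args, doc)."""
        return [
            {
                "name": d.name,
                "arity_class": d.arity_class,
                "stochastic": d.stochastic,
                "args": [
                    {"name": a.name, "required": a.required, "default": a.default}
                    for a in d.arg_spec
                ],
                "doc": d.doc,
            }
            for d in sorted(self._defs.values(), key=lambda d: d.name)
        ]

    def catalog_json(self) -> str:
        return json.dumps(self.to_catalog(), indent=2)


# --------------------------------------------------------------------------
# Core tensor operators (ONNX names and semantics on dense arrays)
# --------------------------------------------------------------------------

def _f(x):
    return np.asarray(x, dtype=float)


def _softmax(x, axis=-1):
    x = _f(x)
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def _reduce(fn, data, axes=None, keepdims=1):
    data = _f(data)
    axis = None if axes is None else tuple(int(a) for a in np.atleast_1d(axes))
    return fn(data, axis=axis, keepdims=bool(keepdims))


def _transpose(data, perm=None):
    data = _f(data)
    return np.transpose(data, axes=None if perm is None else [int(p) for p in perm])


def _concat(a, b, axis=0):
    return np.concatenate([_f(a), _f(b)], axis=int(axis))


def _reshape(data, shape):
    return np.reshape(_f(data), [int(s) for s in np.atleast_1d(shape)])


def _clip(x, min=None, max=None):
    return np.clip(_f(x), min, max)


def _elem(name, fn, doc, args=("x",)):
    return FunctionDef(
        name=name,
        arg_spec=tuple(ArgSpec(a) for a in args),
        arity_class="elementwise",
        implementation=fn,
        doc=doc,
    )


CORE_OPERATOR_NAMES = (
    "add", "sub", "mul", "div", "pow", "neg", "abs", "exp", "log", "sqrt",
    "sin", "cos", "tanh", "sigmoid", "relu", "softmax", "matmul",
    "transpose", "reduce_sum", "reduce_mean", "reduce_max", "clip",
    "concat", "reshape",
)


def _core_defs() -> list[FunctionDef]:
    E, S, R = "elementwise", "structural", "reduction"
    return [
        _elem("add", lambda a, b: _f(a) + _f(b), "Elementwise addition.", ("a", "b")),
        _elem("sub", lambda a, b: _f(a) - _f(b), "Elementwise subtraction.", ("a", "b")),
        _elem("mul", lambda a, b: _f(a) * _f(b), "Elementwise multiplication.", ("a", "b")),
        _elem("div", lambda a, b: _f(a) / _f(b), "Elementwise division (IEEE semantics).", ("a", "b")),
        _elem("pow", lambda a, b: _f(a) ** _f(b), "Elementwise power.", ("a", "b")),
        _elem("neg", lambda x: -_f(x), "Elementwise negation."),
        _elem("abs", lambda x: np.abs(_f(x)), "Elementwise absolute value."),
        _elem("exp", lambda x: np.exp(_f(x)), "Elementwise natural exponential."),
        _elem("log", lambda x: np.log(_f(x)), "Elementwise natural logarithm."),
        _elem("sqrt", lambda x: np.sqrt(_f(x)), "Elementwise square root."),
        _elem("sin", lambda x: np.sin(_f(x)), "Elementwise sine."),
        _elem("cos", lambda x: np.cos(_f(x)), "Elementwise cosine."),
        _elem("tanh", lambda x: np.tanh(_f(x)), "Elementwise hyperbolic tangent."),
        _elem("sigmoid", lambda x: 1.0 / (1.0 + np.exp(-_f(x))),
              "Elementwise logistic sigmoid 1/(1+exp(-x))."),
        _elem("relu", lambda x: np.maximum(_f(x), 0.0),
              "Elementwise rectified linear unit max(x, 0)."),
        FunctionDef("softmax",
                    (ArgSpec("x"), ArgSpec("axis", False, -1)), E, _softmax,
                    "Normalized exponential along `axis` (default last): "
                    "exp(x - max x) / sum exp(x - max x)."),
        FunctionDef("matmul", (ArgSpec("a"), ArgSpec("b")), S,
                    lambda a, b: np.matmul(_f(a), _f(b)),
                    "Matrix product with numpy/ONNX MatMul broadcasting rules."),
        FunctionDef("transpose", (ArgSpec("data"), ArgSpec("perm", False, None)), S,
                    _transpose,
                    "Permute axes; default perm reverses all axes."),
        FunctionDef("reduce_sum",
                    (ArgSpec("data"), ArgSpec("axes", False, None),
                     ArgSpec("keepdims", False, 1)), R,
                    lambda data, axes=None, keepdims=1: _reduce(np.sum, data, axes, keepdims),
                    "Sum over `axes` (default all); keepdims defaults to 1."),
        FunctionDef("reduce_mean",
                    (ArgSpec("data"), ArgSpec("axes", False, None),
                     ArgSpec("keepdims", False, 1)), R,
                    lambda data, axes=None, keepdims=1: _reduce(np.mean, data, axes, keepdims),
                    "Arithmetic mean over `axes` (default all); keepdims defaults to 1."),
        FunctionDef("reduce_max",
                    (ArgSpec("data"), ArgSpec("axes", False, None),
                     ArgSpec("keepdims", False, 1)), R,
                    lambda data, axes=None, keepdims=1: _reduce(np.max, data, axes, keepdims),
                    "Maximum over `axes` (default all); keepdims defaults to 1."),
        FunctionDef("clip",
                    (ArgSpec("x"), ArgSpec("min", False, None),
                     ArgSpec("max", False, None)), E, _clip,
                    "Limit values to the closed interval [min, max]."),
        FunctionDef("concat",
                    (ArgSpec("a"), ArgSpec("b"), ArgSpec("axis", False, 0)), S, _concat,
                    "Concatenate two arrays along `axis`."),
        FunctionDef("reshape", (ArgSpec("data"), ArgSpec("shape")), S, _reshape,
                    "Reshape to the given shape (total size preserved)."),
    ]


def core_operator_set() -> FunctionRegistry:
    """Registry preloaded with the core tensor-operator set.

    The ontology's scope is open-ended; this core set covers the operators
    needed by feedforward tensor models (activations, linear algebra,
    reductions, shape manipulation).  :meth:`FunctionRegistry.register`
    is the extension mechanism toward full operator coverage.
    """
    return FunctionRegistry(_core_defs())


# --------------------------------------------------------------------------
# Domain integrators
# --------------------------------------------------------------------------

def fitzhugh_nagumo_derivatives(V, W, a=0.7, b=0.8, tau=12.5, I_ext=0.0):
    """Time derivatives of the FitzHugh–Nagumo reduced neuron model.

    The two-variable model of excitable membrane dynamics:

        dV/dt = V - V^3/3 - W + I_ext
        dW/dt = (V + a - b*W) / tau

    ``V`` is the fast voltage-like variable, ``W`` the slow recovery
    variable; ``tau`` (> 0) sets the recovery timescale and ``I_ext`` the
    external drive.  With the classic parameters a=0.7, b=0.8, tau=12.5 the
    model rests at a stable fixed point for I_ext=0 and produces sustained
    relaxation oscillations under suprathreshold drive such as I_ext=0.5.

    Returns ``(dV_dt, dW_dt)`` elementwise.
    """
    if np.any(_f(tau) <= 0):
        raise ValueError(f"tau must be positive, got {tau}")
    V, W = _f(V), _f(W)
    dV = V - V**3 / 3.0 - W + _f(I_ext)
    dW = (V + _f(a) - _f(b) * W) / _f(tau)
    return dV, dW


def drift_diffusion_step(x, drift_rate, noise_coeff, dt, noise_sample):
    """One Euler–Maruyama update of a drift-diffusion accumulator.

        x_next = x + drift_rate*dt + noise_coeff*sqrt(dt)*noise_sample

    ``noise_sample`` is a standard-normal draw supplied by the caller, so
    the step itself is deterministic; the engine owns the seeded generator.
    ``dt`` must be positive.
    """
    if np.any(_f(dt) <= 0):
        raise ValueError(f"dt must be positive, got {dt}")
    return _f(x) + _f(drift_rate) * _f(dt) + _f(noise_coeff) * np.sqrt(_f(dt)) * _f(noise_sample)


def _domain_defs() -> list[FunctionDef]:
    return [
        FunctionDef(
            "fitzhugh_nagumo_dv",
            (ArgSpec("V"), ArgSpec("W"), ArgSpec("I_ext", False, 0.0)),
            "elementwise",
            lambda V, W, I_ext=0.0: fitzhugh_nagumo_derivatives(V, W, I_ext=I_ext)[0],
            "FitzHugh–Nagumo voltage derivative dV/dt = V - V^3/3 - W + I_ext.",
        ),
        FunctionDef(
            "fitzhugh_nagumo_dw",
            (ArgSpec("V"), ArgSpec("W"), ArgSpec("a", False, 0.7),
             ArgSpec("b", False, 0.8), ArgSpec("tau", False, 12.5)),
            "elementwise",
            lambda V, W, a=0.7, b=0.8, tau=12.5:
                fitzhugh_nagumo_derivatives(V, W, a=a, b=b, tau=tau)[1],
            "FitzHugh–Nagumo recovery derivative dW/dt = (V + a - b*W)/tau.",
        ),
        FunctionDef(
            "drift_diffusion_step",
            (ArgSpec("x"), ArgSpec("drift_rate"), ArgSpec("noise_coeff"),
             ArgSpec("dt"), ArgSpec("noise_sample")),
            "elementwise",
            drift_diffusion_step,
            "Euler–Maruyama update x + drift_rate*dt + noise_coeff*sqrt(dt)*noise_sample.",
        ),
        FunctionDef(
            "standard_normal", (ArgSpec("size", False, None),), "elementwise",
            lambda rng, size=None: (
                float(rng.standard_normal()) if size is None
                else rng.standard_normal(int(size))),
            "Standard-normal draw(s) from the run-level seeded generator; "
            "a scalar by default, a vector of `size` draws if given.",
            stochastic=True,
        ),
    ]


def standard_registry() -> FunctionRegistry:
    """Core operators plus the domain integrators — the default ontology."""
    reg = core_operator_set()
    for d in _domain_defs():
        reg.register(d)
    return reg
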