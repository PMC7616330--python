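"""Published JSON-Schema documents for the two wire formats, plus a small
validator for the keyword subset those schemas use.

The schemas ship as package data (``schemas/mdf.schema.json`` and
``schemas/tensor_graph.schema.json``) so external tooling can consume
them; :func:`validate_instance` implements exactly the keywords they use
(type, properties, patternProperties, additionalProperties, required,
items, enum, anyOf, $ref into $defs, minProperties/maxProperties,
minimum), which keeps the published documents honest without pulling in a
full validator dependency.
"""

from __future__ import annotations

import json
import re
from importlib import resources

__all__ = ["load_schema", "validate_instance", "SchemaValidationError"]


class SchemaValidationError(ValueError):
    def __init__(self, path: str, message: str):
        super().__init__(f"{path or '$'}: {message}")
        self.path = path


def load_schema(name: str) -> dict:
    """Load a shipped schema by name: ``"mdf"`` or ``"tensor_graph"``."""
    text = (resources.files("mdfkit") / "schemas" / f"{name}.schema.json").read_text()
    return json.loads(text)


_TYPES = {
    "object": lambda v: isinstance(v, dict),
    "array": lambda v: isinstance(v, list),
    "string": lambda v: isinstance(v, str),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "boolean": lambda v: isinstance(v, bool),
    "null": lambda v: v is None,
}


def _resolve(ref: str, root: dict) -> dict:
    if not ref.startswith("#/"):
        raise ValueError(f"only local $ref supported, got {ref!r}")
    node = root
    for part in ref[2:].split("/"):
        node = node[part]
    return node


def validate_instance(instance, schema: dict, root: dict | None = None,
                      path: str = "") -> None:
    """Raise :class:`SchemaValidationError` on the first violation found."""
    root = root if root is not None else schema

    if "$ref" in schema:
        validate_instance(instance, _resolve(schema["$ref"], root), root, path)
        return

    if "anyOf" in schema:
        errors = []
        for alt in schema["anyOf"]:
            try:
                validate_instance(instance, alt, root, path)
                break
            except SchemaValidationError as err:
                errors.append(str(err))
        else:
            raise SchemaValidationError(
                path, "matches no alternative: " + " | ".join(errors))

    stype = schema.get("type")
    if stype is not None:
        types = stype if isinstance(stype, list) else [stype]
        if not any(_TYPES[t](instance) for t in types):
            raise SchemaValidationError(
                path, f"expected {stype}, got {type(instance).__name__}")

    if "enum" in schema and instance not in schema["enum"]:
        raise SchemaValidationError(path, f"{instance!r} not in {schema['enum']}")

    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            raise SchemaValidationError(
                path, f"{instance} below minimum {schema['minimum']}")

    if isinstance(instance, dict):
        if "minProperties" in schema and len(instance) < schema["minProperties"]:
            raise SchemaValidationError(path, "too few properties")
        if "maxProperties" in schema and len(instance) > schema["maxProperties"]:
            raise SchemaValidationError(path, "too many properties")
        for key in schema.get("required", ()):
            if key not in instance:
                raise SchemaValidationError(path, f"missing required key {key!r}")
        props = schema.get("properties", {})
        patterns = schema.get("patternProperties", {})
        extra = schema.get("additionalProperties", True)
        for key, val in instance.items():
            kpath = f"{path}/{key}"
            matched = False
            if key in props:
                validate_instance(val, props[key], root, kpath)
                matched = True
            for pattern, sub in patterns.items():
                if re.search(pattern, key):
                    validate_instance(val, sub, root, kpath)
                    matched = True
            if not matched:
                if extra is False:
                    raise SchemaValidationError(kpath, "unexpected key")
                if isinstance(extra, dict):
                    validate_instance(val, extra, root, kpath)

    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            validate_instance(item, schema["items"], root, f"{path}[{i}]")
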