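"""Structural validation of the analysis-report JSON against the shipped schema.

A deliberately small validator covering the subset of JSON Schema the
report schema uses: ``type``, ``properties``, ``required`` and ``items``.
"""

from __future__ import annotations

import importlib.resources
import json

__all__ = ["report_schema", "validate_report", "SchemaError"]

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "number": (int, float),
    "null": type(None),
}


class SchemaError(ValueError):
    pass


def report_schema() -> dict:
    text = (
        importlib.resources.files("remotecm").joinpath("data/report_schema.json")
    ).read_text()
    return json.loads(text)


def _validate(value, schema: dict, path: str) -> None:
    expected = schema.get("type")
    if expected is not None:
        types = expected if isinstance(expected, list) else [expected]
        ok = False
        for t in types:
            py = _TYPES[t]
            if isinstance(value, py) and not (
                t in ("integer", "number") and isinstance(value, bool)
            ):
                ok = True
                break
        if not ok:
            raise SchemaError(f"{path or '<root>'}: expected {expected}, got {type(value).__name__}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise SchemaError(f"{path or '<root>'}: missing required key {key!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in value:
                _validate(value[key], subschema, f"{path}.{key}" if path else key)
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _validate(item, schema["items"], f"{path}[{i}]")


def validate_report(report: dict) -> None:
    """Raise SchemaError when the report does not match the shipped schema."""
    _validate(report, report_schema(), "")
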