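"""Prediction-report JSON schema and a minimal structural validator.

The report format is published as ``report_schema.json`` next to this
module; :func:`validate_report` checks a report object against it. The
validator covers the subset of JSON Schema the published schema uses
(object/array nesting, required keys, primitive types, numeric bounds).
"""

from __future__ import annotations

import json
from importlib import resources

_TYPE_CHECKS = {
    "object": lambda v: isinstance(v, dict),
    "array": lambda v: isinstance(v, list),
    "string": lambda v: isinstance(v, str),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "boolean": lambda v: isinstance(v, bool),
    "null": lambda v: v is None,
}


class ReportValidationError(ValueError):
    pass


def load_schema() -> dict:
    with resources.files("oratox").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def _check(value, schema: dict, path: str) -> None:
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        if not any(_TYPE_CHECKS[t](value) for t in types):
            raise ReportValidationError(
                f"{path}: expected {'/'.join(types)}, got {type(value).__name__}"
            )
    if value is None:
        return
    if "minimum" in schema and isinstance(value, (int, float)) and value < schema["minimum"]:
        raise ReportValidationError(f"{path}: {value} below minimum {schema['minimum']}")
    if "maximum" in schema and isinstance(value, (int, float)) and value > schema["maximum"]:
        raise ReportValidationError(f"{path}: {value} above maximum {schema['maximum']}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise ReportValidationError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, f"{path}.{key}")
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _check(item, schema["items"], f"{path}[{i}]")


def validate_report(report: dict) -> None:
    """Raise :class:`ReportValidationError` unless the report fits the schema."""
    _check(report, load_schema(), "report")
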