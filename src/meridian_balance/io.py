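"""Serialization, configuration and case-file reading.

JSON is the canonical interchange format; CSV is provided for the flat
tables (meridian reference, counting cascade, system summary).  Case
files and configuration may be JSON or YAML.  All schemas carry a
``schema_version`` and round-trip stably: ``read(write(x)) == x``.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .clock import meridian_at
from .protocol import CaseScript, SomatotopicMap, default_somatotopic_map
from .systems import PairingSystem, name_historical, passes_intrinsic_rules

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "SchemaError",
    "read_case",
    "write_report",
    "systems_to_dicts",
    "systems_from_dicts",
    "load_somatotopic_map",
]

SCHEMA_VERSION = "1.0"


class RunConfig(BaseModel):
    """Run-wide configuration; the defaults reproduce every published count."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    step5_policy: Literal["exclude", "include"] = "exclude"
    somatotopic_map_path: Optional[str] = None
    output_format: Literal["json", "csv", "text"] = "json"
    log_level: str = "WARNING"


class SchemaError(ValueError):
    """Malformed input file; the message points at the offending field."""


def _format_validation_error(exc: ValidationError, path: str | Path) -> str:
    lines = [f"invalid case file {path}:"]
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  at {loc}: {err['msg']}")
    return "\n".join(lines)


def _load_structured(path: str | Path) -> object:
    text = Path(path).read_text()
    suffix = Path(path).suffix.lower()
    if suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        return yaml.safe_load(text)


def read_case(path: str | Path) -> CaseScript:
    """Read a scripted case (presentation + staged findings) from JSON/YAML."""
    data = _load_structured(path)
    try:
        return CaseScript.model_validate(data)
    except ValidationError as exc:
        raise SchemaError(_format_validation_error(exc, path)) from exc


def write_case(script: CaseScript) -> str:
    return json.dumps(script.model_dump(mode="json"), indent=2)


def systems_to_dicts(systems: Sequence[PairingSystem]) -> list[dict[str, object]]:
    return [s.to_dict() for s in systems]


def systems_from_dicts(rows: Sequence[dict[str, object]]) -> list[PairingSystem]:
    """Rebuild pairing systems from their serialized form (round-trip)."""
    out = []
    for row in rows:
        pairs = [tuple(p) for p in row["positions"]]  # type: ignore[index]
        report = passes_intrinsic_rules(pairs)
        if not report.passed:
            raise SchemaError(
                f"serialized system violates the intrinsic rules: {report.failures()}"
            )
        assert report.polarity_profile is not None
        out.append(
            PairingSystem(
                pairs=report.matching,
                step_signature=report.step_signature,
                symmetry_periods=report.symmetry_periods,
                polarity_profile=report.polarity_profile,
                names=tuple(name_historical(report.matching)),
            )
        )
    return out


def _flatten(obj: object) -> object:
    if hasattr(obj, "to_dict"):
        return obj.to_dict()  # type: ignore[union-attr]
    if isinstance(obj, (list, tuple)):
        return [_flatten(x) for x in obj]
    return obj


def write_report(obj: object, fmt: str = "json") -> str:
    """Serialize a report object (or list of them) as json, csv or text."""
    data = _flatten(obj)
    if fmt == "json":
        return json.dumps(data, indent=2, default=str)
    if fmt == "csv":
        rows = data if isinstance(data, list) else [data]
        if not rows or not all(isinstance(r, dict) for r in rows):
            raise ValueError("csv output requires a flat record or list of records")
        fieldnames: list[str] = []
        for r in rows:
            for k in r:  # type: ignore[union-attr]
                if k not in fieldnames:
                    fieldnames.append(k)
        buf = _io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=fieldnames)
        writer.writeheader()
        for r in rows:
            writer.writerow(
                {
                    k: json.dumps(v) if isinstance(v, (dict, list)) else v
                    for k, v in r.items()  # type: ignore[union-attr]
                }
            )
        return buf.getvalue()
    if fmt == "text":
        return yaml.safe_dump(json.loads(json.dumps(data, default=str)), sort_keys=False)
    raise ValueError(f"unsupported format {fmt!r}; expected json, csv or text")


def load_somatotopic_map(path: str | Path | None) -> SomatotopicMap:
    """Load a user somatotopic map, or the default when ``path`` is None.

    The file holds a list of ``{regions: [a, b], kind: image|mirror}``
    entries which extend the shipped map.
    """
    base = default_somatotopic_map()
    if path is None:
        return base
    data = _load_structured(path)
    if not isinstance(data, list):
        raise SchemaError(f"somatotopic map {path} must be a list of entries")
    extra = []
    for i, entry in enumerate(data):
        try:
            a, b = entry["regions"]
            extra.append((a, b, entry.get("kind", "image")))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(
                f"somatotopic map {path}: entry {i} malformed ({exc})"
            ) from exc
    return base.extended(extra)
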