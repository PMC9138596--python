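"""Reading and writing design files (YAML; JSON accepted as a subset)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import ValidationError

from .design import ARUnitDesign, ensure_valid
from .errors import DesignParseError


def design_json_schema() -> dict:
    """JSON schema of the design-file dialect (generated from the model)."""
    return ARUnitDesign.model_json_schema()


def read_design(path: str | Path, validate: bool = True) -> ARUnitDesign:
    """Load a design from a YAML (or JSON) file.

    Raises :class:`DesignParseError` on malformed input (with line context
    where the parser provides it) and
    :class:`~reefscore.errors.DesignValidationError` when the design
    violates a geometric invariant.
    """
    path = Path(path)
    text = path.read_text()
    try:
        payload = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise DesignParseError(f"{path}: malformed design file{where}: {exc}") from exc
    if not isinstance(payload, dict):
        raise DesignParseError(f"{path}: expected a mapping at the top level")
    try:
        design = ARUnitDesign.model_validate(payload)
    except ValidationError as exc:
        raise DesignParseError(f"{path}: schema violation: {exc}") from exc
    if validate:
        ensure_valid(design)
    return design


def write_design(design: ARUnitDesign, path: str | Path) -> Path:
    """Serialise a design to YAML.  ``write(read(x))`` round-trips."""
    path = Path(path)
    payload = design.model_dump(mode="json", exclude_none=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def write_design_json(design: ARUnitDesign, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(design.model_dump(mode="json", exclude_none=True), indent=2)
    )
    return path
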