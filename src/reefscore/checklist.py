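"""Qualitative design checklist from the marine-ecosystem-ecology model.

Each reef-unit determinant carries a fixed sign pattern of potential
impacts on four ecosystem dimensions — substrate availability and light
supply (both energy), nutrient supply, and habitat for settling
individuals.  The checklist reports, for one design, which determinants
are present and which dimensions each one touches; it is advisory
guidance for the designer, upstream of the quantitative index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .design import ARUnitDesign, ensure_valid

Status = Literal["present", "absent", "not-evaluable"]

# dimension -> +1 (positive) / -1 (negative); absent keys mean no impact
_SIGN_TABLE: list[tuple[str, dict[str, int]]] = [
    ("material_type", {"energy-substrate": +1}),
    ("material_ph", {"energy-substrate": +1}),
    ("roughness", {"energy-substrate": +1}),
    ("area", {"energy-substrate": +1, "habitat": +1}),
    ("verticality", {"energy-substrate": +1, "energy-light": -1, "nutrients": +1}),
    ("upper_central_hole", {"energy-light": +1}),
    ("lateral_holes", {"energy-substrate": -1, "nutrients": +1}),
    ("nest_cavity_size", {"habitat": +1}),
    ("nest_cavity_type", {"habitat": +1}),
    ("nest_cavity_number", {"habitat": +1}),
]

DETERMINANTS = tuple(name for name, _ in _SIGN_TABLE)

SEAWATER_PH_RANGE = (7.4, 7.6)


@dataclass
class ChecklistFinding:
    determinant: str
    status: Status
    impacts: dict[str, int]
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "determinant": self.determinant,
            "status": self.status,
            "impacts": dict(self.impacts),
            "note": self.note,
        }


def _status(design: ARUnitDesign, determinant: str) -> tuple[Status, str]:
    if determinant == "material_type":
        return ("present", design.material) if design.material else ("absent", "")
    if determinant == "material_ph":
        if design.material_ph is None:
            return "not-evaluable", "material pH not declared"
        lo, hi = SEAWATER_PH_RANGE
        if lo <= design.material_ph <= hi:
            return "present", f"pH {design.material_ph:g} within seawater range"
        return "absent", (
            f"pH {design.material_ph:g} outside the seawater range "
            f"[{lo}, {hi}]"
        )
    if determinant == "roughness":
        if design.roughness_factor_vertical != 1.0:
            return "present", f"f_rv = {design.roughness_factor_vertical:g}"
        return "absent", "smooth formed finish (f_rv = 1)"
    if determinant == "area":
        return "present", f"{design.bounding_volume:.2f} m^3 prism"
    if determinant == "verticality":
        return "present", "prism presents four vertical faces"
    if determinant == "upper_central_hole":
        hole = design.central_hole()
        if hole is None:
            return "absent", ""
        return "present", f"{hole.diameter * 1000:.0f} mm central hole"
    if determinant == "lateral_holes":
        holes = design.lateral_holes()
        if not holes:
            return "absent", ""
        sizes = ", ".join(f"{h.diameter * 1000:.0f} mm" for h in holes)
        return "present", f"{len(holes)} lateral hole(s): {sizes}"
    # nest_cavity_{size,type,number}
    if not design.nest_cavities:
        return "absent", ""
    if determinant == "nest_cavity_number":
        return "present", f"{len(design.nest_cavities)} cavities"
    diameters = sorted({round(c.diameter, 6) for c in design.nest_cavities})
    sizes = ", ".join(f"{d * 100:.0f} cm" for d in diameters)
    return "present", f"cylindrical blind cavities of {sizes}"


def meem_checklist(design: ARUnitDesign) -> list[ChecklistFinding]:
    """One finding per determinant, with its fixed impact-sign pattern."""
    ensure_valid(design)
    findings = []
    for determinant, impacts in _SIGN_TABLE:
        status, note = _status(design, determinant)
        findings.append(
            ChecklistFinding(
                determinant=determinant,
                status=status,
                impacts=dict(impacts),
                note=note,
            )
        )
    return findings
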