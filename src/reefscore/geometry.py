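"""Surface-inventory accounting for reef-unit designs.

The ecological index works from an inventory of exposed surfaces, carried
in cm**2 (the working unit of the index):

* ``vertical_cm2`` (S_v) — external vertical wall area, minus through-hole
  openings that pierce those walls, plus the cylindrical wall of a top
  central cavity (an internal vertical surface reached by sunlight).
* ``horizontal_cm2`` (S_h) — top face area minus the central-hole opening,
  plus the cavity floor disc.  The seabed-contact bottom face and any
  stability slab carry no biological function and are excluded.
* ``lateral_hole_areas`` — one (opening area, roughness factor) entry per
  wall breached by each lateral hole; these are subtracted in the
  upwelling-surface budget because wall permeability weakens the upwelling
  and back-eddy effects.
* ``nest_cavity_areas`` — one opening-disc area per cavity.  Cavity
  openings are *not* subtracted from the host faces, and cavity interior
  walls are not inventoried: the habitat budget counts sheltered opening
  area only.

Two conventions are flag-configurable because published surface take-offs
do not always follow them (see :class:`InventoryOptions`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .design import ARUnitDesign, SurfaceOverrides, ensure_valid

M2_TO_CM2 = 1.0e4


@dataclass(frozen=True)
class InventoryOptions:
    """Accounting conventions for :func:`compute_surface_inventory`.

    subtract_through_holes
        Remove through-hole opening discs from their host-face areas
        (holes remove attachment substrate).
    include_central_cavity_interior
        Add the central cavity's cylindrical wall to S_v and its floor
        disc to S_h (the top opening admits sunlight to the interior).
    lateral_hole_walls
        ``"per_wall"`` books one opening entry per wall breached by a
        lateral hole (exterior wall plus interior-cavity wall, or two
        exterior walls for a straight-through bore); ``"per_hole"`` books
        a single entry per hole.
    """

    subtract_through_holes: bool = True
    include_central_cavity_interior: bool = True
    lateral_hole_walls: str = "per_wall"  # or "per_hole"


@dataclass
class SurfaceInventory:
    """Derived areas consumed by the index engine (areas in cm**2)."""

    vertical_cm2: float
    horizontal_cm2: float
    lateral_hole_areas: list[tuple[float, float]] = field(default_factory=list)
    nest_cavity_areas: list[float] = field(default_factory=list)
    inclined_surfaces: list[tuple[float, float]] = field(default_factory=list)
    conventions: dict = field(default_factory=dict)
    overrides: Optional[SurfaceOverrides] = None

    @property
    def nest_cavities_total_cm2(self) -> float:
        return float(sum(self.nest_cavity_areas))

    def to_frame(self) -> pd.DataFrame:
        """One row per surface element: area, class, factor."""
        rows = [
            {"area_cm2": self.vertical_cm2, "class": "vertical", "factor": None},
            {"area_cm2": self.horizontal_cm2, "class": "horizontal", "factor": None},
        ]
        rows += [
            {"area_cm2": a, "class": "lateral_hole", "factor": fr}
            for a, fr in self.lateral_hole_areas
        ]
        rows += [
            {"area_cm2": a, "class": "nest_cavity", "factor": None}
            for a in self.nest_cavity_areas
        ]
        rows += [
            {"area_cm2": a, "class": "inclined", "factor": theta}
            for a, theta in self.inclined_surfaces
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "vertical_cm2": self.vertical_cm2,
            "horizontal_cm2": self.horizontal_cm2,
            "lateral_hole_areas": [list(t) for t in self.lateral_hole_areas],
            "nest_cavity_areas": list(self.nest_cavity_areas),
            "inclined_surfaces": [list(t) for t in self.inclined_surfaces],
            "conventions": dict(self.conventions),
            "overrides": self.overrides.model_dump() if self.overrides else None,
        }


def compute_surface_inventory(
    design: ARUnitDesign,
    options: InventoryOptions | None = None,
) -> SurfaceInventory:
    """Derive the exposed-surface inventory of a validated design.

    Raises :class:`~reefscore.errors.DesignValidationError` when the design
    violates its geometric invariants.
    """
    ensure_valid(design)
    opts = options or InventoryOptions()

    # external vertical walls: 2 faces of length x height + 2 of width x height
    s_v = 2.0 * (design.length + design.width) * design.height
    # horizontal exposed area: top face only (bottom rests on the seabed)
    s_h = design.length * design.width

    central = design.central_hole()
    if central is not None and opts.subtract_through_holes:
        s_h -= central.opening_area_m2
    if (
        central is not None
        and central.connects_to == "interior_cavity"
        and opts.include_central_cavity_interior
    ):
        depth = central.depth if central.depth is not None else design.height
        s_v += math.pi * central.diameter * depth  # cavity wall
        s_h += central.opening_area_m2            # cavity floor disc

    lateral_entries: list[tuple[float, float]] = []
    for hole in design.lateral_holes():
        area_cm2 = hole.opening_area_m2 * M2_TO_CM2
        if opts.subtract_through_holes:
            s_v -= hole.opening_area_m2  # opening removes exterior wall substrate
        walls = 1
        if opts.lateral_hole_walls == "per_wall":
            walls = 2  # exterior wall + cavity wall, or both exterior walls
            if (
                hole.connects_to == "interior_cavity"
                and opts.include_central_cavity_interior
                and central is not None
                and opts.subtract_through_holes
            ):
                s_v -= hole.opening_area_m2  # breach of the cavity wall
        lateral_entries.extend([(area_cm2, hole.roughness_factor)] * walls)

    nest_areas = [
        c.opening_area_m2 * M2_TO_CM2 for c in design.nest_cavities
    ]
    inclined = [
        (p.area * M2_TO_CM2, p.angle_deg) for p in design.inclined_panels
    ]

    return SurfaceInventory(
        vertical_cm2=s_v * M2_TO_CM2,
        horizontal_cm2=s_h * M2_TO_CM2,
        lateral_hole_areas=lateral_entries,
        nest_cavity_areas=nest_areas,
        inclined_surfaces=inclined,
        conventions={
            "subtract_through_holes": opts.subtract_through_holes,
            "include_central_cavity_interior": opts.include_central_cavity_interior,
            "lateral_hole_walls": opts.lateral_hole_walls,
            "bottom_face_excluded": True,
            "slab_excluded": True,
            "nest_openings_not_subtracted": True,
            "lateral_bore_walls_not_inventoried": True,
        },
        overrides=design.surface_overrides,
    )
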