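"""Parametric description of a single artificial-reef (AR) unit.

An AR unit is modelled as a rectangular concrete prism (typically a cube of
edge ~1.5 m) that may carry three kinds of features:

* a top central **through hole** opening into an interior cavity, which
  admits sunlight and connects the interior with the water column;
* **lateral through holes** piercing vertical walls, which let water and
  nutrients circulate between the exterior and the interior cavity;
* blind **nest cavities** — cylindrical indentations on the faces that
  provide shelter and spawning substrate and never connect two spaces.

A stability slab of height ``slab_height`` may sit under the prism; it has
no biological role and is excluded from all ecological surface accounting.

Faces are named by compass convention with the prism axes: ``length`` runs
east–west, ``width`` north–south, ``height`` vertically.  Feature positions
are face-local ``(u, v)`` offsets in metres from the face centre (``u``
horizontal, ``v`` vertical on wall faces; ``u`` along length, ``v`` along
width on the top face).
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field

Face = Literal["top", "bottom", "north", "south", "east", "west"]

VERTICAL_FACES: tuple[Face, ...] = ("north", "south", "east", "west")


class ThroughHole(BaseModel):
    """A cylindrical hole connecting two spaces of the unit.

    ``orientation`` distinguishes the upper central hole (vertical axis,
    host face ``top``) from lateral holes (horizontal axis, hosted on a
    wall).  ``connects_to`` records whether the hole ends in the interior
    cavity or pierces straight through to the opposite face.  ``depth`` is
    the axial length of the bore; for the central hole it is the cavity
    depth measured from the top face.
    """

    model_config = ConfigDict(extra="forbid")

    diameter: float
    orientation: Literal["vertical_top", "horizontal_lateral"]
    host_face: Face
    connects_to: Literal["interior_cavity", "opposite_face"]
    roughness_factor: float = 1.0
    depth: Optional[float] = None
    center: Tuple[float, float] = (0.0, 0.0)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def opening_area_m2(self) -> float:
        """Cross-section (opening disc) area of the bore, m**2."""
        return math.pi * self.radius**2


class NestCavity(BaseModel):
    """A blind cylindrical hole providing shelter (never a connection)."""

    model_config = ConfigDict(extra="forbid")

    diameter: float
    depth: float
    host_face: Face = "north"
    center: Tuple[float, float] = (0.0, 0.0)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def opening_area_m2(self) -> float:
        return math.pi * self.radius**2


class SurfaceOverrides(BaseModel):
    """Externally supplied surface totals (cm**2) that take precedence over
    geometry-derived values in index computations.

    Used when a design's surface bookkeeping comes from a source (drawing
    take-offs, published tables) whose conventions cannot be reconstructed
    from the parametric description alone.
    """

    model_config = ConfigDict(extra="forbid")

    weighted_exposed_cm2: Optional[float] = None
    upwelling_cm2: Optional[float] = None
    nest_cavities_cm2: Optional[float] = None


class InclinedPanel(BaseModel):
    """A planar sloped surface attached to the unit (area in m**2,
    inclination in degrees from horizontal)."""

    model_config = ConfigDict(extra="forbid")

    area: float
    angle_deg: float


class ARUnitDesign(BaseModel):
    """Full parametric description of one reef unit."""

    model_config = ConfigDict(extra="forbid")

    name: str
    length: float
    width: float
    height: float
    through_holes: list[ThroughHole] = Field(default_factory=list)
    nest_cavities: list[NestCavity] = Field(default_factory=list)
    inclined_panels: list[InclinedPanel] = Field(default_factory=list)
    material: str = "concrete"
    material_ph: Optional[float] = None
    roughness_factor_vertical: float = 1.0
    slab_height: float = 0.0
    mass_tonnes: Optional[float] = None
    bulk_density: float = 2400.0  # kg/m3, plain structural concrete
    surface_overrides: Optional[SurfaceOverrides] = None

    # --- derived geometry helpers -------------------------------------

    def face_dimensions(self, face: Face) -> tuple[float, float]:
        """(u-extent, v-extent) of a face in metres."""
        if face in ("top", "bottom"):
            return (self.length, self.width)
        if face in ("north", "south"):
            return (self.length, self.height)
        return (self.width, self.height)

    def dimension_along_normal(self, face: Face) -> float:
        """Prism extent along the outward normal of ``face``."""
        if face in ("top", "bottom"):
            return self.height
        if face in ("north", "south"):
            return self.width
        return self.length

    @property
    def bounding_volume(self) -> float:
        """Gross prism volume, m**3 (slab excluded)."""
        return self.length * self.width * self.height

    @property
    def footprint_area(self) -> float:
        return self.length * self.width

    def central_hole(self) -> Optional[ThroughHole]:
        """The upper central hole, if the design has one."""
        for hole in self.through_holes:
            if hole.orientation == "vertical_top":
                return hole
        return None

    def lateral_holes(self) -> list[ThroughHole]:
        return [
            h for h in self.through_holes
            if h.orientation == "horizontal_lateral"
        ]


def _features_on_face(design: ARUnitDesign, face: Face):
    """All (label, radius, center) openings hosted on ``face``."""
    out = []
    for i, h in enumerate(design.through_holes):
        if h.host_face == face:
            out.append((f"through_holes[{i}]", h.radius, h.center))
    for j, c in enumerate(design.nest_cavities):
        if c.host_face == face:
            out.append((f"nest_cavities[{j}]", c.radius, c.center))
    return out


def validate_design(design: ARUnitDesign) -> list[str]:
    """Check every geometric invariant; return violations (empty = valid).

    Violations are returned, not raised, so a caller can present all
    problems with a design file at once.  Each message names the offending
    field.
    """
    v: list[str] = []

    for dim in ("length", "width", "height"):
        if getattr(design, dim) <= 0:
            v.append(f"{dim}: must be > 0")
    if design.slab_height < 0:
        v.append("slab_height: must be >= 0")
    if design.roughness_factor_vertical <= 0:
        v.append("roughness_factor_vertical: must be > 0")
    if design.bulk_density <= 0:
        v.append("bulk_density: must be > 0")
    if v:
        # face-fit checks below would be meaningless on a degenerate prism
        return v

    for i, h in enumerate(design.through_holes):
        tag = f"through_holes[{i}]"
        if h.diameter <= 0:
            v.append(f"{tag}.diameter: must be > 0")
        if h.roughness_factor <= 0:
            v.append(f"{tag}.roughness_factor: must be > 0")
        if h.orientation == "vertical_top" and h.host_face != "top":
            v.append(f"{tag}.host_face: vertical_top hole must sit on 'top'")
        if h.orientation == "horizontal_lateral" and h.host_face not in VERTICAL_FACES:
            v.append(
                f"{tag}.host_face: lateral hole must sit on a vertical face"
            )
        axis = design.dimension_along_normal(h.host_face)
        if h.depth is not None and h.depth > axis:
            v.append(
                f"{tag}.depth: exceeds prism dimension {axis:g} m along axis"
            )
        if h.connects_to == "interior_cavity" and h.orientation == "vertical_top" \
                and h.depth is None:
            v.append(f"{tag}.depth: required for an interior-cavity hole")

    for j, c in enumerate(design.nest_cavities):
        tag = f"nest_cavities[{j}]"
        if c.diameter <= 0:
            v.append(f"{tag}.diameter: must be > 0")
        if c.depth <= 0:
            v.append(f"{tag}.depth: must be > 0")
        axis = design.dimension_along_normal(c.host_face)
        if c.depth >= axis:
            v.append(
                f"{tag}.depth: a nest cavity is blind and must stop short of "
                f"the opposite face ({axis:g} m)"
            )

    for k, p in enumerate(design.inclined_panels):
        tag = f"inclined_panels[{k}]"
        if p.area <= 0:
            v.append(f"{tag}.area: must be > 0")
        if not (0.0 <= p.angle_deg <= 90.0):
            v.append(f"{tag}.angle_deg: must be within [0, 90]")

    faces: tuple[Face, ...] = ("top", "bottom", "north", "south", "east", "west")
    for face in faces:
        feats = _features_on_face(design, face)
        fu, fv = design.face_dimensions(face)
        for label, r, (cu, cv) in feats:
            if abs(cu) + r > fu / 2 + 1e-12 or abs(cv) + r > fv / 2 + 1e-12:
                v.append(
                    f"{label}: opening exceeds face '{face}' "
                    f"({fu:g} x {fv:g} m)"
                )
        for a in range(len(feats)):
            for b in range(a + 1, len(feats)):
                la, ra, (ua, va) = feats[a]
                lb, rb, (ub, vb) = feats[b]
                if math.hypot(ua - ub, va - vb) < ra + rb - 1e-12:
                    v.append(
                        f"{la} and {lb}: openings overlap on face '{face}'"
                    )

    return v


def ensure_valid(design: ARUnitDesign) -> ARUnitDesign:
    """Raise :class:`DesignValidationError` if the design is invalid."""
    from .errors import DesignValidationError

    violations = validate_design(design)
    if violations:
        raise DesignValidationError(violations)
    return design
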