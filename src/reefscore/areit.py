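"""The AREIT comparative index and its three partial indices.

AREIT (AR-Ecosystem Index Transformation) scores a candidate reef-unit
design against a reference design of equal bounding volume as the sum of
three dimensionless partials:

* **EM** (energy modification) — ratio of sunlight-weighted exposed areas,
  ``(S_v*f_ev + S_h*f_eh) / (S_vr*f_ev + S_hr*f_eh)``, with exposure
  factors ``f_ev = 0.5`` for vertical and ``f_eh = 1`` for horizontal
  surfaces.  Sloped surfaces enter with an interpolated exposure factor.
* **NM** (nutrient modification) — ratio of upwelling-effective surfaces
  ``S_upwelling = S_v*f_rv - sum_i S_lh,i*f_r,i`` (vertical area weighted
  by roughness, minus lateral-hole openings which make the walls
  permeable).  Sloped surfaces enter with a verticality factor between 0
  (horizontal) and 1 (vertical).
* **HM** (habitat modification) — ratio of summed nest-cavity opening
  areas.

Each partial equals 1 when the candidate is the reference itself; with
unit weights AREIT is then 3, and values above 3 indicate a design with a
larger positive impact on the ecosystem than the reference.  The index is
purely comparative: designs of very different bounding volume should not
be compared (a warning is emitted).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional

from .design import ARUnitDesign
from .errors import UndefinedIndexError
from .geometry import InventoryOptions, SurfaceInventory, compute_surface_inventory

RoundingMode = Literal["paper", "full"]
InclinedModel = Literal["linear", "sine"]


def _round2(x: float) -> float:
    """Round half-up to two decimals (display/reporting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FactorSet:
    """Exposure and roughness factors plus partial-index weights.

    ``f_ev``/``f_eh`` are the sunlight-exposure factors of vertical and
    horizontal surfaces (defaults 0.5 and 1).  ``f_rv`` is the roughness
    factor of the vertical surfaces (1 = smooth formed concrete; supplied
    per material/finish).  ``weights`` order is (EM, NM, HM); a zero
    weight drops that dimension from the comparison.  ``inclined_model``
    selects how factors interpolate with inclination angle.
    """

    f_ev: float = 0.5
    f_eh: float = 1.0
    f_rv: float = 1.0
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    inclined_model: InclinedModel = "linear"

    def __post_init__(self):
        if not (0 < self.f_ev <= self.f_eh):
            raise ValueError("exposure factors must satisfy 0 < f_ev <= f_eh")
        if self.f_rv <= 0:
            raise ValueError("f_rv must be > 0")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be >= 0")


@dataclass
class IndexReport:
    """All partials, the overall index and the intermediate sums behind
    them, for one candidate/reference comparison."""

    candidate: str
    reference: str
    em: Optional[float]
    nm: Optional[float]
    hm: Optional[float]
    areit: float
    weighted_exposed_cm2: Optional[float]
    weighted_exposed_ref_cm2: Optional[float]
    upwelling_cm2: Optional[float]
    upwelling_ref_cm2: Optional[float]
    nest_cavities_cm2: Optional[float]
    nest_cavities_ref_cm2: Optional[float]
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rounding: RoundingMode = "paper"
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate,
            "reference": self.reference,
            "EM": self.em,
            "NM": self.nm,
            "HM": self.hm,
            "AREIT": self.areit,
            "weighted_exposed_cm2": self.weighted_exposed_cm2,
            "weighted_exposed_ref_cm2": self.weighted_exposed_ref_cm2,
            "upwelling_cm2": self.upwelling_cm2,
            "upwelling_ref_cm2": self.upwelling_ref_cm2,
            "nest_cavities_cm2": self.nest_cavities_cm2,
            "nest_cavities_ref_cm2": self.nest_cavities_ref_cm2,
            "weights": list(self.weights),
            "rounding": self.rounding,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------
# inclined-surface factor models

def inclined_exposure_factor(theta_deg: float, factors: FactorSet) -> float:
    """Sunlight-exposure factor of a plane inclined ``theta_deg`` degrees
    from horizontal: f_eh at 0 deg, f_ev at 90 deg, strictly monotone
    between (linear by default, cosine-shaped under the "sine" model)."""
    if not (0.0 <= theta_deg <= 90.0):
        raise ValueError(f"inclination angle {theta_deg} outside [0, 90] degrees")
    if factors.inclined_model == "sine":
        frac = math.sin(math.radians(theta_deg))
    else:
        frac = theta_deg / 90.0
    return factors.f_eh + (factors.f_ev - factors.f_eh) * frac


def inclined_upwelling_factor(
    theta_deg: float, model: InclinedModel = "linear"
) -> float:
    """Verticality factor for the upwelling contribution of a sloped
    plane: 0 at horizontal, 1 at vertical, strictly monotone."""
    if not (0.0 <= theta_deg <= 90.0):
        raise ValueError(f"inclination angle {theta_deg} outside [0, 90] degrees")
    if model == "sine":
        return math.sin(math.radians(theta_deg))
    return theta_deg / 90.0


# ---------------------------------------------------------------------
# partial indices

def weighted_exposed_area(inv: SurfaceInventory, factors: FactorSet) -> float:
    """Sunlight-weighted exposed area (cm**2), the EM numerator.

    Honours an explicit override when the inventory carries one.
    """
    if inv.overrides is not None and inv.overrides.weighted_exposed_cm2 is not None:
        return inv.overrides.weighted_exposed_cm2
    total = inv.vertical_cm2 * factors.f_ev + inv.horizontal_cm2 * factors.f_eh
    for area, theta in inv.inclined_surfaces:
        total += area * inclined_exposure_factor(theta, factors)
    return total


def energy_modification(
    candidate: SurfaceInventory,
    reference: SurfaceInventory,
    factors: FactorSet = FactorSet(),
) -> float:
    """EM: quotient of sunlight-weighted exposed areas."""
    denom = weighted_exposed_area(reference, factors)
    if denom <= 0:
        raise UndefinedIndexError(
            "energy", "reference contributes nothing to energy (zero exposed area)"
        )
    return weighted_exposed_area(candidate, factors) / denom


def upwelling_surface(inv: SurfaceInventory, factors: FactorSet = FactorSet()) -> float:
    """Upwelling-effective surface (cm**2): roughness-weighted vertical
    area minus lateral-hole openings, plus verticality-weighted sloped
    surfaces; floored at zero.  Nest cavities never enter."""
    if inv.overrides is not None and inv.overrides.upwelling_cm2 is not None:
        return inv.overrides.upwelling_cm2
    total = inv.vertical_cm2 * factors.f_rv
    total -= sum(area * fr for area, fr in inv.lateral_hole_areas)
    for area, theta in inv.inclined_surfaces:
        total += (
            area
            * factors.f_rv
            * inclined_upwelling_factor(theta, factors.inclined_model)
        )
    return max(total, 0.0)


def nutrient_modification(
    candidate: SurfaceInventory,
    reference: SurfaceInventory,
    factors: FactorSet = FactorSet(),
) -> float:
    """NM: quotient of upwelling-effective surfaces."""
    denom = upwelling_surface(reference, factors)
    if denom <= 0:
        raise UndefinedIndexError(
            "nutrient", "reference has zero upwelling surface"
        )
    return upwelling_surface(candidate, factors) / denom


def nest_cavity_area(inv: SurfaceInventory) -> float:
    if inv.overrides is not None and inv.overrides.nest_cavities_cm2 is not None:
        return inv.overrides.nest_cavities_cm2
    return inv.nest_cavities_total_cm2


def habitat_modification(
    candidate: SurfaceInventory, reference: SurfaceInventory
) -> float:
    """HM: quotient of summed nest-cavity opening areas."""
    denom = nest_cavity_area(reference)
    if denom <= 0:
        raise UndefinedIndexError(
            "habitat", "reference has no nest cavities"
        )
    return nest_cavity_area(candidate) / denom


# ---------------------------------------------------------------------
# overall index

def areit_from_inventories(
    candidate: SurfaceInventory,
    reference: SurfaceInventory,
    factors: FactorSet = FactorSet(),
    rounding: RoundingMode = "paper",
    candidate_name: str = "candidate",
    reference_name: str = "reference",
    extra_warnings: list[str] | None = None,
) -> IndexReport:
    """Assemble the full report from two pre-computed inventories."""
    w_em, w_nm, w_hm = factors.weights
    em = nm = hm = None
    wexp = wexp_r = upw = upw_r = nest = nest_r = None

    if w_em > 0:
        em = energy_modification(candidate, reference, factors)
        wexp = weighted_exposed_area(candidate, factors)
        wexp_r = weighted_exposed_area(reference, factors)
    if w_nm > 0:
        nm = nutrient_modification(candidate, reference, factors)
        upw = upwelling_surface(candidate, factors)
        upw_r = upwelling_surface(reference, factors)
    if w_hm > 0:
        hm = habitat_modification(candidate, reference)
        nest = nest_cavity_area(candidate)
        nest_r = nest_cavity_area(reference)

    def shaped(x: Optional[float]) -> Optional[float]:
        if x is None:
            return None
        return _round2(x) if rounding == "paper" else x

    em, nm, hm = shaped(em), shaped(nm), shaped(hm)
    areit = sum(
        w * p for w, p in zip((w_em, w_nm, w_hm), (em, nm, hm)) if p is not None
    )
    if rounding == "paper":
        # strip float dust from summing two-decimal partials without
        # disturbing genuinely weighted sums
        areit = round(areit, 10)
    return IndexReport(
        candidate=candidate_name,
        reference=reference_name,
        em=em,
        nm=nm,
        hm=hm,
        areit=areit,
        weighted_exposed_cm2=wexp,
        weighted_exposed_ref_cm2=wexp_r,
        upwelling_cm2=upw,
        upwelling_ref_cm2=upw_r,
        nest_cavities_cm2=nest,
        nest_cavities_ref_cm2=nest_r,
        weights=factors.weights,
        rounding=rounding,
        warnings=list(extra_warnings or []),
    )


def areit_index(
    candidate: ARUnitDesign,
    reference: ARUnitDesign,
    factors: FactorSet = FactorSet(),
    rounding: RoundingMode = "paper",
    inventory_options: InventoryOptions | None = None,
) -> IndexReport:
    """Score ``candidate`` against ``reference``.

    Both designs are validated, their surface inventories derived, and the
    weighted partials combined.  Under the default ``"paper"`` rounding
    each partial is rounded half-up to two decimals before summing (the
    reporting convention); ``"full"`` keeps full precision and is the mode
    used for programmatic comparison/ranking.
    """
    notes: list[str] = []
    vol_c, vol_r = candidate.bounding_volume, reference.bounding_volume
    if vol_r > 0 and abs(vol_c - vol_r) / vol_r > 0.05:
        msg = (
            f"bounding volumes differ by more than 5% "
            f"({vol_c:.3f} vs {vol_r:.3f} m^3): the index is only meaningful "
            f"between designs occupying the same volume"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    inv_c = compute_surface_inventory(candidate, inventory_options)
    inv_r = compute_surface_inventory(reference, inventory_options)
    return areit_from_inventories(
        inv_c,
        inv_r,
        factors,
        rounding,
        candidate_name=candidate.name,
        reference_name=reference.name,
        extra_warnings=notes,
    )
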