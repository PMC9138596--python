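"""Simplified wave-loading stability analysis for a reef unit.

Implements the desk-level stability procedure: derive a design wave from a
design sea state, evaluate near-bed wave(+current) kinematics with linear
(Airy) or first-order cnoidal theory, compute horizontal loads with the
Morison formulation, and check sliding and overturning of the unit, sizing
a ballast slab when the bare unit fails.

Conventions
-----------
* The design wave height is the Rayleigh-statistics maximum of the design
  sea state, ``H_max = H_s * sqrt(ln(N)/2)`` for ``N`` waves (N = 1000,
  roughly a three-hour storm, by default), capped by the depth-limited
  breaker height ``gamma * h`` (gamma = 0.78).
* Wave theory is selected by the Ursell number ``Ur = H L^2 / h^3``:
  cnoidal above a configurable threshold (default 26), else linear.
* A steady current is superposed on the orbital velocity in the drag term.
* Kinematics are evaluated at mid-height of the unit by default; a strip
  option integrates over >= 2 strips for tall configurations.
* Phase convention: ``phase = kx - wt``; horizontal velocity peaks at
  phase 0 (the crest) and the acceleration is in quadrature.

All quantities SI unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipe, ellipj, ellipk

from .design import ARUnitDesign, ensure_valid
from .errors import SlabInfeasibleError, WaveTheoryError

G = 9.81
RHO_SEAWATER = 1025.0


@dataclass(frozen=True)
class WaveConditions:
    """Design sea state at the reef site."""

    hs: float                 # significant wave height, m
    tp: float                 # peak period, s
    depth: float              # water depth, m
    n_waves: int = 1000       # waves in the design sea state
    current: float = 0.0      # depth-averaged steady current, m/s
    rho: float = RHO_SEAWATER  # water density, kg/m3

    def __post_init__(self):
        if self.hs < 0:
            raise ValueError("hs must be >= 0")
        if self.tp <= 0:
            raise ValueError("tp must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")


@dataclass(frozen=True)
class DesignWave:
    """The extreme individual wave used for the force analysis."""

    height: float
    period: float
    wavelength: float
    wavenumber: float
    theory: Literal["linear", "cnoidal"]
    breaking_limited: bool


@dataclass(frozen=True)
class ForceCoefficients:
    """Empirical coefficients of the force and stability model.

    Defaults suit a bluff cubic concrete block resting on sand: drag
    C_D = 1.05, inertia C_M = 2.0, concrete-on-sand friction mu = 0.6.
    Lift defaults to zero (hook for a user-supplied coefficient).
    """

    cd: float = 1.05
    cm: float = 2.0
    friction: float = 0.6
    cl: float = 0.0
    concrete_density: float = 2400.0  # kg/m3
    slab_plan_area: Optional[float] = None  # m2; default: unit footprint
    strips: int = 1  # vertical strips for kinematics integration


@dataclass
class StabilityReport:
    """Loads and safety factors for one design/sea-state combination."""

    design: str
    wave: DesignWave
    drag_max: float             # N, phase-swept maximum of the drag term
    inertia_max: float          # N, phase-swept maximum of the inertia term
    horizontal_force: float     # N, maximum of the phase-resolved sum
    lift_force: float           # N, at the governing phase
    submerged_weight: float     # N
    sliding_sf: float
    overturning_sf: float
    governing_phase: float      # rad
    slab_height: float          # m, slab included in this evaluation
    no_load_case: bool = False

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "wave": {
                "height_m": self.wave.height,
                "period_s": self.wave.period,
                "wavelength_m": self.wave.wavelength,
                "wavenumber_per_m": self.wave.wavenumber,
                "theory": self.wave.theory,
                "breaking_limited": self.wave.breaking_limited,
            },
            "drag_max_N": self.drag_max,
            "inertia_max_N": self.inertia_max,
            "horizontal_force_N": self.horizontal_force,
            "lift_force_N": self.lift_force,
            "submerged_weight_N": self.submerged_weight,
            "sliding_sf": self.sliding_sf,
            "overturning_sf": self.overturning_sf,
            "governing_phase_rad": self.governing_phase,
            "slab_height_m": self.slab_height,
            "no_load_case": self.no_load_case,
        }


# ---------------------------------------------------------------------
# wave theory

def solve_dispersion(period: float, depth: float) -> float:
    """Wavelength from the linear dispersion relation w^2 = g k tanh(k h).

    Newton iteration from the Eckart/deep-water seed; converges to a
    relative residual far below 1e-10 over the whole coastal range.
    """
    if period <= 0 or depth <= 0:
        raise ValueError("period and depth must be > 0")
    omega = 2.0 * math.pi / period
    target = omega**2 / G  # = k tanh(k h)
    k = max(target, target / math.sqrt(math.tanh(target * depth)))
    for _ in range(100):
        t = math.tanh(k * depth)
        f = k * t - target
        df = t + k * depth * (1.0 - t * t)
        step = f / df
        k -= step
        if abs(step) < 1e-15 * k:
            break
    return 2.0 * math.pi / k


def ursell_number(height: float, wavelength: float, depth: float) -> float:
    return height * wavelength**2 / depth**3


def design_wave(
    conditions: WaveConditions,
    gamma: float = 0.78,
    ursell_threshold: float = 26.0,
) -> DesignWave:
    """Derive the design wave from the sea state.

    Height is the Rayleigh maximum capped at the breaker limit; the theory
    flag records whether the wave is nonlinear enough (Ursell number above
    the threshold) to warrant cnoidal kinematics.
    """
    rayleigh = conditions.hs * math.sqrt(math.log(conditions.n_waves) / 2.0)
    limit = gamma * conditions.depth
    breaking = rayleigh > limit
    h_max = min(rayleigh, limit)
    wavelength = solve_dispersion(conditions.tp, conditions.depth)
    ur = ursell_number(h_max, wavelength, conditions.depth) if h_max > 0 else 0.0
    theory = "cnoidal" if ur > ursell_threshold else "linear"
    return DesignWave(
        height=h_max,
        period=conditions.tp,
        wavelength=wavelength,
        wavenumber=2.0 * math.pi / wavelength,
        theory=theory,
        breaking_limited=breaking,
    )


def linear_kinematics(
    wave: DesignWave,
    depth: float,
    z: float,
    current: float = 0.0,
    phase: float = 0.0,
) -> tuple[float, float]:
    """Airy horizontal velocity and acceleration at elevation ``z`` above
    the bed, with the steady current superposed on the velocity."""
    if not (0.0 <= z <= depth):
        raise ValueError(f"elevation z={z} outside the water column [0, {depth}]")
    if wave.height == 0.0:
        return current, 0.0
    k = wave.wavenumber
    omega = 2.0 * math.pi / wave.period
    profile = math.cosh(k * z) / math.sinh(k * depth)
    amp = 0.5 * wave.height * omega * profile
    u = amp * math.cos(phase) + current
    a = amp * omega * math.sin(phase)
    return u, a


def _cnoidal_celerity(m: float, height: float, depth: float) -> float:
    """First-order cnoidal phase speed."""
    K, E = ellipk(m), ellipe(m)
    corr = (height / (m * depth)) * (1.0 - m / 2.0 - 1.5 * E / K)
    return math.sqrt(G * depth) * (1.0 + corr)


def _m_from_ursell(ur: float) -> float:
    """Invert Ur = (16/3) m K(m)^2 for the elliptic parameter m."""
    def f(m):
        return 16.0 / 3.0 * m * ellipk(m) ** 2 - ur

    lo, hi = 1e-14, 1.0 - 1e-15
    if f(hi) < 0:  # pragma: no cover - K(m) diverges, cannot happen for ur>0
        raise WaveTheoryError(f"elliptic parameter not bracketed (Ur={ur:g})")
    return brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)


@lru_cache(maxsize=256)
def cnoidal_parameters(
    height: float, period: float, depth: float, max_iter: int = 200
) -> tuple[float, float, float]:
    """Solve (m, wavelength, celerity) of a first-order cnoidal wave from
    (H, T, h) by fixed-point iteration on L = c(m) T with m inverted from
    the Ursell number at each step.

    Raises :class:`WaveTheoryError` (reporting the Ursell number) when the
    iteration cannot converge, e.g. for waves far outside the cnoidal
    range.
    """
    if height <= 0:
        raise WaveTheoryError("cnoidal theory needs a finite wave height")
    L = math.sqrt(G * depth) * period  # shallow-water first guess
    m = 0.5
    for _ in range(max_iter):
        ur = ursell_number(height, L, depth)
        try:
            m = _m_from_ursell(ur)
            c = _cnoidal_celerity(m, height, depth)
        except (ValueError, WaveTheoryError) as exc:
            raise WaveTheoryError(
                f"cnoidal parameter solve failed at Ursell number {ur:.3g}"
            ) from exc
        if c <= 0:
            raise WaveTheoryError(
                f"cnoidal celerity non-physical at Ursell number {ur:.3g} "
                f"(wave too steep for first-order theory)"
            )
        L_new = c * period
        if abs(L_new - L) < 1e-12 * L:
            return m, L_new, c
        L = 0.5 * (L + L_new)  # damped update, robust near m -> 1
    raise WaveTheoryError(
        f"cnoidal parameter solve did not converge "
        f"(Ursell number {ursell_number(height, L, depth):.3g})"
    )


def cnoidal_surface(
    height: float, depth: float, m: float, phase: float
) -> float:
    """Surface elevation (m, about still water) of the cn^2 profile at the
    given phase (2*pi per wavelength, crest at 0)."""
    K, E = ellipk(m), ellipe(m)
    trough = (height / m) * (1.0 - m - E / K)
    frac = (phase / (2.0 * math.pi)) % 1.0
    _, cn, _, _ = ellipj(2.0 * K * frac, m)
    return trough + height * cn**2


def cnoidal_kinematics(
    wave: DesignWave,
    depth: float,
    z: float,
    phase: float = 0.0,
    current: float = 0.0,
) -> tuple[float, float]:
    """First-order cnoidal horizontal velocity and acceleration.

    The first-order velocity field is depth-uniform, ``u = c eta / h``
    (``eta`` the surface elevation about still water), the shallow-water
    mass-flux relation; ``z`` is accepted for interface symmetry with
    :func:`linear_kinematics` and only range-checked.  In the small-m
    limit the cn^2 profile degenerates to a sinusoid and the velocity
    matches the depth-averaged Airy value.
    """
    if not (0.0 <= z <= depth):
        raise ValueError(f"elevation z={z} outside the water column [0, {depth}]")
    if wave.height == 0.0:
        return current, 0.0
    m, L, c = cnoidal_parameters(wave.height, wave.period, depth)
    K = ellipk(m)
    frac = (phase / (2.0 * math.pi)) % 1.0
    sn, cn, dn, _ = ellipj(2.0 * K * frac, m)
    eta = cnoidal_surface(wave.height, depth, m, phase)
    u = c * eta / depth + current
    # du/dt with phase = kx - wt: d(cn^2)/dt = +2 cn sn dn * (2K/T)
    a = (c * wave.height / depth) * 2.0 * cn * sn * dn * (2.0 * K / wave.period)
    return u, a


def kinematics(
    wave: DesignWave,
    depth: float,
    z: float,
    phase: float = 0.0,
    current: float = 0.0,
) -> tuple[float, float]:
    """Dispatch to the theory recorded on the design wave."""
    if wave.theory == "cnoidal":
        return cnoidal_kinematics(wave, depth, z, phase, current)
    return linear_kinematics(wave, depth, z, current, phase)


# ---------------------------------------------------------------------
# forces and stability

def morison_force(
    u: float,
    a: float,
    area: float,
    volume: float,
    rho: float = RHO_SEAWATER,
    cd: float = 1.05,
    cm: float = 2.0,
) -> float:
    """Morison load: drag ``0.5 rho C_D A u|u|`` plus inertia
    ``rho C_M V a`` (N)."""
    if area < 0 or volume < 0:
        raise ValueError("projected area and volume must be >= 0")
    return 0.5 * rho * cd * area * u * abs(u) + rho * cm * volume * a


def _strips(design: ARUnitDesign, coeffs: ForceCoefficients):
    """(z_center above bed, frontal area, displaced volume, moment arm)
    strips of the prism.  Frontal width is the prism width (wave attack on
    a principal face).  The ballast slab contributes weight and raises the
    prism — and with it the force arms — but carries no Morison load of
    its own (a flat flagstone at bed level presents negligible frontal
    exposure compared to the unit)."""
    out = []
    n = max(1, coeffs.strips)
    dz = design.height / n
    for i in range(n):
        zc = design.slab_height + (i + 0.5) * dz
        out.append((zc, design.width * dz, design.bounding_volume / n, zc))
    return out


def submerged_weight(design: ARUnitDesign, coeffs: ForceCoefficients,
                     rho_water: float = RHO_SEAWATER) -> float:
    """Submerged weight (N) of prism + slab.

    Uses the declared mass when given, else bulk density times gross
    volume; buoyancy on the same gross volume (holes are treated as
    water-filled voids that cancel between mass and displacement only
    when mass is derived from gross volume — a declared mass should then
    be paired with a matching bulk density).
    """
    vol = design.bounding_volume
    mass = (
        design.mass_tonnes * 1000.0
        if design.mass_tonnes is not None
        else coeffs.concrete_density * vol
    )
    plan = coeffs.slab_plan_area or design.footprint_area
    slab_vol = plan * design.slab_height
    mass += coeffs.concrete_density * slab_vol
    return (mass - rho_water * (vol + slab_vol)) * G


def stability_check(
    design: ARUnitDesign,
    wave: DesignWave,
    conditions: WaveConditions,
    coeffs: ForceCoefficients = ForceCoefficients(),
    n_phases: int = 181,
) -> StabilityReport:
    """Sliding and overturning safety factors at the governing phase.

    Sliding SF = mu (W' - F_lift) / F_H; overturning SF = restoring
    moment over overturning moment about the downstream bottom edge, both
    evaluated at the phase maximising the total Morison force.
    """
    ensure_valid(design)
    strips = _strips(design, coeffs)
    w_sub = submerged_weight(design, coeffs, conditions.rho)
    plan = coeffs.slab_plan_area or design.footprint_area
    lever = design.length / 2.0  # half-extent in the wave direction

    phases = np.linspace(0.0, 2.0 * math.pi, n_phases, endpoint=False)
    best = None
    drag_max = inertia_max = 0.0
    for p in phases:
        f_tot = m_tot = drag_tot = inertia_tot = 0.0
        u_ref = 0.0
        for zc, area, vol, arm in strips:
            z = min(zc, conditions.depth)
            u, a = kinematics(wave, conditions.depth, z, p, conditions.current)
            drag = 0.5 * conditions.rho * coeffs.cd * area * u * abs(u)
            inertia = conditions.rho * coeffs.cm * vol * a
            f = drag + inertia
            f_tot += f
            m_tot += f * arm
            drag_tot += drag
            inertia_tot += inertia
            u_ref = u  # top strip velocity drives lift
        lift = 0.5 * conditions.rho * coeffs.cl * plan * u_ref**2
        drag_max = max(drag_max, abs(drag_tot))
        inertia_max = max(inertia_max, abs(inertia_tot))
        if best is None or abs(f_tot) > abs(best[1]):
            best = (p, f_tot, m_tot, lift)

    phase_star, f_h, m_over, lift = best
    f_h, m_over = abs(f_h), abs(m_over)
    no_load = f_h < 1e-12 and lift < 1e-12
    if no_load:
        sliding = math.inf
        overturning = math.inf
    else:
        sliding = coeffs.friction * (w_sub - lift) / f_h if f_h > 0 else math.inf
        m_restore = w_sub * lever
        m_total_over = m_over + lift * lever
        overturning = (
            m_restore / m_total_over if m_total_over > 0 else math.inf
        )
    return StabilityReport(
        design=design.name,
        wave=wave,
        drag_max=float(drag_max),
        inertia_max=float(inertia_max),
        horizontal_force=float(f_h),
        lift_force=float(lift),
        submerged_weight=float(w_sub),
        sliding_sf=float(sliding),
        overturning_sf=float(overturning),
        governing_phase=float(phase_star),
        slab_height=design.slab_height,
        no_load_case=bool(no_load),
    )


def size_slab(
    design: ARUnitDesign,
    wave: DesignWave,
    conditions: WaveConditions,
    coeffs: ForceCoefficients = ForceCoefficients(),
    target_sliding: float = 1.2,
    target_overturning: float = 1.2,
    resolution: float = 0.01,
    max_height: float = 3.0,
) -> float:
    """Smallest slab height (m, on the ``resolution`` grid) meeting both
    safety-factor targets; 0 when the bare unit already passes.

    Raises :class:`SlabInfeasibleError` naming the limiting failure mode
    when no height up to ``max_height`` suffices.
    """
    if target_sliding <= 0 or target_overturning <= 0:
        raise ValueError("target safety factors must be > 0")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    h = 0.0
    last = None
    while h <= max_height + 1e-12:
        trial = design.model_copy(update={"slab_height": h})
        last = stability_check(trial, wave, conditions, coeffs)
        if (
            last.sliding_sf >= target_sliding
            and last.overturning_sf >= target_overturning
        ):
            return h
        h += resolution
    limiting = (
        "sliding" if last.sliding_sf < target_sliding else "overturning"
    )
    raise SlabInfeasibleError(limiting, max_height)
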