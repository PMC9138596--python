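# Methods

`reefscore` implements a three-stage procedure for designing modular
artificial-reef (AR) units — holed concrete blocks deployed to enhance
net primary production (NPP) and shelter in coastal ecosystems such as
estuaries.  The stages are (1) a qualitative ecological checklist that
guides which geometric features to add to a starting block, (2) a
quantitative comparative index that ranks candidate designs against a
reference design of the same bounding volume, and (3) a simplified
hydrodynamic check that the selected unit neither slides nor overturns
under an extreme design wave, sizing a ballast slab when needed.

## 1. Geometry model and surface inventory

A unit is a rectangular prism (`length x width x height`, typically a
1.5 m cube) carrying three feature types: a top central through hole
opening into an interior cavity (light admission, nutrient exchange),
lateral through holes piercing vertical walls (interior circulation),
and blind cylindrical nest cavities on the faces (shelter and spawning
substrate).  Validation enforces positive dimensions, openings fully
inside their host faces, non-overlapping openings per face, and the
blindness of nest cavities.

The ecological index consumes a *surface inventory* in cm²:

- `S_v` — external vertical wall area, **minus** through-hole openings
  (they remove attachment substrate), **plus** the cylindrical wall of
  the central cavity (an internal vertical surface reached by sunlight
  through the top opening);
- `S_h` — top-face area minus the central opening plus the cavity floor
  disc.  The seabed-contact bottom face and the ballast slab serve no
  biological purpose and are excluded;
- per-wall lateral-hole opening areas with their roughness factors;
- per-cavity opening-disc areas (`pi d²/4`).

Two conventions deserve emphasis because alternative accountings are
plausible:

- **Nest cavities are counted by opening disc, not interior wall, and
  their openings are not subtracted from host faces.**  This is the only
  accounting that reproduces the reference unit's published budget
  (8 × pi × 15² = 5 654.9 ≈ 5 655 cm²; vertical area exactly
  90 000 cm²), and it reads the habitat budget as "sheltered aperture
  area", which is the quantity cavity-dwelling species respond to.
- **A lateral hole books one opening entry per wall it breaches** (the
  exterior wall plus the interior-cavity wall, or two exterior walls for
  a straight-through bore).  Both this and the hole-subtraction /
  cavity-interior conventions are flag-configurable
  (`InventoryOptions`), since published surface take-offs do not always
  state which was used.

The final worked-example design ships with *surface overrides* — the
published take-off totals (68 835 / 107 750 / 9 423 cm²) — because its
drawing-level hole layout per face is not fully recoverable from the
prose description; the geometry-derived totals are computed and reported
alongside whenever the overrides are disabled.

## 2. The comparative index

Against a reference design of equal bounding volume, three dimensionless
partials are formed:

- **EM** (energy): ratio of sunlight-weighted exposed areas
  `(S_v f_ev + S_h f_eh) / (S_vr f_ev + S_hr f_eh)` with exposure
  factors `f_ev = 0.5`, `f_eh = 1`.  Sloped panels enter with an
  interpolated factor `f_e(theta)` running from `f_eh` at horizontal to
  `f_ev` at vertical.
- **NM** (nutrients): ratio of upwelling-effective surfaces
  `S_upwelling = S_v f_rv − Σ S_lh,i f_r,i` — vertical walls weighted by
  a roughness factor, minus lateral-hole openings, whose permeability
  weakens the upwelling/back-eddy circulation that redistributes
  nutrients around a bluff body.  Sloped panels enter with a verticality
  factor `f_u(theta)` from 0 (horizontal) to 1 (vertical).
- **HM** (habitat): ratio of summed nest-cavity opening areas.

The overall score is the weighted sum (unit weights by default); each
partial is 1 and the total is 3 for the reference against itself, so
scores above 3 flag a net improvement.  Design choices:

- **Inclined factors default to linear interpolation in angle**, with a
  sinusoidal option; only the endpoints and monotonicity are physically
  constrained, and linearity is the minimal assumption.
- **Roughness factors default to 1** (smooth formed concrete); they are
  user-supplied per material/finish, as no universal scale exists.
- **Rounding**: `"paper"` mode rounds each partial half-up to two
  decimals before summing — the reporting convention, under which the
  worked example gives 1.02 + 1.20 + 1.67 = 3.89 — while `"full"` mode
  keeps full precision (3.883…) and is used for programmatic ranking.
- **Undefined partials raise** (rather than returning 0 or infinity):
  the index is only meaningful against a reference that itself
  contributes to every compared dimension.  A zero weight drops a
  dimension and its precondition, supporting one- and two-dimensional
  comparisons.
- **Equal-volume guard**: comparing designs whose bounding volumes
  differ by more than 5% emits a warning; the index measures impact per
  occupied volume and is not meaningful across sizes.
- When a through hole pierces an *inclined* plane, the plane's
  contribution is multiplied by `f_u` of its angle and hole openings are
  subtracted with that same factor; the two extensions are never
  combined in the source formulation, so this composition is a
  documented package choice.

## 3. Stability procedure

The desk-level procedure (no CFD, no spectral propagation):

1. **Design wave**: `H_max = H_s sqrt(ln N / 2)` — the mode of the
   Rayleigh-distributed maximum of `N` waves (default `N = 1000`, about
   a three-hour storm; 5.5 m significant height maps to 10.2 m) — capped
   by the depth-limited breaker height `gamma h` with `gamma = 0.78`.
2. **Theory selection** by Ursell number `Ur = H L² / h³` (wavelength
   from the linear dispersion relation, solved by Newton iteration to
   relative residual < 1e-10): first-order cnoidal above `Ur = 26`,
   Airy otherwise.
3. **Kinematics.**  Airy theory gives the standard
   `u = (H/2) ω cosh(kz)/sinh(kh) cos φ` profile.  The cnoidal branch
   solves the elliptic parameter `m` by fixed-point iteration on
   `L = cT`, inverting `Ur = (16/3) m K(m)²` at each step, with the
   first-order celerity
   `c = sqrt(gh) [1 + (H/mh)(1 − m/2 − 3E/2K)]` and the depth-uniform
   shallow-water velocity `u = c η / h` over the cn² surface profile.
   In the small-`m` limit this reproduces the depth-*averaged* Airy
   velocity (the depth-uniform profile corresponds to the vertical
   mean); in the `m → 1` limit the crest-referenced profile approaches
   the solitary-wave `sech²` form.  A steady current is superposed on
   the orbital velocity (simple superposition in the drag term; full
   wave–current interaction modelling is out of scope).
4. **Forces**: Morison formulation
   `F = ½ ρ C_D A u|u| + ρ C_M V a` with defaults `C_D = 1.05`,
   `C_M = 2.0` for a bluff cubic block, evaluated at unit mid-height by
   default (a strip-integration option with ≥ 2 strips serves tall
   configurations), swept over wave phase to find the governing load.
   Lift defaults to zero with a user-settable coefficient hook.
5. **Stability**: sliding SF = `μ (W' − F_L) / F_H` with concrete-on-sand
   friction `μ = 0.6`; overturning SF = restoring / overturning moment
   about the downstream bottom edge, at the phase maximising the total
   force.  The ballast slab (plan area defaulting to the unit footprint,
   configurable) contributes submerged weight and raises the prism — and
   with it the force arms — but carries no Morison load of its own: a
   flat flagstone at bed level presents negligible frontal exposure
   compared with the unit.  A consequence worth knowing: a
   same-footprint slab improves sliding but *reduces* the overturning
   margin (the force arm grows faster than the restoring weight), so
   overturning-critical units need a wider slab (set
   `slab_plan_area`), not a taller one.  `size_slab` scans heights on a
   configurable grid (default 1 cm) and names the limiting failure mode
   when no height up to the configured maximum suffices.

Mass defaults to bulk density (2 400 kg/m³) times gross prism volume
when not declared; buoyancy uses the same gross volume, so holes cancel
consistently.  A declared mass should be paired with a matching density.

## 4. Synthetic designs

`random_design(GeneratorSpec(seed))` draws prism edges from 1–2 m (the
logistic envelope for estuary units), lateral holes of 20–60 cm, nest
cavities of 15–35 cm with up to eight per unit, and places all openings
by rejection sampling until non-overlapping, so every generated design
validates by construction.  Generated designs emulate the *geometric*
variability of real unit catalogues; they do not emulate material
variety, biofouling-dependent roughness, or non-prismatic base solids,
so green property suites demonstrate correctness of the accounting and
the index algebra, not ecological validity of any particular score.

## 5. Numerical choices and problem sizes

- Dispersion: Newton iteration from an Eckart-type seed; residual
  tolerance 1e-15 per step, verified < 1e-10 relative over
  T ∈ [2, 25] s, h ∈ [1, 200] m.
- Cnoidal parameter solve: damped fixed point with Brent inversion of
  the Ursell relation, `m` bracketed in (1e-14, 1 − 1e-15); results are
  cached per (H, T, h).  Waves demanding `K(m)` beyond that bracket
  (extremely long solitary-like waves) raise a wave-theory error
  reporting the Ursell number.
- Phase sweeps use 181 equally spaced phases per cycle; slab sizing uses
  a 1 cm grid by default (2 cm in the test suite).
- Property suites run on 1 000 generated designs for validity, and on
  polygon-approximation oracles (512-segment circles) for area
  agreement within 0.5%.
- Ties in design ranking break lexicographically by name; machine-
  readable outputs are written with sorted keys and no timestamps so
  repeated runs are byte-identical.

## 6. Known limitations

- The index is comparative only; it predicts no absolute ecological
  outcome, and field validation remains necessary.
- The final worked-example design's geometry-derived energy and
  nutrient surfaces do not match the published take-off totals (the
  per-face hole layout behind those totals is under-specified); the
  shipped fixture therefore defaults to the published overrides.
- First-order cnoidal kinematics are depth-uniform; strongly sheared
  columns (large kh) fall back to Airy theory by the Ursell criterion.
- No spectral wave propagation, CFD wave–structure interaction, scour,
  geotechnics, or structural stress analysis; multi-objective
  optimisation over the design space is likewise out of scope.
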