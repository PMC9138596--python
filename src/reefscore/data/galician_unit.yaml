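# Final reef-unit design for Galician estuaries: 1.5 m cube with a 600 mm
# top central hole opening into an interior cavity, 250 mm and 450 mm
# lateral holes, and twenty nest cavities (12 x 20 cm + 8 x 30 cm).
#
# surface_overrides carries the published surface take-off totals; the
# drawing-level hole layout behind them is not fully recoverable from the
# parametric description, so the geometry-derived totals differ (both are
# reported by the tooling).  Cavity centers follow a documented symmetric
# layout; they affect validation only, never an index value.
name: galician-final
length: 1.5
width: 1.5
height: 1.5
material: concrete
material_ph: 7.5
roughness_factor_vertical: 1.0
slab_height: 0.0
mass_tonnes: 5.0
bulk_density: 2400.0
through_holes:
- {diameter: 0.60, orientation: vertical_top, host_face: top,
   connects_to: interior_cavity, depth: 1.0, center: [0.0, 0.0]}
- {diameter: 0.45, orientation: horizontal_lateral, host_face: north,
   connects_to: interior_cavity, center: [0.0, 0.0]}
- {diameter: 0.25, orientation: horizontal_lateral, host_face: east,
   connects_to: interior_cavity, center: [0.0, 0.0]}
nest_cavities:
- {diameter: 0.30, depth: 0.30, host_face: north, center: [-0.45, -0.40]}
- {diameter: 0.30, depth: 0.30, host_face: north, center: [0.45, -0.40]}
- {diameter: 0.30, depth: 0.30, host_face: south, center: [-0.45, -0.40]}
- {diameter: 0.30, depth: 0.30, host_face: south, center: [0.45, -0.40]}
- {diameter: 0.30, depth: 0.30, host_face: east, center: [-0.45, -0.40]}
- {diameter: 0.30, depth: 0.30, host_face: east, center: [0.45, -0.40]}
- {diameter: 0.30, depth: 0.30, host_face: west, center: [-0.45, -0.40]}
- {diameter: 0.30, depth: 0.30, host_face: west, center: [0.45, -0.40]}
- {diameter: 0.20, depth: 0.20, host_face: north, center: [-0.45, 0.40]}
- {diameter: 0.20, depth: 0.20, host_face: north, center: [0.0, 0.45]}
- {diameter: 0.20, depth: 0.20, host_face: north, center: [0.45, 0.40]}
- {diameter: 0.20, depth: 0.20, host_face: south, center: [-0.45, 0.40]}
- {diameter: 0.20, depth: 0.20, host_face: south, center: [0.0, 0.45]}
- {diameter: 0.20, depth: 0.20, host_face: south, center: [0.45, 0.40]}
- {diameter: 0.20, depth: 0.20, host_face: east, center: [-0.45, 0.40]}
- {diameter: 0.20, depth: 0.20, host_face: east, center: [0.0, 0.45]}
- {diameter: 0.20, depth: 0.20, host_face: east, center: [0.45, 0.40]}
- {diameter: 0.20, depth: 0.20, host_face: west, center: [-0.45, 0.40]}
- {diameter: 0.20, depth: 0.20, host_face: west, center: [0.0, 0.45]}
- {diameter: 0.20, depth: 0.20, host_face: west, center: [0.45, 0.40]}
surface_overrides:
  weighted_exposed_cm2: 68835.0
  upwelling_cm2: 107750.0
  nest_cavities_cm2: 9423.0
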