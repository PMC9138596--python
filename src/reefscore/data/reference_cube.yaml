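# Basic (reference) reef-unit design: 1.5 m concrete cube with eight
# 30 cm nest cavities spread over the four vertical faces.
name: reference-cube
length: 1.5
width: 1.5
height: 1.5
material: concrete
material_ph: 7.5
roughness_factor_vertical: 1.0
slab_height: 0.0
bulk_density: 2400.0
through_holes: []
nest_cavities:
- {diameter: 0.30, depth: 0.30, host_face: north, center: [-0.45, 0.0]}
- {diameter: 0.30, depth: 0.30, host_face: north, center: [0.45, 0.0]}
- {diameter: 0.30, depth: 0.30, host_face: south, center: [-0.45, 0.0]}
- {diameter: 0.30, depth: 0.30, host_face: south, center: [0.45, 0.0]}
- {diameter: 0.30, depth: 0.30, host_face: east, center: [-0.45, 0.0]}
- {diameter: 0.30, depth: 0.30, host_face: east, center: [0.45, 0.0]}
- {diameter: 0.30, depth: 0.30, host_face: west, center: [-0.45, 0.0]}
- {diameter: 0.30, depth: 0.30, host_face: west, center: [0.45, 0.0]}
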