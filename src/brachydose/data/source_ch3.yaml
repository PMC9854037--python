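channel_id: '3'
core_radius: 0.05
core_length: 0.2
capsule_outer_diameter: 0.21
capsule_length: 0.58
core_axial_offset: 0.0
cable_length: 2.0
core_material:
  name: cobalt
  density: 8.85
  composition:
    Co: 1.0
capsule_material:
  name: steel1
  density: 7.98
  composition:
    C: 0.001
    Si: 0.007
    Mn: 0.01
    Cr: 0.18
    Ni: 0.1
    Ti: 0.004
    Fe: 0.698
cable_material:
  name: steel2
  density: 7.93
  composition:
    C: 0.001
    Si: 0.007
    Mn: 0.01
    Cr: 0.18
    Ni: 0.09
    Fe: 0.712
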