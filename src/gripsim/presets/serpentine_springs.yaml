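# Scenario deriving the suspension stiffness from serpentine beam geometry
# by the energy method instead of taking the published stiffness set.
# The beam width was calibrated once so that the assembly k_tz reproduces
# 49,557 uN um/rad; see docs/methods.md.
extends: paper_default

suspension:
  mode: castigliano
  E: 160 GPa
  nu_poly: 0.23
  rho: 2330 kg/m^3
  n_springs: 2
  beams:
    - {L: 100 um, b: 8.043248 um, h: 2.5 um, axis: [1, 0, 0]}
    - {L: 20 um,  b: 8.043248 um, h: 2.5 um, axis: [0, 1, 0]}
    - {L: 100 um, b: 8.043248 um, h: 2.5 um, axis: [-1, 0, 0]}
    - {L: 20 um,  b: 8.043248 um, h: 2.5 um, axis: [0, 1, 0]}
    - {L: 100 um, b: 8.043248 um, h: 2.5 um, axis: [1, 0, 0]}
    - {L: 20 um,  b: 8.043248 um, h: 2.5 um, axis: [0, 1, 0]}
    - {L: 100 um, b: 8.043248 um, h: 2.5 um, axis: [-1, 0, 0]}
    - {L: 20 um,  b: 8.043248 um, h: 2.5 um, axis: [0, 1, 0]}
    - {L: 100 um, b: 8.043248 um, h: 2.5 um, axis: [1, 0, 0]}
    - {L: 20 um,  b: 8.043248 um, h: 2.5 um, axis: [0, 1, 0]}
    - {L: 100 um, b: 8.043248 um, h: 2.5 um, axis: [-1, 0, 0]}
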