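# Default microgripper scenario.
#
# Comb-electrode artwork follows the published electrodynamic-bank values
# (R0 = 400 um, theta0 = 6 deg, g = 2 um, h = 7 um, Wf = 2 um); the dc
# electrostatic bank shares the per-layer finger geometry with 120 pairs per
# layer vs 20, both on 3 mobile structural layers.  Suspension stiffness is
# the published analytical set.  Damping-body areas/levers and the contact
# lever r_c are design-plausible defaults documented in docs/methods.md.

comb_electrostatic:
  R0: 400 um
  Wf: 2 um
  g: 2 um
  h: 7 um
  n: 120
  layers: 3
  theta0: 6 deg

comb_electrodynamic:
  R0: 400 um
  Wf: 2 um
  g: 2 um
  h: 7 um
  n: 20
  layers: 3
  theta0: 6 deg

suspension:
  mode: direct
  E: 160 GPa
  nu_poly: 0.23
  rho: 2330 kg/m^3
  n_springs: 2
  stiffness:
    k_tz: 49557 uN*um/rad
    k_tx: 11982 uN*um/rad
    k_Fx: 25.74 uN/um
    k_Fy: 90.76 uN/um
    k_Fz: 10.14 uN/um

inertia:
  J_b: 5.86e-3 kg*um^2

damping:
  mu: 1.81e-5 Pa*s
  d_p: 2 um
  g: 2 um
  bodies:
    - {A_p: 0 um^2, r_am: 150 um, l_am: 150 um}      # body 1: over the etched pit
    - {A_p: 16000 um^2, r_am: 700 um, l_am: 200 um}  # body 2: above substrate
    - {A_p: 15000 um^2, r_am: 1200 um, l_am: 150 um} # body 3: above substrate
  sidewalls:
    - {A_sn: 700 um^2, r_am4: 900 um, count: 60}     # mobile fingers, 3 layers

kinematics:
  r_tip: 250 um
  gap0: 40 um
  r_c: 2500 um

drive:
  V0: 0.25 V
  V1: 0.25 V
  f_hz: 463 Hz
  Vdc: 10 V

solver:
  freq_min: 350 Hz
  freq_max: 900 Hz
  points: 1201
  branch_policy: stable
  ode_rtol: 1.0e-9
  ode_atol: 1.0e-12
  seed: 0
  series_terms: 12
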