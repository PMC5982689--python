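# Methods

This note records the modelling assumptions behind `gripsim`, the defaults
that matter, the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Scope and model structure

The device is reduced to a single rotational degree of freedom: the mobile
arm's angle θ_z about the serpentine-spring pivot.  Only the rotational-z
mode is modelled; out-of-plane and higher modes, stress recovery, fabrication
detail and liquid-environment damping are out of scope.  The arm is
characterised by a polar inertia J_b, a rotational suspension stiffness k_tz,
a lumped rotational damping coefficient c_amT, an electrostatic drive torque,
and — when a cell is gripped — a nonlinear contact torque.

## Electrostatics

The rotary comb capacitance is linear in the overlap angle, so the drive
torque τ₀V² is angle-independent within the overlap range.  The two gap sums
run over finger pairs i = 1 … n−1, exactly as in the source model (whether
they should run to n is unresolved; for n = 20–120 the difference is < 1%).
Fringing fields and vertical (levitation) forces are neglected.  The
side-instability limit is implemented as V_c = g√(k/2C) — the dimensionally
consistent reading — with the lateral stiffness k defaulting to the
suspension's k_Fy (in-plane direction normal to the finger sidewalls).  A
two-plate energy-balance oracle in the tests confirms this bound is the
conservative √2-fold reduction of the toy instability voltage.

Both actuator banks default to the published per-layer artwork (R₀ = 400 µm,
W_f = 2 µm, g = 2 µm, h = 7 µm, θ₀ = 6°) on 3 mobile layers, with 120
pairs/layer for the dc bank and 20 pairs/layer for the ac bank.  The dc
bank's true radial artwork is not published, so dc-voltage headline numbers
(e.g. a 23.4 V limit) are not reproducible from first principles and are not
asserted anywhere; the 129.2 V ac peak cap is treated as a given input when
optimising the push-pull split.

## Suspension

Stiffness is available two ways, selected by `suspension.mode`:

- `direct` — the published five-entry stiffness set (the authoritative
  default used by the dynamics).
- `castigliano` — closed-form energy method on a chain of straight beams:
  internal loads by rigid statics (the chain is statically determinate),
  energy from tension, Saint-Venant torsion and Euler–Bernoulli bending in
  both planes (shear deformation neglected), compliance assembled exactly
  from the quadratic form.  Each stiffness is defined as 1/C_qq per spring
  (single-load Castigliano deflection) and the two springs add in parallel.

Because the actual serpentine artwork is not published, the packaged
`serpentine_springs` preset ships a plausible 6-beam meander (100 µm beams,
20 µm links, 2.5 µm structural thickness) whose width (8.043 µm) was
calibrated once, analytically, so the assembly k_tz reproduces
49,557 µN µm rad⁻¹; the other four stiffnesses then fall where the geometry
puts them (k_tx ≈ 6.0 × 10³ µN µm rad⁻¹, k_Fx ≈ 13.7, k_Fy ≈ 13.3,
k_Fz ≈ 0.75 µN µm⁻¹) and are *not* claimed to match the published set — a
single simple meander cannot satisfy all five simultaneously.  Downstream
physics uses `direct` mode.

The space-frame finite-element oracle (12-dof Euler–Bernoulli elements,
clamped anchor) is an independent route to the same compliances; for point
loads on a determinate chain both routes are exact, so the 2% test tolerance
is generous by construction.  Torsion constants use the exact tanh series
(12 terms by default; the square-section value 0.1406 h⁴ is reproduced to
4 digits).

## Damping

Slide-film (Couette) drag: every moving surface at gap d contributes local
shear µv/d with v = rθ̇, giving rotational coefficients
µA_p r²/d_p (lowest layer over the substrate), (32/3)µ l r² (inter-layer
drag per body, counted twice for the two upper layers) and µA_s r²/g per
comb-finger sidewall.  These printed forms are dimensionally consistent as
torque per unit angular velocity and are implemented as such.  Squeeze-film
effects, rarefaction corrections and liquid damping are excluded.

The arm's body partition is not published.  The default (three bodies with
areas 0 / 16,000 / 15,000 µm², levers 150 / 700 / 1200 µm, half-lengths
150 / 200 / 150 µm, 60 mobile fingers at 900 µm, d_p = g = 2 µm,
µ = 1.81 × 10⁻⁵ Pa s at 20 °C) was chosen once as a design-plausible
millimetre-scale arm; it yields c_amT ≈ 7.0 × 10⁻¹³ N m s rad⁻¹ and a free
quality factor ≈ 24 — a sharp, clearly resolvable resonance typical of such
resonators in air.  All of it is configuration data.

## Cell contact

The gripped cell (radius R, modulus E_c, Poisson ratio v) resists with

    F_xc(δ_r) = [δ_r E_c / 3(1−v²)] · [4a − f(a) a²/π],

where f(a) is the lateral-extension kernel coupling the two contact patches.
As published, the bracket subtracts an inverse length from a length; the
package normalises the kernel term by a² (the minimal commensurate choice)
and exposes the contact radius `law` as a plug-in:

- `geometric` (default): a = √(2Rδ_r − δ_r²), the truncation radius of the
  flattened cap.  This reproduces the published cubic-fit coefficients — with
  r_c = 2500 µm the linear coefficients come out 5.57 × 10⁻⁸ / 2.79 × 10⁻⁸ /
  5.72 × 10⁻⁹ N m rad⁻¹ for BHP / PC-3 / LNCaP, within 2% of the published
  5.69 × 10⁻⁸ / 2.85 × 10⁻⁸ / 5.83 × 10⁻⁹ — but its small-compression limit
  exceeds the classical Hertz sphere–plate force by √2 (frozen in a
  regression test).
- `hertz`: a = √(Rδ_r), whose small-compression limit is exactly
  F = (4/3)E√R δ^{3/2}/(1−v²).

The published cubic coefficients themselves are reported for comparison
only, never asserted: their α_b values sit ~20% above anything this family
of laws produces (plausibly a different fit range), and their printed units
are unrecoverable.

Compression splits equally between the tips, δ_r = r_c θ_z/2, inverting the
published lever relation r_c = 2δ_r/θ_z.  The validity cap is δ_r ≤ 0.6R.
The Poisson ratio defaults to 0.5 (incompressible), the standard assumption
for cells.  The torque is fitted to α_a θ + α_b θ³ through the origin (a
constant offset would violate T_c(0) = 0) on [0, θ_max] with θ_max at 20%
radial compression — for R = 10 µm and r_c = 2500 µm that is 0.0016 rad.
Both coefficients are exactly linear in E_c, which is what makes modulus
inference a one-parameter inversion.

### Lever arms

Neither tip lever is published.  r_tip = 250 µm is back-derived from the
pair (0.382 rad, 95.5 µm tip travel); r_c = 2500 µm from the lever relation
at the squeeze point (δ_r = 2 µm at θ_z = 0.0016 rad).  The two are mutually
inconsistent as a single arm dimension and are deliberately kept as
independent knobs; the Table-5-level agreement above supports the r_c value.

## Dynamics

Ritz averaging with the single-harmonic ansatz θ = c₁cos(ωt−Ψ) balances the
fundamental harmonic of the cubic term ((3/4)α_b c₁³), giving a cubic in c₁²
solved exactly (`numpy.roots`) at every grid frequency; the phase follows
from Ψ = atan2(c_amT ω, k + ¾α_b c₁² − Jω²).  Where three branches coexist,
the intermediate amplitude is flagged unstable (standard fold topology).
Sweeps run low→high by default, staying on the continuous branch and
jumping at the fold; a high→low sweep exposes the hysteresis.

The quality factor is the half-power bandwidth of the swept amplitude curve,
with the peak located by quadratic interpolation around the grid maximum.
For bent (hardening) peaks the upper half-power crossing is taken on the
swept curve, i.e. the fold bounds the bandwidth — an operational choice
frozen in a regression test.  In the linear limit Q matches √(Jk)/c to 1% on
a 2001-point grid.

The time-domain oracle integrates the same ODE (DOP853, rtol 10⁻⁹,
atol 10⁻¹²) from rest over ≥ 50 forcing periods and reads the amplitude off
the last 10 periods; it agrees with the stable Ritz branch within 2% at the
device's weakly nonlinear operating point, conserves energy to integrator
tolerance when undriven/undamped, and reproduces the linear ringdown
decrement c/(2J) to 1%.

### Drive levels

The default squeeze drive V₀ = V₁ = 0.25 V gives B ≈ 2.1 × 10⁻¹³ N m and a
resonance amplitude ≈ 10⁻⁴ rad — a ~0.14 µm cell compression modulation,
small enough that the Duffing hardening shifts the peak by well under 1%,
which keeps the backbone inversion nearly bias-free.  Larger drives bend the
peak visibly (tested up to 30×, where the 1→3→1 branch fold appears).

## Inference

Knowns: J_b, c_amT, k_tz, B, tip kinematics and the cell's geometry (R, v);
unknown: E_c.  Two estimators:

- **frequency_shift** — peak location by quadratic interpolation (the single
  frozen peak-extraction rule), then the backbone relation
  J ω_p² = k_tz + A₁E + ¾A₃E c_p² solved for E, where (A₁, A₃) are the
  cubic-fit coefficients per unit modulus.
- **torque_balance** — at each grid point with amplitude ≥ 0.2 c_p, the
  amplitude equation is solved for the cell's effective stiffness
  k_eff = Jω² − k_tz ± √(B²/c₁² − (c_amT ω)²) (sign by side of the peak),
  converted pointwise to a modulus and reduced by the median.

Noiseless round trips recover E_c to well under 1% across 100 Pa – 10 kPa;
the 5% test tolerance absorbs grid effects at the range edges.  Uncertainty
comes from a multiplicative residual bootstrap (50 draws by default):
residual ratios about the refitted model curve are resampled with
replacement and the estimator re-run; the 95% percentile interval covers the
truth in ≥ 90% of trials at 1% amplitude noise.  Estimates outside
(1, 10⁵) Pa are flagged, not raised.  Classification is nearest |z| against
the reference lines, ties broken toward the stiffer class with a warning.

## Synthetic data

`make_cell_population` draws moduli from a normal distribution with the
reference mean ± sd per cell line (BHP 2797 ± 491, PC-3 1401 ± 162, LNCaP
287 ± 52 Pa; R = 10 µm), truncated at zero by redraw — the simplest
distribution consistent with a mean ± sd summary.  `make_synthetic_measurement`
is the Ritz spectrum with multiplicative Gaussian amplitude noise,
reproducible under a seed.  What this does **not** emulate: capacitive
read-out electronics and their 1/f noise, frequency jitter, adhesion or
viscoelastic cell response, misalignment of the cell between the tips, or
temperature drift.  Passing round-trip tests therefore demonstrates the
self-consistency and conditioning of the inversion, not instrument-level
accuracy on real cells.

## Units

Internal computation is SI throughout; configuration files use the µ-units
natural for MEMS artwork (µm, µN µm rad⁻¹, kg µm²) with per-field unit tags,
converted exactly once at load (and back on save, round-tripping to better
than 12 significant digits).

## Known limitations

- Single-mode model: no coupling to the other four FEM-visible modes.
- The contact law's large-deformation normalisation is a documented choice;
  absolute force accuracy above ~30% compression is untested.
- Damping-body geometry, dc-bank radial artwork and the serpentine artwork
  are design-plausible stand-ins, not published dimensions; quantities that
  depend on them (Q, V_c, dc rotation limits) are self-consistent within the
  model rather than device-verified.
- The bootstrap treats amplitude noise as i.i.d. multiplicative; correlated
  noise would widen true intervals.
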