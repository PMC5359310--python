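# Methods

## Model

### State and structure

The tree is reduced to three state variables: stem radius *r* (m), stem
height *h* (m), and the storage ratio *S* (kg stored carbon per kg
structural carbon, dimensionless). Stem plus crown are treated as a
cylinder whose structural carbon mass is

    Mc = g1 * pi * r^2 * h,

with `g1` an effective carbon density absorbing crown geometry and the
different densities of stem, branches and foliage. Stored carbon above
the critical reserve is carried as

    Sc0 = (S - S1) * g1 * pi * h * r^2 / (1 + S1),

so the audited carbon pool is `Mtot = Mc + Sc0`. `S` is a mass ratio
(stored per structural carbon): this makes the storage respiration term
`C2 * pi * S * h * r^2` dimensionally parallel to maintenance
`C * pi * h * r^2`. Every volumetric coefficient is stored in the
configuration as its value divided by pi (`C_over_pi`, `C2_over_pi`,
`Amax_over_pi`) and multiplied back at load time, so the internal
computation is uniformly in kg, m, y with volume `pi r^2 h`.

### Allometric control

Apical and lateral meristem activities are coupled through a single
control ratio alpha2: differentially `dh/h = 2*alpha2*dr/r`, whose
integral is the power law `h = gamma * r^(2*alpha2)`. When a
red:far-red forcing series is supplied, alpha2 responds to shading as
`alpha2 = alpha0 * exp(-alpha3 * Ra)` and the differential form is used
per step; otherwise alpha2 is constant per stand. Height is nevertheless
integrated as an independent state — this keeps the time-varying-alpha2
case well-posed — and with constant alpha2 the power law re-emerges from
the integration to better than 1e-5 relative, which the test suite
checks as an invariant rather than imposing it.

### Carbon supply

Whole-tree assimilation is a separable product:

    A = Amax * fCO2(Cg) * fPAR(Q1) * fT(T) * fH(h) * r^2 * h

with saturating responses `1 - exp(-Cg/Cr)` and `1 - exp(-Q1/Qr)`, an
asymmetric temperature parabola `1 - ((T - Topt)/Ti)^2` (`Ti` = 21 °C
above the optimum, 25 °C below), and a hydraulic decline
`(h1 - beta*h)/h1` expressing the fall of leaf water potential with
height (beta = 3/4 reflects crown depth). The parabola, the hydraulic
factor, and the sink height factor below are clamped at zero outside
their intended ranges: photosynthesis and growth cease rather than
reverse. Net supply is `A - C*pi*h*r^2 - C2*pi*S*h*r^2`.

### Sink limit and regimes

Meristem-sustained growth is proportional to meristem volume
`Vme/t2 = pi*r^2/t_ratio + 2*pi*r*h` (apical disc plus cambial sheath)
and declines with height as `(h2 - h)/h2`; the cap is

    cap = g1 * k_lat * max(0, (h2 - h)/h2) * Vme/t2.

The thicknesses and the reference rate are not separately identifiable,
so the model is parameterized by the composites `k_lat = t2*Rmax0/g1`
(0.0201 m/y at reference) and `t_ratio = t2/t1` (1 at reference).

Regimes: if net supply exceeds the cap, or `S > S1` (tested with a 1e-9
tolerance), growth is **sink-limited** at `cap / (1 + (S-S1)/(1+S1))` —
the meristem output discounted because new tissue carries storage at the
current density — and the surplus (possibly negative) changes `Sc0`.
Otherwise growth is **source-limited** at the net supply with `dS/dt = 0`.
The divisor reading of the storage discount is the default because it
reproduces the tabulated note that `k_lat = 0.0201` m/y corresponds to a
maximal radial increment of 1.5 cm/y together with alpha2 = 0.34
(`0.0201/1.34 = 0.0150`); the multiplier reading is available behind
`storage_discount="multiplier"`. At the regime boundary (net = cap,
S = S1) the two rates coincide, so the right-hand side is continuous
there. Negative source-limited growth (assimilation below maintenance
with reserves at the floor) shrinks r and h and raises a stress warning;
mass loss through falling density is not representable in this geometry.

Structural growth converts to geometry through
`dr/dt = (dMc/dt) / (2*g1*pi*r*h*(1+alpha2))` and
`dh/dt = 2*alpha2*(h/r)*dr/dt`; `dS/dt` follows from differentiating the
`Sc0` definition by the product rule.

## Parameters

Defaults are the reference table for European beech:

| name | default | units | meaning |
|---|---|---|---|
| g1 | 365 | kg m⁻³ | carbon density of the equivalent cylinder |
| C_over_pi | 73 | kg m⁻³ y⁻¹ | respiration + litter coefficient |
| C2_over_pi | 73 | kg m⁻³ y⁻¹ | storage respiration coefficient |
| k_lat | 0.0201 | m y⁻¹ | t2·Rmax0/g1, max lateral meristem growth |
| t_ratio | 1 | – | t2/t1 thickness ratio |
| beta_h1 | 67.5 | m | β·h1 (photosynthesis limit composite) |
| h2 | 47 | m | meristem-growth limit height |
| S1 | 0.2 | – | critical storage ratio |
| Amax_over_pi | 206 | kg m⁻³ y⁻¹ | max volumetric assimilation |
| Qr | 1000 | W m⁻² | PAR saturation constant |
| Cr | 500 | ppm | CO₂ saturation constant |
| beta | 0.75 | – | canopy geometry integrand |
| Topt, Ti_above, Ti_below | 18, 21, 25 | °C | temperature response |
| alpha2 | 0.34 | – | meristem-activity ratio (plausible 0.34–0.43) |

`t_ratio = inf` and `h2 = inf` are accepted and remove the apical term
and the height limit respectively; they exist for the verification
oracles, not for production runs.

### The reference configuration

`synthetic.reference_parameters()` — used as the truth of the synthetic
stands and the default of the experiments — emulates the *partially
fitted* parameter vector rather than the table centres: Amax/π = 247.2
(+20%), C/π = C2/π = 58.4 (−20%), k_lat = 0.0151 (−25%), h2 = 36 m
(−23%), all inside the calibration margins the fitting protocol itself
allows (20%, and 50% for the coarsely estimated k_lat and h2). The move
is forced by an algebraic fact: with the table centres, positive net
supply requires the factor product `fCO2·fPAR·fT·fH` to exceed
`C(1+S1)/Amax = 0.425`, while `fCO2 ≤ 1 - exp(-288/500) = 0.438` at
pre-industrial CO₂ and `fH(15 m) = 0.875`, so a 15 m tree cannot grow at
the centres under any pre-industrial forcing. Under the reference
configuration the emulated stand grows from 15 m at age 48 to ≈ 35 m at
age 188 and switches from source- to sink-limited in mature age, which
is the qualitative structure the calibration and experiment protocols
assume.

## Numerics

- **Integrator.** Adaptive RK45 (`scipy.integrate.solve_ivp`), applied
  year by year because forcing is piecewise-constant per year (annual
  averaging; splines would smear the counterfactual constructions).
  Defaults rtol 1e-8, atol 1e-10, max step 1 y. Calibration runs use
  rtol 1e-6 for speed; both tolerances are exposed.
- **Events.** A terminal event catches the storage ratio falling through
  S1 (sink→source switch); S is then pinned exactly at S1, which keeps
  the source-regime ledger closure exact and prevents overshoot below
  the floor. A second event locates net supply rising through the cap
  while at the floor (source→sink), where the right-hand side is
  continuous, so the event only sharpens regime bookkeeping. An
  iteration guard disables events for a segment if they stop making
  forward progress. A collapse guard halts the run if r falls below
  1e-6 m.
- **Carbon audit.** The net flux is integrated as an extra quadrature
  state inside the solver; `Trajectory.mass_balance_error()` compares it
  with the change of `Mtot` and stays below 1e-7 on the test runs. The
  per-evaluation ledger closes algebraically at machine precision.
- **Cross-checks.** A fixed-step implicit trapezoidal integrator
  (fixed-point resolved, second order, default step 0.1 y, no event
  machinery) and a closed-form solution of the simplified pure-sink
  configuration (`r(t) = r0 + k_lat·t/(1+alpha2)`, valid when
  `t_ratio = h2 = inf` and S = S1). RK45 vs trapezoid agrees to < 1e-4
  relative over 140 y; RK45 vs the closed form to < 1e-6.
- **Optimizer.** `scipy.optimize.least_squares` (trust-region
  reflective) on parameters scaled by their reference values, box bounds
  `1 ± margin`, start at the box centre, relative finite-difference step
  1e-6. Deterministic given the start point. The loss is the height
  misfit at the measurement ages only; a joint height+volume loss exists
  but is off by default (height is the low-error measurement).
- **Regime reporting.** Within-year regime is summarized by time
  majority, matching the annual granularity of the forcing.

## Synthetic data: what it does and does not establish

The generator emulates the *statistical structure* of long-term beech
yield records: surveys from age 48 to 188 at 8 ± 3 y intervals (clipped
at ≥ 2 y), stand-mean heights ~15→35 m, additive Gaussian observation
noise (0.5 m heights, 5 mm radii — the noise model is an invention; no
error model is published), a shared forcing for trios of neighbouring
stands differing in initial size and allometric ratio, and a thinning
history carried as metadata only (stand density does not feed the
dynamics because alpha2 is constant per stand). Forcing is a stationary
growing-season climatology (T ~ N(14, 0.6²) °C, constant PAR at 2500
W m⁻² on the scale set by Qr — i.e. near light saturation, as required
for viability by the published parameter ratios — and a CO₂ ramp
288→390 ppm with accelerating shape). Real records differ in ways the
generator does not attempt: autocorrelated climate, drought years,
thinning shocks, size-dependent mortality in the dominant-tree mean, and
a time-varying red:far-red environment. Passing the round-trip tests
therefore establishes that the estimator recovers parameters *under the
model's own assumptions*, not that the model is correct for any
particular forest; the published goodness-of-fit against the real German
stands is not reproducible here because those series are not
distributed, and no attempt is made to fake them.

Initial storage is S(0) = S1 (critical reserve) unless specified — the
choice is unstated in the source material and configurable.

## Known limitations

- Shrinkage under stress changes r and h rather than density.
- The apical/lateral aggregation ignores branch-level architecture; root
  meristems and non-cylindrical crowns are out of scope.
- k_lat is weakly identified from height series alone (supply dominates
  the trajectory until late life); identifiable calibrations free it
  only with volume/radius information or longer sink-limited records.
- The mortality process and within-stand red:far-red dynamics are out of
  scope by design.
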