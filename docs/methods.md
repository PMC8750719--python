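# Methods

## Model

The simulator treats a single spherical droplet of constant diameter,
mass and density (no evaporation — heat transfer dominates mass transfer
at the micron sizes of interest) with a spatially uniform temperature.
The lumped energy balance in every stage is

    (π d³/6) ρ C dT/dt = π d² h (T_a − T),

with the stage deciding the heat capacity `C`: the liquid value `C_pd`
during pre-cooling, the solid value `C_ps` during tempering, and during
solidification the semisolid value plus the latent contribution,

    C_eff(T) = C_psd(f(T)) + L / (T_f − T_s).

`C_psd` interpolates between liquid and solid heat capacities through
the liquid-core radius ratio `a = (1 − f)^{1/3}`,
`C_psd = (1 − a) C_ps + a C_pd`, reflecting solidification from the
surface inward. Substances of this kind (cocoa butter in particular)
crystallize over a temperature range without supercooling, so the model
has no nucleation, recalescence or polymorph-selection physics; those
are deliberate non-goals, as are internal temperature gradients (the
Biot number is diagnosed, not resolved) and droplet motion.

### Solid-fraction closure

The solidification-stage balance has two unknowns (temperature and
solid volume fraction) and needs a closure for the volumetric
solidification rate `V̇_f`. We take the solid fraction linear in
temperature across the freezing window:

    f(T) = clip((T_f − T) / (T_f − T_s), 0, 1),

so `V̇_f = −V/(T_f − T_s) · dT/dt` and the latent term folds into
`C_eff` above. This choice (i) couples each solid-fraction increment to
exactly the matching latent release, so a fully solid droplet has
released all of `m L` by construction with no temperature-step
approximation anywhere; (ii) reproduces the observed solidification
behaviour of the validation droplet — onset cooling rate ≈ 0.42 K/s
against the reported ≈ 0.5 K/s, and full solidification of the 263 K
run at ≈ 38.6 s against the reported ≈ 38 s. The alternative closure
(liquid-core *radius* linear in temperature) gives onset rates around
0.16 K/s, far from the observed value, and was rejected.

### Convection closure

`h = Nu·k_a/d` with the Ranz–Marshall correlation
`Nu = 2 + 0.6 Pr^{1/3} Re^{1/2}`. Gas transport properties are
evaluated at the film temperature `(T_d + T_a)/2`, refreshed at every
integrator step — standard practice for external convection over a
sphere, and the choice that reproduces the reference averaged
`Nu ≈ 7.85` / `h ≈ 96.9 W/(m² K)` and the ≈ 6.3 K/s initial cooling
rate of the validation scenario (far-field evaluation gives ≈ 6.0 K/s).
The Prandtl number uses the specific heat *of air*: it is a gas-phase
transport group, and air values (~0.71) match the observed Nu
magnitudes. Because the film temperature drifts from 297.5 K at the
start of the baseline run to ≈ 277 K near its end, the instantaneous Nu
sweeps from ≈ 7.5 up to ≈ 7.9; after pre-cooling it stays within
[7.7, 8.0].

### Air properties

The chamber air is dry and at fixed pressure. Density follows the ideal
gas law (`R = 287 J/(kg K)`); viscosity and thermal conductivity follow
Sutherland-form correlations (`μ₀ = 1.716e−5 Pa·s`, `S = 110.4 K`;
`k₀ = 0.0241 W/(m K)`, `S_k = 194 K`, both referenced to 273.15 K);
`c_p = 1006 J/(kg K)` is constant (it varies by under 1% across
220–320 K). These are the standard dry-air closures for this range; the
source study inherited gas properties from its CFD host code without
stating them, so the correlations here are this package's own choice,
validated through the reproduced Nu, h and cooling rates.

### Material constants

The packaged cocoa-butter record is `ρ = 894 kg/m³`,
`C_pd = 2200 J/(kg K)`, `C_ps = 1250 J/(kg K)`, `L = 157 kJ/kg`,
`T_f = 291 K`, `T_s = 273 K`. The thermal conductivity
`k = 0.18 W/(m K)` is **back-derived** from the reported Biot number of
≈ 0.18 for the 2 mm validation droplet (`Bi = h(d/6)/k` with
`h ≈ 96.9`); no tabulated value was available. It feeds only the Biot
diagnostic, never the energy balance.

## Numerics

- Adaptive RK45 (`scipy.integrate.solve_ivp`) with `rtol = 1e−8`,
  `atol = 1e−9`; halving the tolerances moves stage durations by far
  less than 0.1%.
- Stage transitions are terminal events with root-finding on
  `T − T_f` and `T − T_s`, so each stage starts exactly on its
  threshold (no overshoot-and-clip, no threshold smearing).
- Termination: ambient is an asymptote, so runs end when
  `|T − T_a| < ε` with `ε = 0.5 K` by default (configurable
  `epsilon_end`); a hard cap `t_max` (default 600 s) sets a `truncated`
  flag instead of raising. With a 277 K ambient inside the freezing
  window the baseline droplet therefore ends at solid fraction
  f = (291 − 277.5)/18 = 0.75 and never tempers, matching the reference
  observation that no tempering transition appears at that ambient.
- Output sampling every 0.05 s plus the exact stage-boundary times;
  time-averaged Nu and h are trapezoid integrals over those samples.
- Degenerate inputs: `T_init` below ambient raises (cooling model
  only); `T_init` within `ε` of ambient returns a zero-duration
  trajectory; a `t = C exp(k d)` fit needs ≥ 3 distinct diameters.

### Apparent-specific-heat comparator

`simulate_apparent` integrates the single-equation formulation
`m C_p,app(T) dT/dt = A h (T_a − T)` with forward Euler and `C_p,app`
frozen at the step-start temperature. Under the linear closure the two
formulations are algebraically identical, and the staged and apparent
trajectories agree to < 0.05 K for steps of a few milliseconds. The
comparator exists to quantify the known failure mode of the
apparent-heat method: a step that carries the temperature from above
`T_f` to below `T_s` in one go never samples the latent peak, and the
latent heat accounted along the realized path falls short of
`m L f(T_end)`. That shortfall is reported as `latent_deficit`; the
staged model's ledger (`q_latent = m L f`, exact) cannot exhibit it.

### Energy audit

`energy_audit` recomputes the sensible enthalpy change between the run's
endpoint temperatures in closed form along the staged heat capacities
(the in-window integral of `C_psd` has an analytic antiderivative) and
compares `q_rejected` against sensible + latent. Residuals for the
packaged scenarios are at the integrator-tolerance level, orders of
magnitude below the 0.1% acceptance threshold.

## Gas-cell surrogate

`simulate_coupled` co-integrates the droplet with one well-mixed control
volume refreshed by a cold inflow jet (`ṁ = ρ_a v_in π d_hole²/4`,
default hole diameter 3.2 mm). The cell's thermal mass and inflow rate
use the inflow-state air density, held constant — the local gas warms by
at most a few kelvin, and a fixed thermal mass keeps the cell's energy
ledger exactly conservative (storage + outflow = droplet input, checked
to < 0.1%). The surrogate demonstrates the mechanism and its sign —
feedback warms the local gas, reduces the driving temperature difference
and lengthens every stage; with `V_cell → ∞` or `ṁ → ∞` it converges to
the fixed-ambient model. It makes no claim to replicate any particular
3-D chamber: `V_cell` is a free parameter and coupling is off by
default.

## Parametric study and correlation fit

The standard grid is diameters {200, 300, 400, 500} µm × ambient
{220, 270} K × relative speed {20, 100} cm/s, initial temperature 318 K
(the validation value; the study conditions never restate it) at 1 bar,
run uncoupled with fixed ambient. Stage durations are fitted per
(T_a, V_dg) combination to `t = C exp(k d)` by nonlinear least squares
initialized from the log-space linear fit.

On this grid the durations increase with d, decrease with colder
ambient and faster gas, and the ambient temperature dominates the gas
speed for every size (driving force is linear in `T_a − T_d` but enters
h only through `√Re`). Fits achieve r² ≈ 0.987. One reference trend
does **not** emerge in this model: the solidification-stage exponent
exceeding the pre-cooling exponent. Under the linear closure the latent
term is a constant addition to the heat capacity, so both stage
durations share the same diameter shape `∝ d²/Nu(d)` and latent heat
scales only the prefactor (B/A ≈ 4.5–11.6 here); the fitted exponents
are equal to within ~0.2%, with the tiny film-temperature difference
making the stage-2 exponent marginally *smaller*. The published
exponent gap originated in three-dimensional chamber-gas coupling,
which is outside this model (and the 0-D cell surrogate does not
reproduce it either — it warms during both stages alike). The published
prefactors and exponents ship in
`src/dropsolid/data/table4_reference.json` for side-by-side reporting,
not as targets.

## Estimator inversion

`gwie_h` implements the lumped-capacitance inversion of a measured
cooling interval,

    h = C_p ρ d ln((T0 − T_a)/(T_d − T_a)) / (6 t),

i.e. the exact inverse of the frozen-h pre-cooling exponential; applied
to a synthetic frozen-h run it recovers the generating coefficient to
well under 0.5%. Only this dimensionally consistent ratio form is
implemented: the variant sometimes printed with a bare logarithm of a
dimensional temperature difference is not meaningful as written.
`gwie_nu = h d/k_a` converts to a Nusselt number. Estimates of this
kind differ systematically from the simulator's own trajectory-averaged
Nu and h because they compress a whole interval into one constant-h
exponential.

## What the packaged scenarios do and do not show

The validation scenarios exercise a *millimetre* droplet
(Bi ≈ 0.18, above the 0.1 lumped-model limit — a logged warning, not an
error, since the reference study itself ran this case) against
published cooling rates, stage times and averaged transfer quantities.
Passing them shows the staged model, closures and bookkeeping are
implemented consistently with that reference behaviour; it does not
validate internal-gradient effects at millimetre scale, real chamber
aerodynamics, humidity, radiative exchange, temperature-dependent
material properties, or crystallization kinetics (all out of scope).
The micron-scale sweep is squarely inside the lumped regime
(Bi ~ 10⁻²).
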