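# dropsolid

Three-stage solidification simulator for sprayed food droplets —
developed around spray crystallization of cocoa butter (CB) powder, where
liquid droplets are sprayed into cold air and crystallize in flight.

A small droplet with uniform internal temperature `T_d` cools
convectively through three stages:

1. **Pre-cooling** (liquid, `T_d > T_f`):
   `(πd³/6) ρ C_pd dT_d/dt = πd² h (T_a − T_d)`
2. **Solidification** (`T_s ≤ T_d ≤ T_f`): the droplet crystallizes from
   the surface inward. With liquid-core radius ratio `a = (1 − f)^{1/3}`
   (`f` the solid volume fraction) the semisolid heat capacity is
   `C_psd = (1 − a) C_ps + a C_pd`, and latent heat enters as a source:
   `(πd³/6) ρ C_psd dT_d/dt = πd² h (T_a − T_d) + ρ V̇_f L`.
   The volumetric solidification rate is closed by taking `f` linear in
   temperature across the freezing window `[T_s, T_f]`, which turns the
   latent term into an effective capacity `C_psd + L/(T_f − T_s)` and
   ties every increment of solid fraction to the matching latent-heat
   release (`q_latent = m L f`, exactly).
3. **Tempering** (solid): sensible cooling with `C_ps` toward ambient.

The heat-transfer coefficient comes from the Ranz–Marshall correlation
`Nu = h d/k_a = 2 + 0.6 Pr^{1/3} Re^{1/2}` with dry-air properties
(ideal gas + Sutherland correlations) evaluated at the film temperature
`(T_d + T_a)/2`. Stage transitions are located by root-finding inside an
adaptive ODE integrator, so they land exactly on `T_f` and `T_s`. The
Biot number `h(d/6)/k` is diagnosed at every run and a warning is logged
above the usual 0.1 lumped-model limit.

Also included:

- an **apparent-specific-heat comparator** (`simulate_apparent`): the
  same physics folded into a single equation through a `C_p,app(T)` with
  a latent peak over the freezing window, integrated by fixed-step
  explicit Euler. It demonstrates quantitatively how coarse steps can
  jump the peak and under-release latent heat — the error mode the
  decoupled staged formulation avoids;
- a **well-mixed gas-cell surrogate** (`simulate_coupled`) for
  droplet↔gas thermal feedback, off by default;
- a **parametric-study runner** (`sweep`) over droplet size, ambient
  temperature and relative drop-gas speed, with nonlinear least-squares
  fitting of the stage durations to `t = C exp(k d)` (`fit_exponential`),
  and the lumped-capacitance inversion estimators (`gwie_h`, `gwie_nu`)
  used to extract `h` and `Nu` from measured cooling curves;
- an **energy audit** checking `q_rejected = Δ(sensible enthalpy) +
  q_latent` in closed form.

## Worked example

```python
from dropsolid import COCOA_BUTTER, simulate

traj = simulate(d=2e-3, T_init=318.0, mat=COCOA_BUTTER,
                Ta=277.0, Vdg=0.83, p=1e5)
print(f"initial cooling rate  {traj.rate_initial:.2f} K/s")
print(f"pre-cooling duration  {traj.t_precool:.2f} s")
print(f"onset cooling rate    {traj.rate_solid_onset:.2f} K/s")
print(f"mean Nu / h           {traj.Nu_mean:.2f} / {traj.h_mean:.1f} W/m2K")
print(f"final solid fraction  {traj.f_solid_end:.2f}")
```

prints

```
initial cooling rate  6.11 K/s
pre-cooling duration  7.25 s
onset cooling rate    0.42 K/s
mean Nu / h           7.83 / 96.4 W/m2K
final solid fraction  0.75
```

A 2 mm CB droplet starting at 318 K in a 277 K, 1 bar chamber with an
83 cm/s air stream cools at ~6 K/s, reaches the crystallization onset
(291 K) after ~7.2 s, then slows to ~0.4 K/s as latent heat is released.
Because the ambient (277 K) lies inside the freezing window
(273–291 K), solidification never completes: the run ends within 0.5 K
of ambient at a solid fraction of 0.75. Lowering the ambient to 263 K
(`Ta=263.0`) completes solidification at t ≈ 38.6 s, after which the
solid droplet tempers to ambient.

The same scenarios are available from the shell:

```sh
dropsolid validate                       # both scenarios vs reference values
dropsolid simulate --config baseline_277K --out-dir out/
dropsolid sweep --out sweep.csv          # the 4x2x2 parametric grid
dropsolid fit --input sweep.csv          # t = C exp(k d) per (Ta, Vdg)
```

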