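"""Well-mixed local gas cell: a lumped surrogate for droplet-gas coupling.

In a real crystallization chamber the heat the droplet rejects warms the
gas in its immediate neighbourhood, which lowers the driving temperature
difference and feeds back on the convective coefficient. This module
models that feedback with a single well-mixed control volume around the
droplet, refreshed by a cold inflow jet:

    rho_a V_cell cp_a dT_local/dt = mdot cp_a (T_in - T_local) + q_drop

with ``mdot = rho_a v_in (pi/4) d_hole^2``. The droplet then sees
``T_local`` as its ambient. In the limit of an infinite cell (or infinite
inflow) the local temperature never moves and the coupled run reduces to
the fixed-ambient simulation. The surrogate demonstrates the mechanism
and its sign — coupling always slows every stage — not any particular
chamber geometry.

The cell's thermal mass and the inflow mass rate use the inflow-state air
density, held constant (the gas never warms more than a few kelvin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .convection import transfer_state
from .properties import CP_AIR, AirState, MaterialProperties, air_density
from .solidify import (
    SolverOptions,
    Stage,
    Trajectory,
    _h_nu,
    _stage_cp,
    _stage_for_temperature,
    _stage_fraction,
)

__all__ = ["GasCell", "gas_cell_rhs", "simulate_coupled"]


@dataclass(frozen=True)
class GasCell:
    """Well-mixed control volume around the droplet.

    Attributes
    ----------
    V_cell : float
        Control-volume size, m^3.
    T_in : float
        Inflow gas temperature, K.
    v_in : float
        Inflow speed through the supply hole, m/s.
    d_hole : float
        Supply-hole diameter, m (default 3.2 mm).
    T_local : float or None
        Initial local gas temperature, K; defaults to ``T_in``.
    """

    V_cell: float
    T_in: float
    v_in: float
    d_hole: float = 0.0032
    T_local: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.V_cell > 0.0:
            raise ValueError(f"V_cell must be positive, got {self.V_cell!r}")
        if not self.T_in > 0.0:
            raise ValueError("T_in must be positive")
        if self.v_in < 0.0 or self.d_hole <= 0.0:
            raise ValueError("v_in must be non-negative and d_hole positive")
        if self.T_local is not None and not self.T_local > 0.0:
            raise ValueError("T_local must be positive")

    def mdot(self, p: float) -> float:
        """Inflow mass rate, kg/s, at the inflow state."""
        return air_density(self.T_in, p) * self.v_in * math.pi * self.d_hole**2 / 4.0

    def thermal_mass(self, p: float) -> float:
        """Heat capacity of the gas in the cell, J/K, at the inflow state."""
        return air_density(self.T_in, p) * self.V_cell * CP_AIR


def gas_cell_rhs(cell: GasCell, q_drop: float, air: AirState) -> float:
    """Rate of change of the local gas temperature, K/s.

    ``q_drop`` is the heat input from the droplet, W; ``air`` supplies the
    pressure at which the inflow density is evaluated. At equilibrium
    (``q_drop = 0`` and ``T_local = T_in``) the rate is zero; the steady
    offset under constant load is ``q_drop / (mdot cp_a)``.
    """
    T_local = cell.T_local if cell.T_local is not None else cell.T_in
    mdot = cell.mdot(air.p)
    return (mdot * CP_AIR * (cell.T_in - T_local) + q_drop) / cell.thermal_mass(air.p)


def simulate_coupled(
    d: float,
    T_init: float,
    mat: MaterialProperties,
    cell: GasCell,
    Vdg: float,
    p: float,
    options: Optional[SolverOptions] = None,
) -> Trajectory:
    """Co-integrate the three-stage droplet model with the gas cell.

    The droplet's ambient temperature is the evolving ``T_local``; the
    run terminates when the droplet is within ``epsilon_end`` of the local
    gas temperature. Returned samples carry an extra ``T_local_K`` column,
    and ``q_rejected`` splits into cell storage plus outflow enthalpy
    (tracked internally; see the energy-conservation test).
    """
    opts = options or SolverOptions()
    if not d > 0.0:
        raise ValueError(f"diameter must be positive, got {d!r}")
    T_cell0 = cell.T_local if cell.T_local is not None else cell.T_in
    if T_init < T_cell0:
        raise ValueError("T_init below the local gas temperature: cooling model only")

    m = mat.rho * math.pi * d**3 / 6.0
    area = math.pi * d * d
    mdot = cell.mdot(p)
    C_cell = cell.thermal_mass(p)
    Bi_initial = transfer_state(T_init, T_cell0, p, d, Vdg, mat.k_thermal, warn=True).Bi

    # state: [T_droplet, T_local, q_rejected, q_outflow]
    def make_rhs(stage: Stage):
        def f(t, y):
            T, T_loc = y[0], y[1]
            h = transfer_state(T, T_loc, p, d, Vdg, mat.k_thermal).h
            q_dot = area * h * (T - T_loc)
            dT = -q_dot / (m * _stage_cp(stage, T, mat))
            dT_loc = (mdot * CP_AIR * (cell.T_in - T_loc) + q_dot) / C_cell
            return [dT, dT_loc, q_dot, mdot * CP_AIR * (T_loc - cell.T_in)]

        return f

    def ambient_event(t, y):
        return y[0] - y[1] - opts.epsilon_end

    ambient_event.terminal = True
    ambient_event.direction = -1

    segments: list[tuple] = []
    stage = _stage_for_temperature(T_init, mat)
    stages_visited = [stage]
    t0 = 0.0
    y0 = [T_init, T_cell0, 0.0, 0.0]
    truncated = False
    t_precool: Optional[float] = None
    t_solidify: Optional[float] = None
    rate_solid_onset: Optional[float] = None
    if T_init - T_cell0 <= opts.epsilon_end:
        raise ValueError("initial driving temperature difference within epsilon_end")
    while True:
        events = [ambient_event]
        threshold = None
        if stage is Stage.PRECOOLING:
            threshold = mat.T_freeze
        elif stage is Stage.SOLIDIFYING:
            threshold = mat.T_solidus
        if threshold is not None:
            def threshold_event(t, y, _th=threshold):
                return y[0] - _th

            threshold_event.terminal = True
            threshold_event.direction = -1
            events.append(threshold_event)
        sol = solve_ivp(
            make_rhs(stage), (t0, opts.t_max), y0,
            events=events, dense_output=True, rtol=opts.rtol, atol=opts.atol,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"coupled integration failed in stage {stage.value}: {sol.message}")
        t1 = sol.t[-1]
        segments.append((sol, stage, t0, t1))
        crossed = len(events) > 1 and sol.t_events[1].size > 0
        if crossed:
            t_cross = float(sol.t_events[1][0])
            y_cross = list(sol.y_events[1][0])
            y_cross[0] = threshold
            if stage is Stage.PRECOOLING:
                t_precool = t_cross
                stage = Stage.SOLIDIFYING
                h = transfer_state(threshold, y_cross[1], p, d, Vdg, mat.k_thermal).h
                rate_solid_onset = abs(
                    -area * h * (threshold - y_cross[1]) / (m * _stage_cp(stage, threshold, mat))
                )
            else:
                t_solidify = t_cross - (t_precool or 0.0)
                stage = Stage.TEMPERING
            stages_visited.append(stage)
            t0, y0 = t_cross, y_cross
            continue
        if sol.t_events[0].size > 0:
            break
        truncated = True
        break

    t_end = segments[-1][3]
    seg_starts = np.array([s[2] for s in segments])
    grid = np.arange(0.0, t_end, opts.sample_interval)
    grid = np.unique(np.concatenate([grid, seg_starts, [t_end]]))
    rows = {k: [] for k in ("t_s", "T_K", "f_solid", "stage", "Nu", "h_W_m2K", "T_local_K")}
    for t in grid:
        i = max(int(np.searchsorted(seg_starts, t, side="right")) - 1, 0)
        sol_i, stage_i, _, _ = segments[i]
        T, T_loc = (float(v) for v in sol_i.sol(t)[:2])
        h, Nu = _h_nu(T, T_loc, p, d, Vdg, mat, None)
        rows["t_s"].append(float(t))
        rows["T_K"].append(T)
        rows["f_solid"].append(_stage_fraction(stage_i, T, mat))
        rows["stage"].append(stage_i.value)
        rows["Nu"].append(Nu)
        rows["h_W_m2K"].append(h)
        rows["T_local_K"].append(T_loc)
    samples = pd.DataFrame(rows)

    final_sol, final_stage, _, _ = segments[-1]
    yf = final_sol.sol(t_end)
    T_end, T_loc_end, q_rejected, q_outflow = (float(v) for v in yf[:4])
    f_end = _stage_fraction(final_stage, T_end, mat)

    h0 = transfer_state(T_init, T_cell0, p, d, Vdg, mat.k_thermal).h
    rate_initial = abs(
        -area * h0 * (T_init - T_cell0) / (m * _stage_cp(stages_visited[0], T_init, mat))
    )
    tarr = samples["t_s"].to_numpy()
    Nu_mean = float(np.trapezoid(samples["Nu"].to_numpy(), tarr) / t_end)
    h_mean = float(np.trapezoid(samples["h_W_m2K"].to_numpy(), tarr) / t_end)

    traj = Trajectory(
        d=d, T_init=T_init, Ta=cell.T_in, p=p, Vdg=Vdg, samples=samples,
        t_end=t_end, T_end=T_end, f_solid_end=f_end,
        t_precool=t_precool, t_solidify=t_solidify,
        rate_initial=rate_initial, rate_solid_onset=rate_solid_onset,
        Nu_mean=Nu_mean, h_mean=h_mean, Bi_initial=Bi_initial,
        q_rejected=q_rejected, q_latent=m * mat.latent_heat * f_end,
        truncated=truncated, stages_visited=tuple(stages_visited),
    )
    # stash the cell-side ledgers for energy-conservation checks
    traj.cell_storage = C_cell * (T_loc_end - T_cell0)  # type: ignore[attr-defined]
    traj.cell_outflow = q_outflow  # type: ignore[attr-defined]
    return traj
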