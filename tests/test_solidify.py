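import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dropsolid import (
    COCOA_BUTTER,
    DropletState,
    MaterialProperties,
    SolverOptions,
    Stage,
    apparent_cp,
    cp_semisolid,
    energy_audit,
    rhs,
    simulate,
    simulate_apparent,
    solid_fraction,
)

CB = COCOA_BUTTER


def droplet_mass(d, mat=CB):
    return mat.rho * math.pi * d**3 / 6.0


class TestClosures:
    @pytest.mark.parametrize(
        "T, expected", [(291.0, 0.0), (273.0, 1.0), (282.0, 0.5), (300.0, 0.0), (250.0, 1.0)]
    )
    def test_solid_fraction_linear_in_temperature(self, T, expected):
        assert solid_fraction(T, CB) == expected

    @given(st.floats(min_value=250.0, max_value=300.0))
    def test_solid_fraction_bounded_and_monotone(self, T):
        f = solid_fraction(T, CB)
        assert 0.0 <= f <= 1.0
        assert solid_fraction(T - 0.5, CB) >= f

    @pytest.mark.parametrize(
        "f, expected",
        [(0.0, 2200.0), (1.0, 1250.0), (0.875, 1725.0)],  # f=0.875 -> core ratio a=0.5
    )
    def test_cp_semisolid_interpolates_through_core_radius(self, f, expected):
        assert cp_semisolid(f, CB) == pytest.approx(expected, rel=1e-12)

    def test_cp_semisolid_domain(self):
        with pytest.raises(ValueError):
            cp_semisolid(1.5, CB)

    def test_core_radius_ratio(self):
        state = DropletState(d=1e-3, T=280.0, stage=Stage.SOLIDIFYING, f_solid=0.875)
        assert state.a == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize(
        "T, expected",
        [
            (300.0, 2200.0),  # liquid branch
            (270.0, 1250.0),  # solid branch
            # mid-window: semisolid Cp at f=0.5 (a=0.5^(1/3)) plus latent peak L/18
            (282.0, 2004.024 + 157000.0 / 18.0),
        ],
    )
    def test_apparent_cp_branches(self, T, expected):
        assert apparent_cp(T, CB) == pytest.approx(expected, rel=1e-5)

    def test_apparent_cp_peak_dominates_window(self):
        assert apparent_cp(282.0, CB) > 4 * CB.cp_liquid


class TestRhs:
    def test_stage1_matches_hand_energy_balance(self):
        state = DropletState(d=2e-3, T=318.0, stage=Stage.PRECOOLING, f_solid=0.0)
        dTdt, q_dot = rhs(state, CB, 277.0, 0.83, 1e5, freeze_h=100.0)
        expected = 6 * 100.0 * (277.0 - 318.0) / (CB.rho * CB.cp_liquid * 2e-3)
        assert dTdt == pytest.approx(expected, rel=1e-12)
        assert q_dot == pytest.approx(math.pi * (2e-3) ** 2 * 100.0 * 41.0, rel=1e-12)

    def test_stage2_effective_capacity_slows_cooling(self):
        pre = DropletState(d=2e-3, T=291.0, stage=Stage.PRECOOLING, f_solid=0.0)
        sol = DropletState(d=2e-3, T=291.0, stage=Stage.SOLIDIFYING, f_solid=0.0)
        r_pre, _ = rhs(pre, CB, 277.0, 0.83, 1e5)
        r_sol, _ = rhs(sol, CB, 277.0, 0.83, 1e5)
        ratio = (CB.cp_liquid + CB.latent_heat / CB.freezing_range) / CB.cp_liquid
        assert r_pre / r_sol == pytest.approx(ratio, rel=1e-12)

    def test_zero_driving_force(self):
        state = DropletState(d=2e-3, T=277.0, stage=Stage.TEMPERING, f_solid=1.0)
        dTdt, q_dot = rhs(state, CB, 277.0, 0.83, 1e5)
        assert dTdt == 0.0 and q_dot == 0.0


class TestSimulate:
    def test_frozen_h_stage1_matches_closed_form(self):
        """With h pinned, pre-cooling is the textbook lumped exponential."""
        h = 96.0
        # material that never freezes in the run: window far below ambient
        mat = MaterialProperties(
            rho=894.0, cp_liquid=2200.0, cp_solid=1250.0, latent_heat=157000.0,
            T_freeze=250.0, T_solidus=240.0, k_thermal=0.18,
        )
        opts = SolverOptions(freeze_h=h)
        traj = simulate(2e-3, 318.0, mat, 277.0, 0.83, 1e5, opts)
        tau = mat.rho * mat.cp_liquid * 2e-3 / (6 * h)
        t = traj.samples["t_s"].to_numpy()
        analytic = 277.0 + 41.0 * np.exp(-t / tau)
        assert np.allclose(traj.samples["T_K"].to_numpy(), analytic, rtol=1e-6, atol=1e-4)
        assert traj.stages_visited == (Stage.PRECOOLING,)

    def test_stage_ordering_and_monotone_samples(self, cold_traj):
        t = cold_traj.samples["t_s"].to_numpy()
        assert np.all(np.diff(t) > 0)
        stage_rank = {"precooling": 0, "solidifying": 1, "tempering": 2}
        ranks = cold_traj.samples["stage"].map(stage_rank).to_numpy()
        assert np.all(np.diff(ranks) >= 0)
        assert cold_traj.stages_visited == (
            Stage.PRECOOLING, Stage.SOLIDIFYING, Stage.TEMPERING,
        )

    def test_temperature_and_fraction_monotone(self, cold_traj):
        assert np.all(np.diff(cold_traj.samples["T_K"].to_numpy()) < 0)
        f = cold_traj.samples["f_solid"].to_numpy()
        assert np.all(np.diff(f) >= 0)
        assert f[0] == 0.0 and f[-1] == 1.0

    def test_transitions_land_on_thresholds(self, cold_traj):
        s = cold_traj.samples
        T_at_onset = s.loc[s["t_s"] == cold_traj.t_precool, "T_K"].iloc[0]
        assert T_at_onset == pytest.approx(CB.T_freeze, abs=1e-9)
        t_full = cold_traj.t_precool + cold_traj.t_solidify
        T_at_full = s.loc[np.isclose(s["t_s"], t_full), "T_K"].iloc[0]
        assert T_at_full == pytest.approx(CB.T_solidus, abs=1e-9)

    def test_latent_ledger_tracks_solid_fraction(self, cold_traj, baseline_traj):
        m = droplet_mass(2e-3)
        assert cold_traj.q_latent == pytest.approx(m * CB.latent_heat, rel=1e-12)
        assert baseline_traj.q_latent == pytest.approx(
            m * CB.latent_heat * baseline_traj.f_solid_end, rel=1e-12
        )

    def test_baseline_never_fully_solidifies(self, baseline_traj):
        # ambient (277 K) sits inside the freezing window: stage 2 cannot end
        assert baseline_traj.t_solidify is None
        assert baseline_traj.f_solid_end == pytest.approx(
            solid_fraction(277.5, CB), abs=1e-6
        )
        assert not baseline_traj.truncated

    def test_tolerance_halving_leaves_timings(self, cb):
        coarse = simulate(2e-3, 318.0, cb, 263.0, 0.83, 1e5, SolverOptions(rtol=1e-6, atol=1e-8))
        fine = simulate(2e-3, 318.0, cb, 263.0, 0.83, 1e5, SolverOptions(rtol=5e-7, atol=4e-9))
        assert fine.t_precool == pytest.approx(coarse.t_precool, rel=1e-3)
        assert fine.t_solidify == pytest.approx(coarse.t_solidify, rel=1e-3)

    def test_constant_temperature_when_started_at_ambient(self, cb):
        traj = simulate(2e-3, 277.0, cb, 277.0, 0.83, 1e5)
        assert traj.t_end == 0.0
        assert traj.T_end == 277.0
        assert len(traj.samples) == 1

    def test_heating_configuration_rejected(self, cb):
        with pytest.raises(ValueError, match="cooling"):
            simulate(2e-3, 260.0, cb, 277.0, 0.83, 1e5)

    def test_truncation_flag_on_short_time_cap(self, cb):
        traj = simulate(2e-3, 318.0, cb, 277.0, 0.83, 1e5, SolverOptions(t_max=3.0))
        assert traj.truncated
        assert traj.t_end == pytest.approx(3.0)


class TestEnergyAudit:
    def test_residual_small_for_completed_runs(self, baseline_traj, cold_traj):
        for traj in (baseline_traj, cold_traj):
            assert energy_audit(traj, CB) < 1e-6 * traj.q_rejected

    def test_zero_duration_run_balances_trivially(self, cb):
        traj = simulate(2e-3, 277.0, cb, 277.0, 0.83, 1e5)
        assert energy_audit(traj, cb) == 0.0

    def test_total_latent_heat_of_validation_droplet(self, cold_traj):
        assert cold_traj.q_latent == pytest.approx(0.588, abs=5e-4)


class TestApparentCpComparator:
    def test_fine_step_converges_to_staged_model(self, cb, cold_traj):
        """The two formulations are equivalent in the small-step limit."""
        app = simulate_apparent(2e-3, 318.0, cb, 263.0, 0.83, 1e5, dt=2e-3)
        ref = np.interp(
            app.samples["t_s"], cold_traj.samples["t_s"], cold_traj.samples["T_K"]
        )
        mask = app.samples["t_s"].to_numpy() <= cold_traj.t_end
        err = np.abs(app.samples["T_K"].to_numpy() - ref)[mask]
        assert err.max() < 0.05
        # nearly all latent heat is captured with fine steps
        assert abs(app.latent_deficit) < 1e-3 * droplet_mass(2e-3) * cb.latent_heat

    def test_coarse_step_misses_latent_peak(self, cb):
        """One step across the freezing window releases no latent heat."""
        T0 = cb.T_freeze + 1.0
        state = DropletState(d=2e-3, T=T0, stage=Stage.PRECOOLING, f_solid=0.0)
        rate0 = abs(rhs(state, cb, 263.0, 0.83, 1e5)[0])
        dt = (T0 - (cb.T_solidus - 2.0)) / rate0  # first step lands below the window
        traj = simulate_apparent(2e-3, T0, cb, 263.0, 0.83, 1e5, dt=dt)
        assert traj.f_solid_end == 1.0
        assert traj.latent_deficit > 0.0
        assert traj.latent_deficit > 0.9 * droplet_mass(2e-3) * cb.latent_heat

    def test_no_latent_heat_no_deficit_at_any_step(self):
        mat = MaterialProperties(
            rho=894.0, cp_liquid=2200.0, cp_solid=1250.0, latent_heat=1e-9,
            T_freeze=291.0, T_solidus=273.0, k_thermal=0.18,
        )
        m = droplet_mass(2e-3, mat)
        for dt in (5.0, 0.5, 0.01):
            traj = simulate_apparent(2e-3, 318.0, mat, 263.0, 0.83, 1e5, dt=dt)
            assert abs(traj.latent_deficit) <= m * mat.latent_heat

    def test_nonpositive_step_rejected(self, cb):
        with pytest.raises(ValueError):
            simulate_apparent(2e-3, 318.0, cb, 263.0, 0.83, 1e5, dt=0.0)
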