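import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dropsolid import (
    COCOA_BUTTER,
    SolverOptions,
    air_state,
    fit_exponential,
    gwie_h,
    gwie_nu,
    htc,
    run_validation,
    simulate,
    sweep,
    sweep_dataframe,
)


class TestRunValidation:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            run_validation("warm_300K")

    def test_cold_scenario_reaches_tempering(self):
        summary = run_validation("cold_263K")
        assert summary["f_solid_end"] == 1.0
        assert summary["t_full_solid_s"] == pytest.approx(
            summary["t_precool_s"] + summary["t_solidify_s"]
        )


class TestSweep:
    def test_single_point_grid(self):
        records = sweep([300.0], [250.0], [50.0])
        assert len(records) == 1
        assert records[0].t_precool_s > 0 and records[0].t_solidify_s > 0

    def test_deterministic_ordering_diameter_outermost(self):
        records = sweep([200.0, 400.0], [220.0, 250.0], [50.0])
        assert [(r.d_um, r.Ta_K) for r in records] == [
            (200.0, 220.0), (200.0, 250.0), (400.0, 220.0), (400.0, 250.0),
        ]

    def test_times_increase_with_diameter(self):
        records = sweep([200.0, 500.0], [250.0], [50.0])
        assert records[1].t_precool_s > records[0].t_precool_s
        assert records[1].t_solidify_s > records[0].t_solidify_s

    def test_failure_annotated_with_combination(self):
        # ambient above the solidus: solidification can never complete
        with pytest.raises(RuntimeError, match="Ta=280.0"):
            sweep([200.0], [280.0], [50.0])

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            sweep([], [250.0], [50.0])

    def test_dataframe_columns(self):
        df = sweep_dataframe(sweep([300.0], [250.0], [50.0]))
        assert list(df.columns) == ["d_um", "Ta_K", "Vdg_cm_s", "t_precool_s", "t_solidify_s"]


class TestFitExponential:
    def test_noiseless_recovery(self):
        d = np.array([200.0, 300.0, 400.0, 500.0])
        t = 0.5 * np.exp(0.002 * d)
        fit = fit_exponential(d, t)
        assert fit.prefactor == pytest.approx(0.5, rel=1e-10)
        assert fit.rate == pytest.approx(0.002, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert np.abs(fit.residuals).max() < 1e-10

    def test_callable_evaluates_model(self):
        d = np.array([200.0, 300.0, 400.0, 500.0])
        fit = fit_exponential(d, 0.5 * np.exp(0.002 * d))
        assert fit(250.0) == pytest.approx(0.5 * math.exp(0.5), rel=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_exponential([200.0, 300.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="3 distinct"):
            fit_exponential([200.0, 200.0, 300.0], [1.0, 1.0, 2.0])

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_exponential([200.0, 300.0, 400.0], [1.0, 0.0, 2.0])


class TestGwieEstimators:
    def test_inversion_consistency_with_frozen_h(self):
        """Applied to a frozen-h lumped cooling curve, the estimator
        recovers the coefficient that generated it."""
        h_true = 96.0
        from dropsolid import MaterialProperties

        mat = MaterialProperties(
            rho=894.0, cp_liquid=2200.0, cp_solid=1250.0, latent_heat=157000.0,
            T_freeze=250.0, T_solidus=240.0, k_thermal=0.18,
        )
        traj = simulate(2e-3, 318.0, mat, 277.0, 0.83, 1e5, SolverOptions(freeze_h=h_true))
        row = traj.samples.iloc[len(traj.samples) // 2]
        h_est = gwie_h(2200.0, 894.0, 2e-3, 318.0, row["T_K"], 277.0, row["t_s"])
        assert abs(h_est - h_true) / h_true < 0.005

    @given(st.floats(min_value=0.5, max_value=20.0))
    def test_inverse_time_scaling(self, t):
        h1 = gwie_h(2200.0, 894.0, 2e-3, 318.0, 291.0, 277.0, t)
        h2 = gwie_h(2200.0, 894.0, 2e-3, 318.0, 291.0, 277.0, 2 * t)
        assert h1 == pytest.approx(2 * h2, rel=1e-12)

    def test_log_undefined_when_droplet_at_ambient(self):
        with pytest.raises(ValueError):
            gwie_h(2200.0, 894.0, 2e-3, 318.0, 277.0, 277.0, 7.0)
        with pytest.raises(ValueError):
            gwie_h(2200.0, 894.0, 2e-3, 318.0, 318.0, 277.0, 7.0)  # no cooling yet

    def test_gwie_nu_arithmetic_and_roundtrip(self):
        assert gwie_nu(96.86, 2e-3, 0.0244) == pytest.approx(7.94, abs=0.005)
        ka = air_state(277.0, 1e5).k_a
        assert gwie_nu(htc(7.85, ka, 2e-3), 2e-3, ka) == pytest.approx(7.85, rel=1e-12)
        assert gwie_nu(0.0, 2e-3, 0.0244) == 0.0
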