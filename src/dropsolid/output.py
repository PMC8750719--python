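"""Serialization of trajectories: CSV time series and JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .properties import MaterialProperties
from .solidify import Trajectory, energy_audit

__all__ = ["trajectory_summary", "write_outputs", "read_trajectory_csv"]


def trajectory_summary(traj: Trajectory, mat: MaterialProperties) -> dict:
    """JSON-ready summary of a completed trajectory.

    Durations in seconds, rates as positive magnitudes in K/s; ``null``
    entries mark stages the run never completed (e.g. no full
    solidification when ambient sits inside the freezing window).
    """
    return {
        "t_precool_s": traj.t_precool,
        "t_solidify_s": traj.t_solidify,
        "t_end_s": traj.t_end,
        "T_end_K": traj.T_end,
        "f_solid_end": traj.f_solid_end,
        "rate_initial_K_s": traj.rate_initial,
        "rate_solid_onset_K_s": traj.rate_solid_onset,
        "Nu_mean": traj.Nu_mean,
        "h_mean": traj.h_mean,
        "Bi": traj.Bi_initial,
        "q_rejected_J": traj.q_rejected,
        "q_latent_J": traj.q_latent,
        "energy_residual_J": energy_audit(traj, mat),
        "truncated": traj.truncated,
    }


def write_outputs(
    traj: Trajectory,
    summary: dict,
    csv_path: str | Path,
    json_path: Optional[str | Path] = None,
) -> None:
    """Write the sampled time series as CSV and the summary as JSON.

    Rewriting the same trajectory to the same paths is idempotent. An
    empty trajectory (no samples) is a contract violation and raises.
    """
    if traj.samples.empty:
        raise ValueError("trajectory has no samples; nothing to write")
    traj.samples.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read back a time-series CSV written by :func:`write_outputs`.

    Uses round-trip float parsing so a written series is recovered
    bit-for-bit.
    """
    return pd.read_csv(path, float_precision="round_trip")
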