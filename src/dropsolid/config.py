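"""YAML run configuration: schema, validation, packaged scenario files.

Config keys carry explicit SI unit suffixes (``Ta_K``, ``Vdg_m_s``,
``d_m`` ...) so that a value can never be silently misread in the wrong
unit — the mix of mm, microns, cm/s and bar in the source literature
makes that an easy mistake. Unknown keys anywhere in the file are
rejected with an error naming the key; missing optional blocks fall back
to documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import yaml

from .chamber import GasCell
from .properties import COCOA_BUTTER, MaterialProperties
from .solidify import SolverOptions

__all__ = ["RunConfig", "load_config", "packaged_config_path", "PACKAGED_CONFIGS"]

#: Names of scenario configs shipped inside the package.
PACKAGED_CONFIGS = ("baseline_277K", "cold_263K")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated inputs for one simulation run."""

    material: MaterialProperties
    d_m: float
    T_init_K: float
    Ta_K: float
    p_Pa: float
    Vdg_m_s: float
    coupling: Optional[GasCell] = None
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if not self.d_m > 0.0:
            raise ValueError(f"droplet.d_m must be positive, got {self.d_m!r}")
        for name in ("T_init_K", "Ta_K", "p_Pa"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.Vdg_m_s < 0.0:
            raise ValueError(f"ambient.Vdg_m_s must be non-negative, got {self.Vdg_m_s!r}")


_MATERIAL_KEYS = {
    "rho_kg_m3": "rho",
    "cp_liquid_J_kgK": "cp_liquid",
    "cp_solid_J_kgK": "cp_solid",
    "latent_heat_J_kg": "latent_heat",
    "T_freeze_K": "T_freeze",
    "T_solidus_K": "T_solidus",
    "k_thermal_W_mK": "k_thermal",
}
_SOLVER_KEYS = {
    "rtol": "rtol",
    "atol": "atol",
    "epsilon_end_K": "epsilon_end",
    "t_max_s": "t_max",
    "sample_interval_s": "sample_interval",
}
_COUPLING_KEYS = {
    "enabled": None,
    "V_cell_m3": "V_cell",
    "T_in_K": "T_in",
    "v_in_m_s": "v_in",
    "d_hole_m": "d_hole",
}


def _require_mapping(block: Any, name: str) -> dict:
    if not isinstance(block, dict):
        raise ValueError(f"config section {name!r} must be a mapping, got {type(block).__name__}")
    return block


def _reject_unknown(block: dict, allowed: set[str], section: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )


def _number(block: dict, key: str, section: str) -> float:
    value = block[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValueError(f"{section}.{key} must be a number, got {value!r}")
    return float(value)


def _parse_material(block: Any) -> MaterialProperties:
    if block is None or block == "cocoa_butter":
        return COCOA_BUTTER
    block = _require_mapping(block, "material")
    _reject_unknown(block, set(_MATERIAL_KEYS), "material")
    missing = set(_MATERIAL_KEYS) - set(block)
    if missing:
        raise ValueError(f"material section missing key(s) {sorted(missing)}")
    return MaterialProperties(
        **{attr: _number(block, key, "material") for key, attr in _MATERIAL_KEYS.items()}
    )


def _parse_solver(block: Any) -> SolverOptions:
    if block is None:
        return SolverOptions()
    block = _require_mapping(block, "solver")
    _reject_unknown(block, set(_SOLVER_KEYS), "solver")
    kwargs = {
        attr: _number(block, key, "solver") for key, attr in _SOLVER_KEYS.items() if key in block
    }
    return SolverOptions(**kwargs)


def _parse_coupling(block: Any) -> Optional[GasCell]:
    if block is None:
        return None
    block = _require_mapping(block, "coupling")
    _reject_unknown(block, set(_COUPLING_KEYS), "coupling")
    enabled = block.get("enabled", False)
    if not isinstance(enabled, bool):
        raise ValueError(f"coupling.enabled must be a boolean, got {enabled!r}")
    if not enabled:
        return None
    for key in ("V_cell_m3", "T_in_K", "v_in_m_s"):
        if key not in block:
            raise ValueError(f"coupling section missing key {key!r} (required when enabled)")
    return GasCell(
        V_cell=_number(block, "V_cell_m3", "coupling"),
        T_in=_number(block, "T_in_K", "coupling"),
        v_in=_number(block, "v_in_m_s", "coupling"),
        d_hole=_number(block, "d_hole_m", "coupling") if "d_hole_m" in block else 0.0032,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration from a YAML file.

    Raises ``ValueError`` naming the offending field and constraint on
    any invalid or unknown entry.
    """
    raw = yaml.safe_load(Path(path).read_text())
    doc = _require_mapping(raw, "<root>")
    _reject_unknown(doc, {"material", "droplet", "ambient", "coupling", "solver"}, "<root>")
    for section in ("droplet", "ambient"):
        if section not in doc:
            raise ValueError(f"config is missing required section {section!r}")

    droplet = _require_mapping(doc["droplet"], "droplet")
    _reject_unknown(droplet, {"d_m", "T_init_K"}, "droplet")
    ambient = _require_mapping(doc["ambient"], "ambient")
    _reject_unknown(ambient, {"Ta_K", "p_Pa", "Vdg_m_s"}, "ambient")
    for block, section, keys in (
        (droplet, "droplet", ("d_m", "T_init_K")),
        (ambient, "ambient", ("Ta_K", "p_Pa", "Vdg_m_s")),
    ):
        for key in keys:
            if key not in block:
                raise ValueError(f"config section {section!r} missing key {key!r}")

    return RunConfig(
        material=_parse_material(doc.get("material")),
        d_m=_number(droplet, "d_m", "droplet"),
        T_init_K=_number(droplet, "T_init_K", "droplet"),
        Ta_K=_number(ambient, "Ta_K", "ambient"),
        p_Pa=_number(ambient, "p_Pa", "ambient"),
        Vdg_m_s=_number(ambient, "Vdg_m_s", "ambient"),
        coupling=_parse_coupling(doc.get("coupling")),
        solver=_parse_solver(doc.get("solver")),
    )


def packaged_config_path(name: str) -> Path:
    """Filesystem path of a packaged scenario config (e.g. ``baseline_277K``)."""
    if name not in PACKAGED_CONFIGS:
        raise KeyError(f"unknown packaged config {name!r}; available: {PACKAGED_CONFIGS}")
    return Path(str(resources.files("dropsolid").joinpath("data", f"{name}.yaml")))
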