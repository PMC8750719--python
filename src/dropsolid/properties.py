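"""Thermophysical property containers and dry-air transport correlations.

The droplet model needs two kinds of properties: constants of the
solidifying material (density, solid/liquid specific heats, latent heat,
the phase-change temperature window) and temperature-dependent transport
properties of the surrounding air (density, viscosity, conductivity) from
which the Prandtl number is assembled.

Air follows the ideal-gas law for density and Sutherland-form
correlations for viscosity and thermal conductivity — the standard dry-air
closures for this temperature range. The specific heat of air is held
constant at 1006 J/(kg K); it varies by under 1% between 220 and 320 K.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MaterialProperties",
    "AirState",
    "COCOA_BUTTER",
    "R_AIR",
    "CP_AIR",
    "air_density",
    "air_viscosity",
    "air_conductivity",
    "air_state",
]

#: Specific gas constant of dry air, J/(kg K).
R_AIR = 287.0
#: Specific heat of air at constant pressure, J/(kg K); treated as constant.
CP_AIR = 1006.0

# Sutherland's law reference constants for dry air.
_MU_REF = 1.716e-5  # Pa s at 273.15 K
_K_REF = 0.0241  # W/(m K) at 273.15 K
_T_REF = 273.15  # K
_S_MU = 110.4  # K, Sutherland constant for viscosity
_S_K = 194.0  # K, Sutherland constant for conductivity


@dataclass(frozen=True)
class MaterialProperties:
    """Constant thermophysical properties of the solidifying substance.

    Properties are assumed constant within each phase (they may differ
    between liquid and solid). Phase change spreads over the temperature
    window [T_solidus, T_freeze].

    Parameters
    ----------
    rho : float
        Density, kg/m^3 (same in both phases; the droplet neither shrinks
        nor loses mass).
    cp_liquid : float
        Specific heat of the liquid, J/(kg K).
    cp_solid : float
        Specific heat of the solid, J/(kg K).
    latent_heat : float
        Latent heat of crystallization, J/kg.
    T_freeze : float
        Phase-change onset temperature, K (solidification starts here on
        cooling).
    T_solidus : float
        Phase-change end temperature, K (the droplet is fully solid).
    k_thermal : float
        Thermal conductivity, W/(m K). Used only for the Biot-number
        diagnostic, never in the lumped energy balance.
    """

    rho: float
    cp_liquid: float
    cp_solid: float
    latent_heat: float
    T_freeze: float
    T_solidus: float
    k_thermal: float

    def __post_init__(self) -> None:
        for name in (
            "rho",
            "cp_liquid",
            "cp_solid",
            "latent_heat",
            "T_freeze",
            "T_solidus",
            "k_thermal",
        ):
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"MaterialProperties.{name} must be strictly positive, got {value!r}")
        if not self.T_freeze > self.T_solidus:
            raise ValueError(
                f"T_freeze ({self.T_freeze} K) must exceed T_solidus ({self.T_solidus} K)"
            )

    @property
    def freezing_range(self) -> float:
        """Width of the phase-change window T_freeze - T_solidus, K."""
        return self.T_freeze - self.T_solidus


#: Cocoa butter. Density, specific heats and latent heat are standard
#: literature values; the onset/end temperatures 291 K / 273 K bracket the
#: crystallization window. The thermal conductivity 0.18 W/(m K) is
#: back-derived from the reported Biot number of ~0.18 for a 2 mm droplet
#: with h ~ 97 W/(m^2 K); it only feeds the Bi diagnostic.
COCOA_BUTTER = MaterialProperties(
    rho=894.0,
    cp_liquid=2200.0,
    cp_solid=1250.0,
    latent_heat=157_000.0,
    T_freeze=291.0,
    T_solidus=273.0,
    k_thermal=0.18,
)


@dataclass(frozen=True)
class AirState:
    """Ambient gas state with derived transport properties.

    Attributes
    ----------
    T : float
        Temperature, K.
    p : float
        Pressure, Pa.
    rho_a : float
        Density, kg/m^3.
    mu_a : float
        Dynamic viscosity, Pa s.
    k_a : float
        Thermal conductivity, W/(m K).
    cp_a : float
        Specific heat, J/(kg K).
    Pr : float
        Prandtl number cp_a * mu_a / k_a.
    """

    T: float
    p: float
    rho_a: float
    mu_a: float
    k_a: float
    cp_a: float
    Pr: float

    def __post_init__(self) -> None:
        for name in ("rho_a", "mu_a", "k_a", "cp_a", "Pr"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"AirState.{name} must be strictly positive")
        expected = self.cp_a * self.mu_a / self.k_a
        if abs(self.Pr - expected) > 1e-12 * expected:
            raise ValueError("AirState.Pr inconsistent with cp_a*mu_a/k_a")


def air_density(T: float, p: float) -> float:
    """Dry-air density from the ideal-gas law, kg/m^3.

    Parameters
    ----------
    T : float
        Temperature, K (must be positive).
    p : float
        Pressure, Pa (must be positive).
    """
    if not T > 0.0:
        raise ValueError(f"temperature must be positive, got {T!r}")
    if not p > 0.0:
        raise ValueError(f"pressure must be positive, got {p!r}")
    return p / (R_AIR * T)


def air_viscosity(T: float) -> float:
    """Dry-air dynamic viscosity from Sutherland's law, Pa s."""
    if not T > 0.0:
        raise ValueError(f"temperature must be positive, got {T!r}")
    return _MU_REF * (T / _T_REF) ** 1.5 * (_T_REF + _S_MU) / (T + _S_MU)


def air_conductivity(T: float) -> float:
    """Dry-air thermal conductivity, Sutherland form, W/(m K)."""
    if not T > 0.0:
        raise ValueError(f"temperature must be positive, got {T!r}")
    return _K_REF * (T / _T_REF) ** 1.5 * (_T_REF + _S_K) / (T + _S_K)


def air_state(T: float, p: float) -> AirState:
    """Assemble a full :class:`AirState` at temperature ``T`` and pressure ``p``."""
    mu = air_viscosity(T)
    k = air_conductivity(T)
    return AirState(
        T=T,
        p=p,
        rho_a=air_density(T, p),
        mu_a=mu,
        k_a=k,
        cp_a=CP_AIR,
        Pr=CP_AIR * mu / k,
    )
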