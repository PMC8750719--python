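"""Convective heat transfer to a sphere: Re, Pr, Nu, h and the Biot check.

The heat-transfer coefficient driving every stage of the droplet model
comes from the Ranz-Marshall correlation

    Nu = 2 + 0.6 Pr^(1/3) Re^(1/2),        h = Nu k_a / d,

with the gas-phase transport properties evaluated at the film temperature
(Td + Ta)/2 so that the cooling rates track the warming of the gas layer
around the droplet. The Biot number h (d/6) / k diagnoses whether the
spatially-uniform droplet temperature assumption is defensible; values
above 0.1 raise a warning, not an error, because validation-scale (mm)
droplets exceed it while the micron-scale droplets the model targets do
not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .properties import AirState, air_state

__all__ = [
    "BIOT_LUMPED_LIMIT",
    "TransferState",
    "reynolds",
    "nusselt",
    "htc",
    "biot",
    "film_temperature",
    "transfer_state",
]

logger = logging.getLogger(__name__)

#: Conventional upper bound on Bi for the uniform-temperature assumption.
BIOT_LUMPED_LIMIT = 0.1


@dataclass(frozen=True)
class TransferState:
    """Dimensionless groups and the heat-transfer coefficient at one instant.

    Attributes
    ----------
    Re, Pr, Nu : float
        Reynolds, Prandtl and Nusselt numbers (dimensionless).
    h : float
        Convective heat-transfer coefficient, W/(m^2 K); equals Nu*k_a/d
        for the air state used.
    Bi : float
        Biot number h*(d/6)/k_material (dimensionless).
    """

    Re: float
    Pr: float
    Nu: float
    h: float
    Bi: float


def reynolds(d: float, Vdg: float, air: AirState) -> float:
    """Droplet Reynolds number d * rho_a * Vdg / mu_a.

    ``Vdg`` is the relative drop-gas speed in m/s; zero relative motion
    gives Re = 0 (stagnant gas).
    """
    if not d > 0.0:
        raise ValueError(f"diameter must be positive, got {d!r}")
    if Vdg < 0.0:
        raise ValueError(f"relative speed must be non-negative, got {Vdg!r}")
    return d * air.rho_a * Vdg / air.mu_a


def nusselt(Re: float, Pr: float) -> float:
    """Ranz-Marshall Nusselt number 2 + 0.6 Pr^(1/3) Re^(1/2).

    The additive 2 is the conduction limit for a sphere in stagnant gas,
    so Nu >= 2 always.
    """
    if Re < 0.0:
        raise ValueError(f"Reynolds number must be non-negative, got {Re!r}")
    if not Pr > 0.0:
        raise ValueError(f"Prandtl number must be positive, got {Pr!r}")
    return 2.0 + 0.6 * Pr ** (1.0 / 3.0) * Re**0.5


def htc(Nu: float, ka: float, d: float) -> float:
    """Heat-transfer coefficient h = Nu * ka / d, W/(m^2 K)."""
    if not d > 0.0:
        raise ValueError(f"diameter must be positive, got {d!r}")
    return Nu * ka / d


def biot(h: float, d: float, k_material: float) -> float:
    """Biot number h * l / k with sphere characteristic length l = V/A = d/6.

    Emits a warning through the module logger when Bi exceeds
    :data:`BIOT_LUMPED_LIMIT` — the lumped (uniform-temperature) model is
    then stretched beyond its usual validity window.
    """
    if not k_material > 0.0:
        raise ValueError(f"material conductivity must be positive, got {k_material!r}")
    if not d > 0.0:
        raise ValueError(f"diameter must be positive, got {d!r}")
    if h < 0.0:
        raise ValueError(f"heat-transfer coefficient must be non-negative, got {h!r}")
    Bi = h * (d / 6.0) / k_material
    if Bi > BIOT_LUMPED_LIMIT:
        logger.warning(
            "Biot number %.3g exceeds the lumped-model limit %.2g; "
            "internal temperature gradients are not negligible",
            Bi,
            BIOT_LUMPED_LIMIT,
        )
    return Bi


def film_temperature(Td: float, Ta: float) -> float:
    """Film temperature (Td + Ta)/2 at which gas properties are evaluated."""
    if not (Td > 0.0 and Ta > 0.0):
        raise ValueError("temperatures must be positive")
    return 0.5 * (Td + Ta)


def transfer_state(
    Td: float,
    Ta: float,
    p: float,
    d: float,
    Vdg: float,
    k_material: float,
    *,
    warn: bool = False,
) -> TransferState:
    """Evaluate the full convective closure at one droplet state.

    Gas properties are taken at the film temperature (Td + Ta)/2. With
    ``warn=False`` the Biot number is computed without triggering the
    >0.1 log warning (the per-step path would otherwise spam it).
    """
    air = air_state(film_temperature(Td, Ta), p)
    Re = reynolds(d, Vdg, air)
    Nu = nusselt(Re, air.Pr)
    h = htc(Nu, air.k_a, d)
    if warn:
        Bi = biot(h, d, k_material)
    else:
        Bi = h * (d / 6.0) / k_material
    return TransferState(Re=Re, Pr=air.Pr, Nu=Nu, h=h, Bi=Bi)
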