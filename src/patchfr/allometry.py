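"""Body-mass scaling of the traits that drive the feeding-trial simulator.

All traits follow empirical power laws of body mass (in mg): movement
velocity ``V = v0 * M**a_v`` [cm/s], gut capacity ``G = g0 * M**a_g`` [mg],
digestion rate ``D = d0 * M**a_d`` [mg/s] and handling time
``Th = h0 * Mp**a_h_p * Mn**a_h_n`` [s].  The probability that an attack
succeeds is a generalized Ricker function of the predator:prey body-mass
ratio ``R``::

    S_a = a0 * ((R / R_opt) * exp(1 - R / R_opt)) ** lambda

which peaks at ``S_a = a0`` for ``R = R_opt`` and falls off for predators
that are too small or too large relative to their prey.

Masses are expressed in **milligrams** throughout this module.  The
population-dynamics layer (:mod:`patchfr.odepop`) uses different mass units
per rate equation and performs its own conversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["AllometricConstants", "TraitSet", "attack_success", "compute_traits"]


@dataclass(frozen=True)
class AllometricConstants:
    """Empirical constants of the trait power laws.

    Defaults are the values measured for terrestrial invertebrate
    predator-prey pairs; override individual fields to explore other taxa.
    """

    v0: float = 0.546      # velocity intercept [cm s^-1 mg^-a_v]
    a_v: float = 0.29
    g0: float = 0.50       # gut-capacity intercept [mg mg^-a_g]
    a_g: float = 0.434
    d0: float = 5e-5       # digestion-rate intercept [mg s^-1 mg^-a_d]
    a_d: float = 0.75
    h0: float = 37.504     # handling-time intercept [s]
    a_h_p: float = -0.330  # handling-time exponent, predator mass
    a_h_n: float = 0.173   # handling-time exponent, prey mass
    a0: float = 0.10       # maximum attack success [probability]
    R_opt: float = 100.0   # optimal predator:prey mass ratio
    lam: float = 1.0       # Ricker shape parameter

    def __post_init__(self) -> None:
        for name in ("v0", "g0", "d0", "h0", "a0", "R_opt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.a0 > 1:
            raise ValueError(f"a0 is a probability and must be <= 1, got {self.a0}")


@dataclass(frozen=True)
class TraitSet:
    """Per-trial traits implied by a (predator mass, prey mass) pair."""

    velocity_pred: float   # cm s^-1
    velocity_prey: float   # cm s^-1
    gut_capacity: float    # mg
    digestion_rate: float  # mg s^-1
    handling_time: float   # s
    attack_success: float  # probability per encounter

    def __post_init__(self) -> None:
        for name in (
            "velocity_pred",
            "velocity_prey",
            "gut_capacity",
            "digestion_rate",
            "handling_time",
            "attack_success",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.attack_success > 1:
            raise ValueError("attack_success is a probability")


def attack_success(mass_ratio: float, constants: AllometricConstants | None = None) -> float:
    """Probability that an attack succeeds, given the predator:prey mass ratio.

    Generalized Ricker curve with maximum ``a0`` at ``mass_ratio == R_opt``;
    with ``lam == 0`` the curve degenerates to the constant ``a0``.
    """
    if constants is None:
        constants = AllometricConstants()
    if mass_ratio <= 0:
        raise ValueError(f"mass_ratio must be > 0, got {mass_ratio}")
    rel = mass_ratio / constants.R_opt
    return constants.a0 * (rel * math.exp(1.0 - rel)) ** constants.lam


def compute_traits(
    predator_mass: float,
    prey_mass: float,
    constants: AllometricConstants | None = None,
) -> TraitSet:
    """Evaluate all allometric traits for one predator-prey body-mass pair.

    Parameters
    ----------
    predator_mass, prey_mass
        Body masses in milligrams; both must be positive.
    constants
        Trait-scaling constants; defaults to the built-in empirical set.
    """
    if constants is None:
        constants = AllometricConstants()
    if predator_mass <= 0 or prey_mass <= 0:
        raise ValueError(
            f"masses must be > 0 mg, got predator={predator_mass}, prey={prey_mass}"
        )
    c = constants
    return TraitSet(
        velocity_pred=c.v0 * predator_mass**c.a_v,
        velocity_prey=c.v0 * prey_mass**c.a_v,
        gut_capacity=c.g0 * predator_mass**c.a_g,
        digestion_rate=c.d0 * predator_mass**c.a_d,
        handling_time=c.h0 * predator_mass**c.a_h_p * prey_mass**c.a_h_n,
        attack_success=attack_success(predator_mass / prey_mass, c),
    )
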