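"""Allometric Rosenzweig-MacArthur predator-prey dynamics on a patch.

Prey density N [# m^-2] grows logistically and is consumed through Real's
functional response; predator density P converts consumption with
assimilation efficiency ``e`` during a foraging-time fraction ``omega`` and
pays a metabolic loss ``x``::

    dN/dt = r N (1 - N/K) - omega f(N) P
    dP/dt = e omega f(N) P - x P,      f(N) = f_max N^h / (N0^h + N^h)

Rates are per day.  r, K and x come from empirical body-mass and
temperature scalings (different equations use different mass units: K uses
prey mass in grams, r in micrograms, x predator mass in grams with a
J/s -> 1/d conversion specific to the predator's milligram mass); N0 and h
come from the fitted functional response of the feeding-trial simulator,
and f_max (prey/h in the trials) is converted to prey/day.

The interior equilibrium follows from the isoclines in closed form.  A
population is considered extinct below two individuals per patch, so the
extinction boundary in density units is 2/A for patch area A — this patch
scaling, not any change in the interaction, is what removes predators from
small patches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "EnvironmentSpec",
    "PopulationParams",
    "EquilibriumResult",
    "Status",
    "InfeasiblePredatorError",
    "carrying_capacity",
    "growth_rate",
    "metabolic_rate",
    "population_params",
    "predator_isocline",
    "prey_isocline",
    "classify_equilibrium",
    "coexistence_map",
    "simulate_dynamics",
    "RosenzweigMacArthur",
]


class InfeasiblePredatorError(ValueError):
    """The predator cannot balance metabolism even at saturation
    (e * omega * f_max <= x): no positive predator isocline exists."""


class Status(str, Enum):
    COEXISTENCE = "coexistence"
    PREDATOR_EXTINCT = "predator_extinct"
    PREY_EXTINCT = "prey_extinct"


@dataclass(frozen=True)
class EnvironmentSpec:
    """Constants of the empirical rate scalings (invertebrate detritivore
    communities under temperate-climate productivity).

    ``ln_K0``/``b_K``/``E_K`` scale the carrying capacity with prey mass
    (gram) and temperature; the habitat productivity term uses ``sigma0``,
    ``E_sigma``, ``T0`` and ``z``; ``tl0``/``tl`` adjust for the prey's
    trophic level.  ``ln_r0``/``b_r``/``E_r`` scale the prey growth rate
    (mass in microgram); ``ln_x0``/``b_x``/``E_x`` the predator metabolic
    rate (mass in gram), multiplied by a field-to-basal factor ``sigma_fm``
    and the J/s -> 1/d conversion ``c_x = 12342.86 / M_p`` (M_p in mg).
    """

    temperature: float = 282.65        # K
    predator_mass_mg: float = 100.0
    prey_mass_mg: float = 1.0
    boltzmann: float = 8.62e-5         # eV K^-1
    # carrying capacity
    ln_K0: float = -31.15
    b_K: float = -0.72
    E_K: float = 0.71
    sigma0: float = 600.0
    E_sigma: float = -0.35
    T0: float = 293.15
    z: float = 1.03
    tl0: float = -2.68
    tl: float = 1.5
    # prey intrinsic growth
    ln_r0: float = 32.39
    b_r: float = -0.25
    E_r: float = -0.84
    # predator metabolism
    ln_x0: float = 27.68
    b_x: float = 0.72
    E_x: float = 0.87
    sigma_fm: float = 3.0              # field:basal metabolic rate
    cx_scale: float = 12342.86         # J s^-1 -> d^-1, divided by M_p [mg]

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.predator_mass_mg <= 0 or self.prey_mass_mg <= 0:
            raise ValueError("masses must be > 0")


def carrying_capacity(env: EnvironmentSpec) -> float:
    """Prey carrying capacity K [# m^-2] from mass, temperature, habitat
    productivity and trophic level."""
    kT = env.boltzmann * env.temperature
    mass_g = env.prey_mass_mg / 1000.0
    production = env.sigma0 * math.exp(
        env.E_sigma * (env.T0 - env.temperature) / (kT * env.T0)
    )
    return (
        math.exp(env.ln_K0)
        * mass_g**env.b_K
        * math.exp(env.E_K / kT)
        * production**env.z
        * math.exp(env.tl0 * (env.tl - 1.0))
    )


def growth_rate(env: EnvironmentSpec) -> float:
    """Prey intrinsic growth rate r [d^-1] (mass in microgram)."""
    kT = env.boltzmann * env.temperature
    mass_ug = env.prey_mass_mg * 1000.0
    return math.exp(env.ln_r0) * mass_ug**env.b_r * math.exp(env.E_r / kT)


def metabolic_rate(env: EnvironmentSpec) -> float:
    """Predator metabolic loss rate x [d^-1] (mass in gram), including the
    field-to-basal factor and the J/s -> 1/d normalization."""
    kT = env.boltzmann * env.temperature
    mass_g = env.predator_mass_mg / 1000.0
    c_x = env.cx_scale / env.predator_mass_mg
    return (
        env.sigma_fm
        * c_x
        * math.exp(env.ln_x0)
        * mass_g**env.b_x
        * math.exp(-env.E_x / kT)
    )


@dataclass(frozen=True)
class PopulationParams:
    """Complete rate set of the patch-level predator-prey ODE (per day)."""

    r: float       # prey growth [d^-1]
    K: float       # prey carrying capacity [# m^-2]
    x: float       # predator metabolism [d^-1]
    e: float       # assimilation efficiency
    omega: float   # effective foraging-time proportion
    fmax: float    # maximum feeding rate [# d^-1]
    n0: float      # half-saturation density [# m^-2]
    h: float       # Hill exponent

    def __post_init__(self) -> None:
        for name in ("r", "K", "x", "fmax", "n0", "h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.e <= 1:
            raise ValueError("e must be in (0, 1]")
        if not 0 < self.omega <= 1:
            raise ValueError("omega must be in (0, 1]")


@dataclass(frozen=True)
class EquilibriumResult:
    """Survival classification of one patch."""

    status: Status
    N_star: float                # prey density at the reported state [# m^-2]
    P_star: float                # predator density [# m^-2]
    extinction_boundary: float   # 2 individuals / patch area [# m^-2]
    N_interior: float | None = None  # interior equilibrium, if it exists
    P_interior: float | None = None
    stable: bool | None = None       # sign of the interior-equilibrium eigenvalues


def population_params(
    ln_fmax: float,
    n0: float,
    h: float,
    env: EnvironmentSpec | None = None,
    e: float = 0.85,
    omega: float = 0.5,
) -> PopulationParams:
    """Assemble ODE rates from a fitted functional response and environment.

    ``ln_fmax`` is on the per-hour scale of the feeding trials and is
    converted to per-day; ``omega`` then discounts for the ~12 h daily
    foraging window.
    """
    if env is None:
        env = EnvironmentSpec()
    return PopulationParams(
        r=growth_rate(env),
        K=carrying_capacity(env),
        x=metabolic_rate(env),
        e=e,
        omega=omega,
        fmax=math.exp(ln_fmax) * 24.0,
        n0=n0,
        h=h,
    )


# ---------------------------------------------------------------------------
# isoclines, equilibrium, classification
# ---------------------------------------------------------------------------

def predator_isocline(params: PopulationParams) -> float:
    """Prey density N* at which the predator population is stationary.

    Raises :class:`InfeasiblePredatorError` when assimilated feeding cannot
    match metabolism even at saturation.
    """
    surplus = params.e * params.omega * params.fmax - params.x
    if surplus <= 0:
        raise InfeasiblePredatorError(
            f"e*omega*fmax = {params.e * params.omega * params.fmax:.4g} "
            f"<= x = {params.x:.4g}"
        )
    return (params.x * params.n0**params.h / surplus) ** (1.0 / params.h)


def prey_isocline(params: PopulationParams, N) -> np.ndarray | float:
    """Predator density P at which prey growth balances consumption."""
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("N must be > 0")
    p = params
    out = (
        p.r * N ** (1.0 - p.h) * (p.K - N) * (p.n0**p.h + N**p.h)
        / (p.K * p.omega * p.fmax)
    )
    return float(out) if out.ndim == 0 else out


def _rhs(params: PopulationParams, N: float, P: float) -> tuple[float, float]:
    p = params
    f = p.fmax * N**p.h / (p.n0**p.h + N**p.h)
    dN = p.r * N * (1.0 - N / p.K) - p.omega * f * P
    dP = p.e * p.omega * f * P - p.x * P
    return dN, dP


def _jacobian(params: PopulationParams, N: float, P: float) -> np.ndarray:
    p = params
    Nh = N**p.h
    denom = p.n0**p.h + Nh
    f = p.fmax * Nh / denom
    dfdN = p.fmax * p.h * p.n0**p.h * Nh / (N * denom**2)
    return np.array(
        [
            [p.r * (1.0 - 2.0 * N / p.K) - p.omega * dfdN * P, -p.omega * f],
            [p.e * p.omega * dfdN * P, p.e * p.omega * f - p.x],
        ]
    )


def classify_equilibrium(params: PopulationParams, area_m2: float) -> EquilibriumResult:
    """Compare the interior equilibrium with the two-individuals-per-patch
    extinction boundary.

    The predator goes extinct if no interior equilibrium exists (energetic
    infeasibility or N* >= K) or its equilibrium density falls below the
    boundary; the prey then sits at K (and is itself flagged extinct in the
    degenerate case K < boundary).
    """
    if area_m2 <= 0:
        raise ValueError("area must be > 0")
    boundary = 2.0 / area_m2
    n_int = p_int = None
    stable = None
    try:
        n_star = predator_isocline(params)
    except InfeasiblePredatorError:
        n_star = math.inf
    if n_star < params.K:
        p_star = float(prey_isocline(params, n_star))
        n_int, p_int = n_star, p_star
        eig = np.linalg.eigvals(_jacobian(params, n_star, p_star))
        stable = bool(np.all(eig.real < 0))
        if p_star >= boundary:
            return EquilibriumResult(
                Status.COEXISTENCE, n_star, p_star, boundary,
                N_interior=n_int, P_interior=p_int, stable=stable,
            )
    if params.K < boundary:
        return EquilibriumResult(
            Status.PREY_EXTINCT, 0.0, 0.0, boundary,
            N_interior=n_int, P_interior=p_int, stable=stable,
        )
    return EquilibriumResult(
        Status.PREDATOR_EXTINCT, params.K, 0.0, boundary,
        N_interior=n_int, P_interior=p_int, stable=stable,
    )


def coexistence_map(
    areas: Sequence[float],
    refuge_fractions: Sequence[float],
    fit,
    env: EnvironmentSpec | None = None,
    e: float = 0.85,
    omega: float = 0.5,
    ln_fmax: float | None = None,
) -> pd.DataFrame:
    """Classify every patch-size x refuge combination on the habitat grid.

    ``fit`` is a fitted functional response (anything with ``predict_n0_h``
    and ``ln_fmax``); N0 and h are predicted per grid cell, f_max is shared.
    Infeasibility surfaces as a classification, never as an exception.
    """
    if env is None:
        env = EnvironmentSpec()
    if ln_fmax is None:
        ln_fmax = fit.ln_fmax
    rows = []
    for area in areas:
        for refuge in refuge_fractions:
            n0, h = fit.predict_n0_h(area, refuge)
            params = population_params(ln_fmax, float(n0), float(h), env, e, omega)
            res = classify_equilibrium(params, area)
            rows.append(
                {
                    "area_m2": area,
                    "refuge_fraction": refuge,
                    "status": res.status.value,
                    "N_star": res.N_star,
                    "P_star": res.P_star,
                    "boundary": res.extinction_boundary,
                    "N_interior": res.N_interior,
                    "P_interior": res.P_interior,
                    "stable": res.stable,
                    "n0": float(n0),
                    "h": float(h),
                }
            )
    return pd.DataFrame(rows)


def simulate_dynamics(
    params: PopulationParams,
    N_init: float,
    P_init: float,
    t_end: float,
    n_points: int = 500,
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Numerically integrate the ODE (cross-validation of the equilibria).

    Returns ``(t, N, P)`` arrays over ``[0, t_end]`` days.
    """
    if N_init <= 0 or P_init < 0:
        raise ValueError("initial densities must be positive (prey) and >= 0")
    sol = solve_ivp(
        lambda t, y: _rhs(params, y[0], y[1]),
        (0.0, t_end),
        [N_init, P_init],
        method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_points),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]


class RosenzweigMacArthur:
    """Object wrapper around one parameterised predator-prey system.

    Bundles the rate set with the isoclines, equilibrium classification and
    trajectory simulation::

        sys = RosenzweigMacArthur(params)
        sys.equilibrium()            # (N*, P*)
        sys.classify(area_m2=4.0)    # EquilibriumResult
        sys.simulate(10, 0.1, 5000)  # (t, N, P)
    """

    def __init__(self, params: PopulationParams) -> None:
        self.params = params

    def rhs(self, t: float, y: Sequence[float]) -> list[float]:
        dN, dP = _rhs(self.params, y[0], y[1])
        return [dN, dP]

    def jacobian(self, N: float, P: float) -> np.ndarray:
        return _jacobian(self.params, N, P)

    def predator_isocline(self) -> float:
        return predator_isocline(self.params)

    def prey_isocline(self, N):
        return prey_isocline(self.params, N)

    def equilibrium(self) -> tuple[float, float]:
        """Interior equilibrium (N*, P*), ignoring extinction boundaries."""
        n_star = predator_isocline(self.params)
        return n_star, float(prey_isocline(self.params, n_star))

    def classify(self, area_m2: float) -> EquilibriumResult:
        return classify_equilibrium(self.params, area_m2)

    def simulate(self, N_init: float, P_init: float, t_end: float, **kwargs):
        return simulate_dynamics(self.params, N_init, P_init, t_end, **kwargs)
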