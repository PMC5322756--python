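"""Individual-based feeding-trial simulator.

One predator forages on a fixed density of prey in a square arena of
1 cm x 1 cm cells for one simulated hour (3,600 one-second steps by
default).  A configurable fraction of cells is marked as prey refuge: both
species move through refuge cells freely, but no attack can happen there.
Every eaten prey is instantly replaced at a uniformly random position, so
prey density is exactly constant within a trial.

Movement is an unbiased random walk: a uniform direction in [0, 2*pi) and a
body-mass-dependent step length (velocity x step duration), truncated at the
arena walls (individuals stop at the boundary; walls are impenetrable).

Each step runs in a fixed order: all prey move first, then the predator
(1) digests, (2) keeps handling a previously caught prey if any handling
time remains, (3) rests if its gut is at or above the satiation threshold
(60% of capacity), and otherwise (4) moves and attacks a single prey in its
cell — if one is present and the cell is not a refuge — with the allometric
attack-success probability.

Two engines produce bit-identical results from the same seed: a numba
kernel (default, used for experiment sweeps) and a pure-Python reference
used for unit-level verification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .allometry import AllometricConstants, TraitSet, compute_traits

__all__ = [
    "GUT_SATIATION_THRESHOLD",
    "Arena",
    "Individual",
    "TrialConfig",
    "TrialRecord",
    "build_arena",
    "random_walk_step",
    "predator_step",
    "run_feeding_trial",
    "run_max_feeding_trial",
    "run_max_feeding_experiment",
    "density_ladder",
    "run_experiment",
]

logger = logging.getLogger(__name__)

#: Gut fullness (fraction of capacity) at or above which the predator rests.
GUT_SATIATION_THRESHOLD = 0.6

#: Gut fullness at the start of a trial: predators enter half full, the
#: digestion-limited steady state is reached within the first few captures.
GUT_INITIAL_FRACTION = 0.5

#: Number of cells per square meter at the 1 cm resolution.
CELLS_PER_M2 = 10_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Arena:
    """Square grid of 1 cm^2 cells with a boolean refuge mask and hard walls."""

    width_cells: int
    height_cells: int
    refuge_mask: np.ndarray  # bool, shape (height_cells, width_cells)

    def __post_init__(self) -> None:
        self.refuge_mask = np.asarray(self.refuge_mask, dtype=bool)
        if self.refuge_mask.shape != (self.height_cells, self.width_cells):
            raise ValueError("refuge_mask shape does not match the grid")

    @property
    def n_cells(self) -> int:
        return self.width_cells * self.height_cells

    @property
    def refuge_count(self) -> int:
        return int(self.refuge_mask.sum())

    @property
    def area_m2(self) -> float:
        return self.n_cells / CELLS_PER_M2

    def is_refuge(self, x: float, y: float) -> bool:
        return bool(self.refuge_mask[int(y), int(x)])


@dataclass
class Individual:
    """A mobile predator or prey with continuous position and feeding state."""

    role: Literal["predator", "prey"]
    x: float
    y: float
    gut_content: float = 0.0           # mg, predator only
    handling_steps_remaining: int = 0  # predator only
    prey_identity: int | None = None   # prey only

    @property
    def cell(self) -> tuple[int, int]:
        return (int(self.x), int(self.y))


@dataclass(frozen=True)
class TrialConfig:
    """Design point of one feeding trial."""

    area_m2: float
    refuge_fraction: float
    prey_count: int
    n_steps: int = 3600
    step_seconds: float = 1.0
    predator_mass: float = 100.0  # mg
    prey_mass: float = 1.0        # mg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prey_count < 1:
            raise ValueError("prey_count must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0.0 <= self.refuge_fraction <= 1.0:
            raise ValueError("refuge_fraction must be in [0, 1]")

    @property
    def density(self) -> float:
        """Prey density [individuals m^-2]."""
        return self.prey_count / self.area_m2


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one feeding trial."""

    config: TrialConfig
    eaten_count: int

    @property
    def density(self) -> float:
        return self.config.density


# ---------------------------------------------------------------------------
# arena and elementary steps
# ---------------------------------------------------------------------------

def _grid_side(area_m2: float) -> int:
    side = math.sqrt(area_m2 * CELLS_PER_M2)
    side_int = round(side)
    if side_int < 1 or abs(side - side_int) > 1e-6:
        raise ValueError(
            f"area {area_m2} m^2 does not resolve to a square grid of 1 cm cells"
        )
    return side_int


def build_arena(
    area_m2: float,
    refuge_fraction: float,
    rng: np.random.Generator | None = None,
) -> Arena:
    """Build a square arena with the exact refuge-cell count placed uniformly.

    The refuge cells are drawn without replacement, freshly on every call
    (each simulation run gets a new refuge layout).
    """
    if not 0.0 <= refuge_fraction <= 1.0:
        raise ValueError("refuge_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    side = _grid_side(area_m2)
    n_cells = side * side
    n_refuge = round(refuge_fraction * n_cells)
    mask = np.zeros(n_cells, dtype=bool)
    if n_refuge:
        mask[rng.choice(n_cells, size=n_refuge, replace=False)] = True
    return Arena(width_cells=side, height_cells=side, refuge_mask=mask.reshape(side, side))


def _uniform(rng) -> float:
    """A U[0,1) draw from either a Generator or a legacy RandomState."""
    try:
        return float(rng.random())
    except AttributeError:
        return float(rng.random_sample())


def random_walk_step(
    ind: Individual,
    velocity: float,
    arena: Arena,
    rng,
    step_seconds: float = 1.0,
) -> Individual:
    """One random-walk step: uniform direction, allometric distance, hard walls.

    A displacement that would cross a wall is truncated at the first wall
    contact.  The individual is updated in place and returned.
    """
    angle = 2.0 * math.pi * _uniform(rng)
    ind.x, ind.y = _kernels._move(
        ind.x, ind.y, velocity * step_seconds, angle,
        float(arena.width_cells), float(arena.height_cells),
    )
    return ind


def predator_step(
    predator: Individual,
    prey_list: list[Individual],
    arena: Arena,
    traits: TraitSet,
    rng,
    step_seconds: float = 1.0,
    prey_mass: float = 1.0,
) -> tuple[Individual, list[Individual], bool]:
    """One predator decision step (digest -> handle -> rest -> move -> attack).

    Operates on ``Individual`` objects; the prey list keeps constant length
    because an eaten prey is replaced in place at a random position.  Returns
    the predator, the prey list and whether a prey was eaten this step.
    """
    predator.gut_content = max(
        0.0, predator.gut_content - traits.digestion_rate * step_seconds
    )
    if predator.handling_steps_remaining > 0:
        predator.handling_steps_remaining -= 1
        return predator, prey_list, False
    if predator.gut_content >= GUT_SATIATION_THRESHOLD * traits.gut_capacity:
        return predator, prey_list, False

    random_walk_step(predator, traits.velocity_pred, arena, rng, step_seconds)
    cell = predator.cell
    in_cell = [p for p in prey_list if p.cell == cell]
    if not in_cell or arena.is_refuge(predator.x, predator.y):
        return predator, prey_list, False
    t = int(_uniform(rng) * len(in_cell))
    t = min(t, len(in_cell) - 1)
    target = in_cell[t]
    if _uniform(rng) >= traits.attack_success:
        return predator, prey_list, False  # failed attack: prey stays put
    predator.gut_content += prey_mass
    predator.handling_steps_remaining = _handling_steps(traits, step_seconds)
    target.x = _uniform(rng) * arena.width_cells
    target.y = _uniform(rng) * arena.height_cells
    return predator, prey_list, True


def _handling_steps(traits: TraitSet, step_seconds: float) -> int:
    return int(round(traits.handling_time / step_seconds))


# ---------------------------------------------------------------------------
# full trials
# ---------------------------------------------------------------------------

def _trial_inputs(cfg: TrialConfig, constants: AllometricConstants | None):
    traits = compute_traits(cfg.predator_mass, cfg.prey_mass, constants)
    ss = np.random.SeedSequence(cfg.seed)
    arena_ss, kernel_ss = ss.spawn(2)
    arena = build_arena(cfg.area_m2, cfg.refuge_fraction, np.random.default_rng(arena_ss))
    kernel_seed = int(kernel_ss.generate_state(1)[0] & 0x7FFFFFFF)
    return traits, arena, kernel_seed


def run_feeding_trial(
    cfg: TrialConfig,
    constants: AllometricConstants | None = None,
    engine: Literal["numba", "python"] = "numba",
) -> TrialRecord:
    """Run one spatial feeding trial, reproducible from ``cfg.seed``.

    The refuge layout and the trial randomness are both derived from the
    config seed, so identical configs give bit-identical records with either
    engine.
    """
    traits, arena, kernel_seed = _trial_inputs(cfg, constants)
    args = (
        arena.width_cells,
        arena.height_cells,
        arena.refuge_mask.reshape(-1),
        cfg.prey_count,
        cfg.n_steps,
        traits.velocity_pred * cfg.step_seconds,
        traits.velocity_prey * cfg.step_seconds,
        traits.digestion_rate * cfg.step_seconds,
        traits.gut_capacity,
        GUT_INITIAL_FRACTION * traits.gut_capacity,
        GUT_SATIATION_THRESHOLD,
        _handling_steps(traits, cfg.step_seconds),
        traits.attack_success,
        cfg.prey_mass,
        kernel_seed,
    )
    if engine == "numba":
        eaten = int(_kernels.run_trial_kernel(*args))
    elif engine == "python":
        eaten = _run_trial_python(*args)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return TrialRecord(config=cfg, eaten_count=eaten)


def _run_trial_python(
    width,
    height,
    refuge_flat,
    n_prey,
    n_steps,
    step_pred,
    step_prey,
    digestion_per_step,
    gut_capacity,
    gut_init,
    gut_threshold,
    handling_steps,
    attack_p,
    prey_mass,
    seed,
    trace: dict | None = None,
):
    """Reference engine, draw-for-draw identical to the numba kernel.

    When ``trace`` is a dict it is filled with per-step diagnostics
    (prey-count conservation, gut content, handling state) for invariant
    tests.
    """
    rs = np.random.RandomState(seed)
    u = rs.random_sample
    w, h = float(width), float(height)
    two_pi = 2.0 * math.pi

    px = np.empty(n_prey)
    py = np.empty(n_prey)
    pcell = np.empty(n_prey, np.int64)
    counts = np.zeros(width * height, np.int32)
    for i in range(n_prey):
        px[i] = u() * w
        py[i] = u() * h
        c = int(py[i]) * width + int(px[i])
        pcell[i] = c
        counts[c] += 1
    qx = u() * w
    qy = u() * h

    gut = gut_init
    handling = 0
    eaten = 0
    thresh = gut_threshold * gut_capacity
    if trace is not None:
        trace.update(prey_total=[], gut=[], handling=[], eaten=[])

    for _ in range(n_steps):
        for i in range(n_prey):
            ang = two_pi * u()
            px[i], py[i] = _kernels._move(px[i], py[i], step_prey, ang, w, h)
            c = int(py[i]) * width + int(px[i])
            if c != pcell[i]:
                counts[pcell[i]] -= 1
                counts[c] += 1
                pcell[i] = c

        gut = max(0.0, gut - digestion_per_step)
        if handling > 0:
            handling -= 1
        elif gut >= thresh:
            pass
        else:
            ang = two_pi * u()
            qx, qy = _kernels._move(qx, qy, step_pred, ang, w, h)
            c = int(qy) * width + int(qx)
            if (not refuge_flat[c]) and counts[c] > 0:
                t = min(int(u() * counts[c]), counts[c] - 1)
                idx = -1
                seen = 0
                for i in range(n_prey):
                    if pcell[i] == c:
                        if seen == t:
                            idx = i
                            break
                        seen += 1
                if u() < attack_p:
                    eaten += 1
                    gut += prey_mass
                    handling = handling_steps
                    px[idx] = u() * w
                    py[idx] = u() * h
                    nc = int(py[idx]) * width + int(px[idx])
                    counts[c] -= 1
                    counts[nc] += 1
                    pcell[idx] = nc
        if trace is not None:
            trace["prey_total"].append(int(counts.sum()))
            trace["gut"].append(gut)
            trace["handling"].append(handling)
            trace["eaten"].append(eaten)
    return eaten


def run_max_feeding_trial(
    cfg: TrialConfig,
    constants: AllometricConstants | None = None,
) -> int:
    """Non-spatial maximum-feeding trial: a prey is encountered every step.

    The physiological machinery (digestion, 60% gut threshold, handling,
    attack success) is identical to the spatial trial, but space is removed:
    whenever the predator is hungry and not handling, an attack happens with
    the allometric success probability.  Returns the number of prey eaten.
    """
    traits = compute_traits(cfg.predator_mass, cfg.prey_mass, constants)
    ss = np.random.SeedSequence(cfg.seed)
    rs = np.random.RandomState(int(ss.generate_state(1)[0] & 0x7FFFFFFF))
    u = rs.random_sample
    digestion = traits.digestion_rate * cfg.step_seconds
    thresh = GUT_SATIATION_THRESHOLD * traits.gut_capacity
    handling_steps = _handling_steps(traits, cfg.step_seconds)
    gut = GUT_INITIAL_FRACTION * traits.gut_capacity
    handling = 0
    eaten = 0
    for _ in range(cfg.n_steps):
        gut = max(0.0, gut - digestion)
        if handling > 0:
            handling -= 1
        elif gut >= thresh:
            pass
        elif u() < traits.attack_success:
            eaten += 1
            gut += cfg.prey_mass
            handling = handling_steps
    return eaten


def run_max_feeding_experiment(
    reps: int = 50,
    seed: int = 0,
    constants: AllometricConstants | None = None,
    predator_mass: float = 100.0,
    prey_mass: float = 1.0,
    n_steps: int = 3600,
) -> np.ndarray:
    """Replicate non-spatial maximum-feeding trials; returns eaten counts."""
    counts = np.empty(reps, dtype=int)
    for rep in range(reps):
        cfg = TrialConfig(
            area_m2=0.04,
            refuge_fraction=0.0,
            prey_count=1,
            n_steps=n_steps,
            predator_mass=predator_mass,
            prey_mass=prey_mass,
            seed=_derive_seed(seed, 0, 0, 0, 0, rep),
        )
        counts[rep] = run_max_feeding_trial(cfg, constants)
    return counts


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

#: Twelve patch sizes (m^2) of the full design, petri dish to field patch.
FULL_AREAS = (0.04, 0.16, 0.64, 1.44, 2.56, 4.0, 16.0, 36.0, 49.0, 64.0, 81.0, 100.0)
#: Refuge fractions of the full design: 5%-75% in 5% steps.
FULL_REFUGES = tuple(round(0.05 * i, 2) for i in range(1, 16))

#: Reduced factorial used for desk-scale runs: the five smallest patches and
#: 5%-75% refuge in 10% steps.
DESK_AREAS = (0.04, 0.16, 0.64, 1.44, 2.56)
DESK_REFUGES = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75)


def _derive_seed(master: int, stage: int, i_area: int, i_refuge: int, exponent: int, rep: int) -> int:
    """Deterministic per-trial seed: SeedSequence over the design coordinates.

    Every trial is independently reproducible from its recorded seed via
    ``run_feeding_trial`` without replaying the rest of the sweep.
    """
    ss = np.random.SeedSequence([master, stage, i_area, i_refuge, exponent, rep])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _ladder_trials(
    area_m2: float,
    refuge_fraction: float,
    constants: AllometricConstants | None,
    fmax_estimate: float,
    reps: int,
    seed: int,
    i_area: int,
    i_refuge: int,
    predator_mass: float,
    prey_mass: float,
    n_steps: int,
    satiation_fraction: float,
    max_exponent: int,
    engine: str,
) -> list[TrialRecord]:
    """Run the 2^0, 2^1, ... density ladder until the predator is satiated.

    The ladder stops at the first exponent whose mean eaten count over
    ``reps`` trials reaches ``satiation_fraction`` of the non-spatial
    maximum-feeding estimate.  All ladder trials are returned as data.
    """
    records: list[TrialRecord] = []
    target = satiation_fraction * fmax_estimate
    # physical crowding bound: beyond ~16 prey per cell the feeding rate is
    # long since at its plateau, so the ladder never needs to climb past it
    n_cells = _grid_side(area_m2) ** 2
    cap = min(max_exponent, int(math.ceil(math.log2(16 * n_cells))))
    for exponent in range(cap + 1):
        level: list[TrialRecord] = []
        for rep in range(reps):
            cfg = TrialConfig(
                area_m2=area_m2,
                refuge_fraction=refuge_fraction,
                prey_count=2**exponent,
                n_steps=n_steps,
                predator_mass=predator_mass,
                prey_mass=prey_mass,
                seed=_derive_seed(seed, 1, i_area, i_refuge, exponent, rep),
            )
            try:
                level.append(run_feeding_trial(cfg, constants, engine=engine))
            except Exception:
                logger.exception("trial failed at %s", cfg)
        records.extend(level)
        if level and np.mean([r.eaten_count for r in level]) >= target:
            return records
    logger.warning(
        "satiation not reached by 2^%d at area=%s refuge=%s",
        cap, area_m2, refuge_fraction,
    )
    return records


def density_ladder(
    area_m2: float,
    refuge_fraction: float,
    constants: AllometricConstants | None = None,
    pilot_reps: int = 5,
    seed: int = 0,
    fmax_estimate: float | None = None,
    predator_mass: float = 100.0,
    prey_mass: float = 1.0,
    n_steps: int = 3600,
    satiation_fraction: float = 0.9,
    max_exponent: int = 24,
    engine: str = "numba",
) -> list[int]:
    """Prey counts 2^0 ... 2^n for one design point, n set by pilot satiation.

    ``n`` is the smallest exponent whose pilot mean feeding (``pilot_reps``
    replicate trials) reaches ``satiation_fraction`` of the non-spatial
    maximum-feeding estimate (computed from 50 replicates if not supplied).
    """
    if fmax_estimate is None:
        fmax_estimate = float(
            run_max_feeding_experiment(
                50, seed=seed, constants=constants,
                predator_mass=predator_mass, prey_mass=prey_mass, n_steps=n_steps,
            ).mean()
        )
    records = _ladder_trials(
        area_m2, refuge_fraction, constants, fmax_estimate, pilot_reps, seed,
        0, 0, predator_mass, prey_mass, n_steps, satiation_fraction,
        max_exponent, engine,
    )
    return sorted({r.config.prey_count for r in records})


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the interchange table used by the fitters."""
    rows = [
        {
            "area_m2": r.config.area_m2,
            "refuge_fraction": r.config.refuge_fraction,
            "prey_count": r.config.prey_count,
            "density_per_m2": r.density,
            "rep": i,
            "seed": r.config.seed,
            "eaten": r.eaten_count,
        }
        for i, r in enumerate(records)
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "area_m2", "refuge_fraction", "prey_count",
            "density_per_m2", "rep", "seed", "eaten",
        ],
    )
    # rep index within each design point x density
    if len(df):
        df["rep"] = df.groupby(["area_m2", "refuge_fraction", "prey_count"]).cumcount()
    return df


def run_experiment(
    areas: Sequence[float] = DESK_AREAS,
    refuge_fractions: Sequence[float] = DESK_REFUGES,
    reps: int = 5,
    seed: int = 0,
    constants: AllometricConstants | None = None,
    predator_mass: float = 100.0,
    prey_mass: float = 1.0,
    n_steps: int = 3600,
    satiation_fraction: float = 0.9,
    max_exponent: int = 24,
    fmax_estimate: float | None = None,
    engine: str = "numba",
) -> pd.DataFrame:
    """Full-factorial feeding experiment over patch sizes x refuge fractions.

    For every design point the prey-density ladder 2^0 ... 2^n is simulated
    with ``reps`` replicate trials per density (one predator per trial, a
    fresh refuge layout per trial), with n chosen adaptively by the
    satiation rule.  Per-trial failures are logged and skipped rather than
    aborting the sweep.  Returns the flat trial table.
    """
    if not len(areas) or not len(refuge_fractions):
        raise ValueError("design lists must be non-empty")
    if fmax_estimate is None:
        fmax_estimate = float(
            run_max_feeding_experiment(
                50, seed=seed, constants=constants,
                predator_mass=predator_mass, prey_mass=prey_mass, n_steps=n_steps,
            ).mean()
        )
    records: list[TrialRecord] = []
    if reps > 0:
        for i_area, area in enumerate(areas):
            for i_refuge, refuge in enumerate(refuge_fractions):
                records.extend(
                    _ladder_trials(
                        area, refuge, constants, fmax_estimate, reps, seed,
                        i_area, i_refuge, predator_mass, prey_mass, n_steps,
                        satiation_fraction, max_exponent, engine,
                    )
                )
                logger.info(
                    "design point area=%s refuge=%s done (%d trials)",
                    area, refuge, len(records),
                )
    return records_to_frame(records)
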