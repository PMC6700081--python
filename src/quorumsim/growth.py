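"""Seeding, the division event loop and daughter-cell placement.

One division step picks a mother uniformly at random, leaves one
daughter on the mother's exact position, places the second daughter by
the configured scenario (fixed displacement at a uniform angle, or
independent Gaussian x/y offsets), advances the clock by
t_gap = 1/(gamma * n) with n the pre-division cell count, and then
resolves the induction cascade.  The deterministic increment makes the
per-capita growth exactly exponential at rate gamma: after growing from
n0 to n cells the clock reads (1/gamma) * sum_{k=n0}^{n-1} 1/k.

RNG draw order (one numpy Generator per replicate): Poisson seed count,
seed radii, seed angles; then per step the mother index followed by the
placement draws.  No draw depends on induction state, which is why the
first-induction time of a fixed seed is independent of eta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import resolve_cascade
from .colony import Cell, Colony, EventLog
from .field import FieldSpec
from .params import PlacementScenario, SimulationParams

__all__ = [
    "seed_poisson_disk",
    "seed_grid",
    "place_daughter",
    "division_step",
    "run_simulation",
    "FirstInductionState",
    "SimulationResult",
]


def _field_spec(params: SimulationParams) -> FieldSpec:
    return FieldSpec(alpha=params.alpha, r_c=params.r_c)


def seed_poisson_disk(params: SimulationParams, rng: np.random.Generator) -> Colony:
    """Seed a colony with n_c ~ Poisson(rho * pi * R^2) cells uniform in the disk.

    Area-uniform placement (radius R*sqrt(u), uniform angle); each seed
    receives its own lineage label.  No cell is induced here; the t = 0
    threshold evaluation happens in :func:`run_simulation`.
    """
    mean = params.rho * np.pi * params.R**2
    n_c = int(rng.poisson(mean))
    r = params.R * np.sqrt(rng.random(n_c))
    theta = 2.0 * np.pi * rng.random(n_c)
    return Colony(
        r * np.cos(theta),
        r * np.sin(theta),
        np.arange(n_c),
        spec=_field_spec(params),
        eta=params.eta,
        include_self=params.include_self,
    )


def seed_grid(
    n_cells: int,
    spacing: float,
    *,
    params: SimulationParams,
) -> Colony:
    """Deterministic square-lattice seeding (one seed per node, centered on the origin).

    ``n_cells`` must be a perfect square; nearest lattice neighbours sit
    exactly ``spacing`` um apart.  Used for well-separated-lineage
    experiments and (with n_cells = 1) single-seed burst runs.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    side = int(round(np.sqrt(n_cells)))
    if side * side != n_cells or n_cells <= 0:
        raise ValueError("n_cells must be a positive perfect square")
    offsets = (np.arange(side) - (side - 1) / 2.0) * spacing
    gx, gy = np.meshgrid(offsets, offsets)
    return Colony(
        gx.ravel(),
        gy.ravel(),
        np.arange(n_cells),
        spec=_field_spec(params),
        eta=params.eta,
        include_self=params.include_self,
    )


def place_daughter(
    mother: Cell | tuple[float, float],
    scenario: PlacementScenario,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Position of the displaced daughter; the other daughter keeps the mother's spot.

    fixed mode: distance exactly d_new at a uniform azimuthal angle.
    gaussian mode: independent Normal(0, sigma_str^2) offsets per axis.
    Daughters are never rejected or clipped and may leave the seeding disk.
    """
    if isinstance(mother, Cell):
        x0, y0 = mother.x, mother.y
    else:
        x0, y0 = mother
    if scenario.mode == "fixed":
        angle = 2.0 * np.pi * rng.random()
        return x0 + scenario.d_new * np.cos(angle), y0 + scenario.d_new * np.sin(angle)
    dx, dy = rng.normal(0.0, scenario.sigma_str, size=2)
    return x0 + dx, y0 + dy


def division_step(
    colony: Colony,
    params: SimulationParams,
    rng: np.random.Generator,
) -> dict:
    """Execute one division: pick mother, place daughter, advance clock, cascade.

    Mutates the colony and returns the step record (mother/daughter ids,
    k_t, chi, c_bar, n, cascade member ids).
    """
    n = colony.n
    if n == 0:
        raise ValueError("cannot divide an empty colony")
    mother = int(rng.integers(n))
    x_new, y_new = place_daughter(
        (float(colony.x[mother]), float(colony.y[mother])), params.placement, rng
    )
    colony.t += 1.0 / (params.gamma * n)
    daughter = colony.add_cell(x_new, y_new, int(colony.lineage[mother]))
    result = resolve_cascade(colony, params.beta_thr)
    colony.step += 1
    return {
        "step": colony.step,
        "t": colony.t,
        "mother_id": mother,
        "daughter_id": daughter,
        "k_t": result.k_t,
        "chi": colony.chi,
        "c_bar": float(colony.concentrations.mean()),
        "n": colony.n,
        "members": result.newly_induced_ids,
    }


@dataclass(frozen=True)
class FirstInductionState:
    """Snapshot taken right after the first cascade with k_t > 0."""

    t: float
    n: int
    newly_induced_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    lineage: np.ndarray


@dataclass
class SimulationResult:
    """Final colony, event log and optional snapshots of one replicate."""

    colony: Colony
    log: EventLog
    params: SimulationParams
    first_induction: FirstInductionState | None = None
    snapshots: dict[float, "Colony"] = field(default_factory=dict)


def _initial_colony(params: SimulationParams, rng: np.random.Generator) -> Colony:
    if params.seeding == "grid":
        return seed_grid(params.grid_n, params.grid_spacing, params=params)
    return seed_poisson_disk(params, rng)


def run_simulation(
    params: SimulationParams,
    *,
    initial_colony: Colony | None = None,
    stop_after_first_induction: bool = False,
    snapshot_times: tuple[float, ...] = (),
) -> SimulationResult:
    """Run one replicate: seed, evaluate induction at t = 0, loop divisions.

    The seed configuration is threshold-checked before any division (a
    dense draw may already be super-threshold, recorded as step 0 at
    t = 0).  The loop then repeats :func:`division_step` until the
    termination rule fires; ``max_time`` stops before the step whose
    time increment would pass the bound, so the clock never exceeds it.

    ``stop_after_first_induction`` ends the run right after the first
    cascade with k_t > 0 (used by first-passage ensembles);
    ``snapshot_times`` requests colony copies at the first step whose
    clock passes each listed time.
    """
    rng = np.random.default_rng(params.rng_seed)
    colony = initial_colony if initial_colony is not None else _initial_colony(params, rng)
    log = EventLog()
    snapshots: dict[float, Colony] = {}
    pending_snaps = sorted(snapshot_times)
    first: FirstInductionState | None = None

    def capture_first(members: np.ndarray) -> FirstInductionState:
        return FirstInductionState(
            t=colony.t,
            n=colony.n,
            newly_induced_ids=members.copy(),
            x=colony.x.copy(),
            y=colony.y.copy(),
            lineage=colony.lineage.copy(),
        )

    # t = 0 evaluation of the seed configuration
    if colony.n:
        res0 = resolve_cascade(colony, params.beta_thr)
        log.append(
            0, 0.0, -1, -1, res0.k_t, colony.chi,
            float(colony.concentrations.mean()), colony.n, res0.newly_induced_ids,
        )
        if res0.k_t > 0:
            first = capture_first(res0.newly_induced_ids)

    term = params.termination
    while colony.n:
        if first is not None and stop_after_first_induction:
            break
        if term.kind == "max_time" and colony.t + 1.0 / (params.gamma * colony.n) > term.value:
            break
        if term.kind == "full_induction" and colony.n_induced == colony.n:
            break
        if term.kind == "max_cells" and colony.n >= term.value:
            break
        rec = division_step(colony, params, rng)
        log.append(
            rec["step"], rec["t"], rec["mother_id"], rec["daughter_id"],
            rec["k_t"], rec["chi"], rec["c_bar"], rec["n"], rec["members"],
        )
        if first is None and rec["k_t"] > 0:
            first = capture_first(rec["members"])
        while pending_snaps and colony.t >= pending_snaps[0]:
            snapshots[pending_snaps.pop(0)] = colony.copy()

    return SimulationResult(
        colony=colony, log=log, params=params, first_induction=first, snapshots=snapshots
    )
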