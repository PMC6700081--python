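"""Parameter set, validation and the reproducible-RNG contract.

Unit conventions
----------------
Lengths are micrometres, times are minutes, rates are per minute unless
stated otherwise.  Concentrations are dimensionless "threshold units":
the steady-state field of one non-induced cell evaluated at the
touching distance 2*r_c equals 1, and the induction threshold beta_thr
is expressed directly in these units (the default 30 means "thirty
touching-cell contributions").

Reproducibility
---------------
Each replicate uses a single ``numpy.random.Generator`` seeded with
``rng_seed``; replicate ensembles derive per-replicate seeds as
``base_seed + replicate_index``.  All stochastic draws (Poisson seed
count, seed positions, mother choice, placement angle or Gaussian
offsets) come from this one stream in a fixed, documented order, so two
runs with identical parameters produce bit-identical event logs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

__all__ = [
    "PlacementScenario",
    "Termination",
    "SimulationParams",
    "validate_params",
    "params_to_config_text",
    "params_from_config_text",
]

#: Reference defaults for a growing colony.
_DEFAULTS = {
    "r_c": 2.5,          # cell radius, um
    "R": 100.0,          # initial seeding-disk radius, um
    "rho": 0.0025,       # initial areal density, cells/um^2
    "gamma": 1.0 / 60.0, # per-cell division rate, 1/min
    "phi": 1.0,          # basal AI production rate, 1/s (renormalizes time only)
    "eta": 0.0,          # surplus production factor on induction
    "beta_thr": 30.0,    # induction threshold, threshold units
}


@dataclass(frozen=True)
class PlacementScenario:
    """Daughter-cell placement rule.

    ``fixed`` mode displaces the daughter by exactly ``d_new`` um at a
    uniform random azimuthal angle; ``gaussian`` mode draws independent
    x/y offsets from Normal(0, sigma_str**2).
    """

    mode: str  # "fixed" | "gaussian"
    d_new: float | None = None
    sigma_str: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "gaussian"):
            raise ValueError(f"unknown placement mode {self.mode!r}")
        if self.mode == "fixed":
            if self.d_new is None or self.sigma_str is not None:
                raise ValueError("fixed placement requires d_new and no sigma_str")
            if self.d_new < 0:
                raise ValueError("d_new must be >= 0")
        else:
            if self.sigma_str is None or self.d_new is not None:
                raise ValueError("gaussian placement requires sigma_str and no d_new")
            if self.sigma_str < 0:
                raise ValueError("sigma_str must be >= 0")

    @staticmethod
    def fixed(d_new: float) -> "PlacementScenario":
        return PlacementScenario("fixed", d_new=float(d_new))

    @staticmethod
    def gaussian(sigma_str: float) -> "PlacementScenario":
        return PlacementScenario("gaussian", sigma_str=float(sigma_str))


@dataclass(frozen=True)
class Termination:
    """Stopping rule for the division loop.

    kind is one of ``max_time`` (minutes), ``full_induction`` or
    ``max_cells`` (cell count); ``value`` carries the numeric bound for
    the first and last kinds.
    """

    kind: str
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("max_time", "full_induction", "max_cells"):
            raise ValueError(f"unknown termination kind {self.kind!r}")
        if self.kind in ("max_time", "max_cells"):
            if self.value is None or self.value <= 0:
                raise ValueError(f"termination {self.kind} needs a positive value")
        elif self.value is not None:
            raise ValueError("full_induction takes no value")

    @staticmethod
    def max_time(T: float) -> "Termination":
        return Termination("max_time", float(T))

    @staticmethod
    def full_induction() -> "Termination":
        return Termination("full_induction")

    @staticmethod
    def max_cells(N: int) -> "Termination":
        return Termination("max_cells", float(N))


@dataclass(frozen=True)
class SimulationParams:
    """Immutable, fully validated parameter set for one simulation."""

    alpha: float                      # inverse squared signal range, 1/um^2
    placement: PlacementScenario
    termination: Termination
    rng_seed: int
    r_c: float = _DEFAULTS["r_c"]
    R: float = _DEFAULTS["R"]
    rho: float = _DEFAULTS["rho"]
    gamma: float = _DEFAULTS["gamma"]
    phi: float = _DEFAULTS["phi"]
    eta: float = _DEFAULTS["eta"]
    beta_thr: float = _DEFAULTS["beta_thr"]
    D: float | None = None            # AI diffusivity, um^2/s (optional; alpha = delta/D)
    delta: float | None = None        # AI degradation rate, 1/s (optional)
    include_self: bool = True         # count a cell's own field (the truncated self term)
    seeding: str = "poisson_disk"     # "poisson_disk" | "grid"
    grid_n: int = 100                 # seeds for grid seeding (perfect square)
    grid_spacing: float = 200.0       # lattice constant, um

    def __post_init__(self) -> None:
        for name in ("r_c", "R", "gamma", "beta_thr", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if (self.D is None) != (self.delta is None):
            raise ValueError("give both D and delta or neither")
        if self.D is not None:
            if self.D <= 0 or self.delta <= 0:
                raise ValueError("D and delta must be > 0")
            if not math.isclose(self.alpha, self.delta / self.D, rel_tol=1e-12):
                raise ValueError(
                    f"alpha={self.alpha} conflicts with delta/D={self.delta / self.D}"
                )
        if self.seeding not in ("poisson_disk", "grid"):
            raise ValueError(f"unknown seeding mode {self.seeding!r}")
        if self.seeding == "grid":
            if self.grid_n <= 0 or self.grid_spacing <= 0:
                raise ValueError("grid seeding needs positive grid_n and grid_spacing")

    def replace(self, **changes: Any) -> "SimulationParams":
        return dataclasses.replace(self, **changes)


def validate_params(raw: Mapping[str, Any]) -> SimulationParams:
    """Build a :class:`SimulationParams` from a flat key-value mapping.

    Keys mirror field names.  Placement is given either as
    ``d_new: <um>`` or ``sigma_str: <um>`` (exactly one), or as a nested
    ``placement`` object.  ``alpha`` may be omitted when both ``D``
    (um^2/s) and ``delta`` (1/s) are supplied.  Omitted scalar fields
    take the defaults listed in :data:`_DEFAULTS`; the termination
    default is ``max_time: 240`` minutes.
    """
    raw = dict(raw)

    # --- signal range ---
    D = raw.pop("D", None)
    delta = raw.pop("delta", None)
    alpha = raw.pop("alpha", None)
    if alpha is None:
        if D is None or delta is None:
            raise ValueError("supply alpha, or both D and delta")
        alpha = float(delta) / float(D)

    # --- placement ---
    placement = raw.pop("placement", None)
    d_new = raw.pop("d_new", None)
    sigma_str = raw.pop("sigma_str", None)
    if placement is not None:
        if d_new is not None or sigma_str is not None:
            raise ValueError("give placement or d_new/sigma_str, not both")
        if isinstance(placement, Mapping):
            placement = PlacementScenario(**placement)
        elif not isinstance(placement, PlacementScenario):
            raise ValueError("placement must be a mapping or PlacementScenario")
    else:
        if (d_new is None) == (sigma_str is None):
            raise ValueError("set exactly one of d_new and sigma_str")
        placement = (
            PlacementScenario.fixed(d_new)
            if d_new is not None
            else PlacementScenario.gaussian(sigma_str)
        )

    # --- termination ---
    term = raw.pop("termination", None)
    if term is None:
        term = Termination.max_time(240.0)
    elif isinstance(term, Mapping):
        term = Termination(**term)
    elif isinstance(term, str):
        term = Termination(term)
    elif not isinstance(term, Termination):
        raise ValueError("termination must be a mapping, string or Termination")

    rng_seed = int(raw.pop("rng_seed", raw.pop("seed", 0)))

    kwargs: dict[str, Any] = {}
    for field in (
        "r_c", "R", "rho", "gamma", "phi", "eta", "beta_thr",
        "include_self", "seeding", "grid_n", "grid_spacing",
    ):
        if field in raw:
            kwargs[field] = raw.pop(field)
    if raw:
        raise ValueError(f"unknown parameter keys: {sorted(raw)}")

    if D is not None and delta is not None:
        kwargs["D"] = float(D)
        kwargs["delta"] = float(delta)

    return SimulationParams(
        alpha=float(alpha),
        placement=placement,
        termination=term,
        rng_seed=rng_seed,
        **kwargs,
    )


def _params_to_dict(params: SimulationParams) -> dict[str, Any]:
    d: dict[str, Any] = {
        "alpha": params.alpha,
        "r_c": params.r_c,
        "R": params.R,
        "rho": params.rho,
        "gamma": params.gamma,
        "phi": params.phi,
        "eta": params.eta,
        "beta_thr": params.beta_thr,
        "include_self": params.include_self,
        "seeding": params.seeding,
        "grid_n": params.grid_n,
        "grid_spacing": params.grid_spacing,
        "rng_seed": params.rng_seed,
    }
    if params.placement.mode == "fixed":
        d["d_new"] = params.placement.d_new
    else:
        d["sigma_str"] = params.placement.sigma_str
    d["termination"] = {"kind": params.termination.kind}
    if params.termination.value is not None:
        d["termination"]["value"] = params.termination.value
    if params.D is not None:
        d["D"] = params.D
        d["delta"] = params.delta
    return d


def params_to_config_text(params: SimulationParams) -> str:
    """Serialize to flat YAML; ``params_from_config_text`` round-trips exactly."""
    return yaml.safe_dump(_params_to_dict(params), sort_keys=True)


def params_from_config_text(text: str) -> SimulationParams:
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError("config must be a flat key-value mapping")
    return validate_params(raw)
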