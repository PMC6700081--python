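"""Steady-state autoinducer field of a single cell and its superposition.

A cell emitting at constant rate into a 2D medium with diffusivity D
and first-order degradation delta has the screened steady-state profile
K0(r*sqrt(alpha)) with alpha = delta/D, normalized so that the
concentration equals 1 at the touching distance of two cells,
r = 2*r_c.  For overlapping cells (r <= 2*r_c) the profile is truncated
to that touching value, which removes the logarithmic divergence of K0
at the origin.  The concentration a cell perceives is the weighted sum
of these single-cell fields over the whole colony, induced cells
contributing with weight (1 + eta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import brentq
from scipy.special import k0

if TYPE_CHECKING:  # pragma: no cover
    from .colony import Colony

__all__ = [
    "FieldSpec",
    "c_single",
    "percent_decay_distance",
    "signal_range",
    "perceived_concentration",
    "perceived_concentrations",
    "concentration_field_on_grid",
]


@dataclass(frozen=True)
class FieldSpec:
    """Geometry of the single-cell field: inverse squared signal range and cell radius."""

    alpha: float  # 1/um^2
    r_c: float = 2.5  # um
    norm: float = field(init=False)  # K0 at the touching distance

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.r_c <= 0:
            raise ValueError("r_c must be > 0")
        norm = float(k0(2.0 * self.r_c * np.sqrt(self.alpha)))
        if not np.isfinite(norm) or norm <= 0:
            raise ValueError(
                f"K0 normalization underflows for alpha={self.alpha}, r_c={self.r_c}"
            )
        object.__setattr__(self, "norm", norm)


def c_single(r, spec: FieldSpec):
    """Normalized single-cell concentration at center distance ``r`` (um).

    Equals K0(r*sqrt(alpha)) / K0(2*r_c*sqrt(alpha)) for r > 2*r_c and
    exactly 1 for 0 <= r <= 2*r_c (truncation).  Accepts scalars or
    arrays; strictly decreasing and continuous beyond the truncation
    radius, tending to 0 as r -> infinity.
    """
    r_arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r_arr)):
        raise ValueError("r must be finite")
    if np.any(r_arr < 0):
        raise ValueError("r must be >= 0")
    two_rc = 2.0 * spec.r_c
    out = k0(np.maximum(r_arr, two_rc) * np.sqrt(spec.alpha)) / spec.norm
    out = np.where(r_arr <= two_rc, 1.0, out)
    return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out


def signal_range(alpha: float) -> float:
    """Typical distance 1/sqrt(alpha) an AI molecule diffuses before degrading (um)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return 1.0 / np.sqrt(alpha)


def percent_decay_distance(spec: FieldSpec, i: float) -> float:
    """Distance r_i (um from the cell center) where the field drops to i percent.

    Solves c_single(r_i) = i/100 on r >= 2*r_c; i = 100 returns the
    touching distance itself.  The root is bracketed geometrically and
    refined to 1e-10 relative tolerance.
    """
    if not 0 < i <= 100:
        raise ValueError("i must be in (0, 100]")
    target = i / 100.0
    lo = 2.0 * spec.r_c
    if target >= 1.0:
        return lo
    hi = 2.0 * lo
    while c_single(hi, spec) > target:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for valid specs
            raise RuntimeError("failed to bracket decay distance")
    return float(brentq(lambda r: c_single(r, spec) - target, lo, hi, rtol=1e-10))


def perceived_concentration(colony: "Colony", cell_index: int, *, include_self: bool | None = None) -> float:
    """Perceived AI concentration of one cell, computed from scratch.

    Sums w_j * c_single(d_ij) over all cells j, with w_j = 1 + eta for
    induced emitters.  With ``include_self`` (the colony default) the
    j = i term contributes the cell's own weight via the truncation.
    This naive path is independent of the colony's incremental cache
    and serves as its validation oracle.
    """
    if not 0 <= cell_index < colony.n:
        raise IndexError(cell_index)
    if include_self is None:
        include_self = colony.include_self
    d = np.hypot(colony.x - colony.x[cell_index], colony.y - colony.y[cell_index])
    contrib = c_single(d, colony.spec) * colony.weights
    if not include_self:
        contrib[cell_index] = 0.0
    return float(contrib.sum())


def perceived_concentrations(colony: "Colony") -> np.ndarray:
    """From-scratch perceived concentration of every cell (O(n^2) oracle)."""
    return np.array(
        [perceived_concentration(colony, i) for i in range(colony.n)]
    )


def concentration_field_on_grid(
    colony: "Colony",
    x_nodes: np.ndarray,
    y_nodes: np.ndarray,
) -> np.ndarray:
    """Superposed AI field on a rectangular grid, shape (len(y), len(x)).

    Used for heat-map export only; induction decisions always evaluate
    the field at cell positions.  An empty colony yields zeros.
    """
    x_nodes = np.asarray(x_nodes, dtype=float)
    y_nodes = np.asarray(y_nodes, dtype=float)
    out = np.zeros((y_nodes.size, x_nodes.size))
    if colony.n == 0:
        return out
    w = colony.weights
    gx = x_nodes[None, :]
    gy = y_nodes[:, None]
    for j in range(colony.n):  # cell at a time keeps memory bounded
        d = np.hypot(gx - colony.x[j], gy - colony.y[j])
        out += w[j] * c_single(d, colony.spec)
    return out
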