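"""Colony state: array-backed cell collection with cached AI concentrations.

The colony keeps, for every cell, the perceived autoinducer
concentration (the superposition of all cells' steady-state fields,
optionally including the cell's own truncated self term).  The cache is
maintained incrementally: adding a cell or inducing a cell touches all
n cells once (O(n)), so a whole run costs O(N^2) instead of O(N^3).
``recompute_concentrations`` provides the full-recompute validation
path used by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .field import FieldSpec, c_single

__all__ = ["Cell", "Colony", "EventLog"]


@dataclass(frozen=True)
class Cell:
    """Read-only view of a single cell."""

    id: int
    x: float
    y: float
    lineage: int
    induced: bool
    t_induced: float  # minutes; NaN while non-induced


class Colony:
    """Mutable simulation state: cells, clock and division-step counter."""

    def __init__(
        self,
        x: Iterable[float],
        y: Iterable[float],
        lineage: Iterable[int],
        *,
        spec: FieldSpec,
        eta: float,
        include_self: bool = True,
        capacity: int = 256,
    ) -> None:
        x = np.asarray(list(x), dtype=float)
        y = np.asarray(list(y), dtype=float)
        lineage = np.asarray(list(lineage), dtype=np.int64)
        if not (x.shape == y.shape == lineage.shape):
            raise ValueError("x, y, lineage must have equal length")
        n = x.size
        cap = max(capacity, 2 * n, 2)
        self.spec = spec
        self.eta = float(eta)
        self.include_self = bool(include_self)
        self._x = np.empty(cap)
        self._y = np.empty(cap)
        self._lineage = np.empty(cap, dtype=np.int64)
        self._induced = np.zeros(cap, dtype=bool)
        self._t_induced = np.full(cap, np.nan)
        self._conc = np.zeros(cap)
        self._x[:n] = x
        self._y[:n] = y
        self._lineage[:n] = lineage
        self.n = n
        self.t = 0.0
        self.step = 0
        if n:
            self.recompute_concentrations()

    # ------------------------------------------------------------------ views
    @property
    def x(self) -> np.ndarray:
        return self._x[: self.n]

    @property
    def y(self) -> np.ndarray:
        return self._y[: self.n]

    @property
    def lineage(self) -> np.ndarray:
        return self._lineage[: self.n]

    @property
    def induced(self) -> np.ndarray:
        return self._induced[: self.n]

    @property
    def t_induced(self) -> np.ndarray:
        return self._t_induced[: self.n]

    @property
    def concentrations(self) -> np.ndarray:
        """Cached perceived concentration of every cell (threshold units)."""
        return self._conc[: self.n]

    @property
    def weights(self) -> np.ndarray:
        """Per-cell emission weight: 1 for basal, 1 + eta once induced."""
        return 1.0 + self.eta * self.induced

    @property
    def n_induced(self) -> int:
        return int(self.induced.sum())

    @property
    def chi(self) -> float:
        """Fraction of induced cells (0 for an empty colony)."""
        return self.n_induced / self.n if self.n else 0.0

    def cell(self, i: int) -> Cell:
        if not 0 <= i < self.n:
            raise IndexError(i)
        return Cell(
            id=i,
            x=float(self._x[i]),
            y=float(self._y[i]),
            lineage=int(self._lineage[i]),
            induced=bool(self._induced[i]),
            t_induced=float(self._t_induced[i]),
        )

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[Cell]:
        return (self.cell(i) for i in range(self.n))

    # ------------------------------------------------------------- mutation
    def _grow(self) -> None:
        cap = 2 * self._x.size
        for name in ("_x", "_y", "_conc", "_t_induced"):
            arr = getattr(self, name)
            new = np.empty(cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            if name == "_t_induced":
                new[self.n :] = np.nan
            setattr(self, name, new)
        lin = np.empty(cap, dtype=np.int64)
        lin[: self.n] = self._lineage[: self.n]
        self._lineage = lin
        ind = np.zeros(cap, dtype=bool)
        ind[: self.n] = self._induced[: self.n]
        self._induced = ind

    def _contrib_to_all(self, x: float, y: float) -> np.ndarray:
        """Unit-weight field of a cell at (x, y) evaluated at every cell."""
        d = np.hypot(self.x - x, self.y - y)
        return c_single(d, self.spec)

    def add_cell(self, x: float, y: float, lineage: int) -> int:
        """Append a non-induced cell, updating all cached concentrations.

        Returns the new cell's id.  The newcomer's concentration is the
        weighted sum of all existing fields plus (optionally) its own
        self term; every existing cell gains the newcomer's unit-weight
        contribution.
        """
        if self.n == self._x.size:
            self._grow()
        contrib = self._contrib_to_all(x, y)
        newcomer = float(np.dot(self.weights, contrib))
        if self.include_self:
            newcomer += 1.0  # own field truncated to 1 at r = 0
        self._conc[: self.n] += contrib
        i = self.n
        self._x[i] = x
        self._y[i] = y
        self._lineage[i] = lineage
        self._induced[i] = False
        self._t_induced[i] = np.nan
        self._conc[i] = newcomer
        self.n += 1
        return i

    def induce(self, ids: np.ndarray, t: float) -> None:
        """Irreversibly induce ``ids`` at time ``t`` (minutes).

        Each newly induced cell's emission weight rises from 1 to
        1 + eta, adding eta times its unit field to every concentration.
        """
        ids = np.atleast_1d(np.asarray(ids, dtype=np.int64))
        if ids.size == 0:
            return
        if self._induced[ids].any():
            raise ValueError("cell already induced")
        self._induced[ids] = True
        self._t_induced[ids] = t
        if self.eta == 0.0:
            return
        for i in ids:
            contrib = self._contrib_to_all(self._x[i], self._y[i])
            if not self.include_self:
                contrib[i] = 0.0
            self._conc[: self.n] += self.eta * contrib

    def recompute_concentrations(self) -> None:
        """Full O(n^2) recomputation of the concentration cache."""
        n = self.n
        if n == 0:
            return
        w = self.weights
        conc = np.empty(n)
        for i in range(n):  # row at a time keeps memory flat for large n
            d = np.hypot(self.x - self._x[i], self.y - self._y[i])
            c = c_single(d, self.spec)
            if not self.include_self:
                c[i] = 0.0
            conc[i] = np.dot(w, c)
        self._conc[:n] = conc

    # ---------------------------------------------------------------- copies
    def copy(self) -> "Colony":
        dup = Colony.__new__(Colony)
        dup.spec = self.spec
        dup.eta = self.eta
        dup.include_self = self.include_self
        for name in ("_x", "_y", "_lineage", "_induced", "_t_induced", "_conc"):
            setattr(dup, name, getattr(self, name).copy())
        dup.n = self.n
        dup.t = self.t
        dup.step = self.step
        return dup

    # -------------------------------------------------------------------- io
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "x_um": self.x.copy(),
                "y_um": self.y.copy(),
                "lineage": self.lineage.copy(),
                "induced": self.induced.copy(),
                "t_induced_min": self.t_induced.copy(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @staticmethod
    def from_dataframe(
        df: pd.DataFrame,
        *,
        spec: FieldSpec,
        eta: float,
        include_self: bool = True,
    ) -> "Colony":
        col = Colony(
            df["x_um"].to_numpy(float),
            df["y_um"].to_numpy(float),
            df["lineage"].to_numpy(np.int64),
            spec=spec,
            eta=eta,
            include_self=include_self,
        )
        if "induced" in df.columns and df["induced"].any():
            ids = np.flatnonzero(df["induced"].to_numpy(bool))
            t_ind = df["t_induced_min"].to_numpy(float)[ids]
            col._induced[ids] = True
            col._t_induced[ids] = t_ind
            col.recompute_concentrations()
        return col

    @staticmethod
    def from_csv(path, *, spec: FieldSpec, eta: float, include_self: bool = True) -> "Colony":
        return Colony.from_dataframe(
            pd.read_csv(path), spec=spec, eta=eta, include_self=include_self
        )


class EventLog:
    """Per-division-step record of the induction dynamics.

    One row per step: time (min), mother and daughter ids (-1 for the
    seed-evaluation row at t = 0), the number k_t of cells induced in
    the step's cascade, the induced fraction chi and mean perceived
    concentration c_bar after the step, and the colony size n.  Burst
    membership (the ids induced in a step) is kept for steps with
    k_t > 0.
    """

    def __init__(self) -> None:
        self.step: list[int] = []
        self.t: list[float] = []
        self.mother_id: list[int] = []
        self.daughter_id: list[int] = []
        self.k_t: list[int] = []
        self.chi: list[float] = []
        self.c_bar: list[float] = []
        self.n: list[int] = []
        self.burst_members: dict[int, np.ndarray] = {}

    def append(
        self,
        step: int,
        t: float,
        mother_id: int,
        daughter_id: int,
        k_t: int,
        chi: float,
        c_bar: float,
        n: int,
        members: np.ndarray | None = None,
    ) -> None:
        self.step.append(step)
        self.t.append(t)
        self.mother_id.append(mother_id)
        self.daughter_id.append(daughter_id)
        self.k_t.append(k_t)
        self.chi.append(chi)
        self.c_bar.append(c_bar)
        self.n.append(n)
        if k_t > 0:
            self.burst_members[step] = np.asarray(members, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.step)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.asarray(self.step, dtype=np.int64),
                "t_min": np.asarray(self.t),
                "mother_id": np.asarray(self.mother_id, dtype=np.int64),
                "daughter_id": np.asarray(self.daughter_id, dtype=np.int64),
                "k_t": np.asarray(self.k_t, dtype=np.int64),
                "chi": np.asarray(self.chi),
                "c_bar": np.asarray(self.c_bar),
                "n": np.asarray(self.n, dtype=np.int64),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
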