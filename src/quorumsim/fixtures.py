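"""Deterministic, hand-checkable seed colonies used across the test suites."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "touching_pair",
    "collinear_triple",
    "grid_100",
    "single_seed",
    "dense_blob",
)


def _table(x, y, lineage=None) -> pd.DataFrame:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lineage = np.arange(x.size) if lineage is None else np.asarray(lineage)
    return pd.DataFrame(
        {
            "id": np.arange(x.size),
            "x_um": x,
            "y_um": y,
            "lineage": lineage,
            "induced": np.zeros(x.size, dtype=bool),
            "t_induced_min": np.full(x.size, np.nan),
        }
    )


def make_fixture(name: str) -> pd.DataFrame:
    """Cell table (id, x_um, y_um, lineage, induced, t_induced_min) for ``name``.

    touching_pair: two cells exactly 5 um apart (one touching-distance
    contribution each).  collinear_triple: cells at x = 0, 5, 10 um, the
    cascade oracle geometry.  grid_100: 10x10 lattice, 200 um spacing.
    single_seed: one cell at the origin.  dense_blob: 20 cells in a
    5 um-radius disk from a frozen RNG, a worst-case overlap cluster.
    """
    if name == "touching_pair":
        return _table([0.0, 5.0], [0.0, 0.0])
    if name == "collinear_triple":
        return _table([0.0, 5.0, 10.0], [0.0, 0.0, 0.0])
    if name == "grid_100":
        offsets = (np.arange(10) - 4.5) * 200.0
        gx, gy = np.meshgrid(offsets, offsets)
        return _table(gx.ravel(), gy.ravel())
    if name == "single_seed":
        return _table([0.0], [0.0])
    if name == "dense_blob":
        rng = np.random.default_rng(7)
        r = 5.0 * np.sqrt(rng.random(20))
        th = 2.0 * np.pi * rng.random(20)
        return _table(r * np.cos(th), r * np.sin(th))
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
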