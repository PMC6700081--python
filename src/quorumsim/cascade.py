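"""Threshold test and fixed-point resolution of induction cascades.

Inducing a cell raises its emission weight from 1 to 1 + eta and can
push further cells over the threshold within the same division step.
Because induction never lowers any perceived concentration, the
threshold-closure operator is monotone and its least fixed point is
unique: the final induced set does not depend on the order in which
cells are processed.  ``resolve_cascade`` computes it with synchronous
sweeps (induce all over-threshold cells at once, update, repeat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colony import Colony

__all__ = ["CascadeResult", "threshold_check", "resolve_cascade"]


@dataclass(frozen=True)
class CascadeResult:
    """Outcome of one cascade: ids induced this step and the sweep count."""

    newly_induced_ids: np.ndarray  # chronological (sweep) order
    n_sweeps: int  # threshold_check invocations, including the final empty one

    @property
    def k_t(self) -> int:
        return int(self.newly_induced_ids.size)


def threshold_check(colony: Colony, beta_thr: float) -> np.ndarray:
    """Ids of non-induced cells whose perceived concentration is >= beta_thr.

    Inclusive comparison; does not mutate the colony.
    """
    mask = ~colony.induced & (colony.concentrations >= beta_thr)
    return np.flatnonzero(mask)


def resolve_cascade(colony: Colony, beta_thr: float) -> CascadeResult:
    """Run synchronous sweeps until no further cell crosses the threshold.

    All cells flagged in one sweep are induced simultaneously with
    ``t_induced`` equal to the colony clock (sweeps are instantaneous);
    their surplus emission is then visible to the next sweep.
    Terminates in at most n + 1 sweeps since every non-final sweep
    induces at least one cell.
    """
    induced_ids: list[np.ndarray] = []
    n_sweeps = 0
    while True:
        n_sweeps += 1
        hits = threshold_check(colony, beta_thr)
        if hits.size == 0:
            break
        colony.induce(hits, colony.t)
        induced_ids.append(hits)
    ids = (
        np.concatenate(induced_ids)
        if induced_ids
        else np.empty(0, dtype=np.int64)
    )
    return CascadeResult(newly_induced_ids=ids, n_sweeps=n_sweeps)
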