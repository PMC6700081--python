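"""Replicate orchestration and parameter sweeps.

Replicate seeds derive deterministically from the base seed
(``base + replicate_index``; sweeps add a grid-point offset), so any
single row of a sweep can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import SimulationResult, run_simulation
from .observables import (
    EnsembleSummary,
    cluster_metrics_at_first_induction,
    first_induction_time,
    induction_time_at_fraction,
    mfpt,
    relative_burst_size,
)
from .params import PlacementScenario, SimulationParams

__all__ = [
    "replicate_seed",
    "run_replicates",
    "summarize_replicates",
    "SweepSpec",
    "run_sweep",
]

#: Seed stride between sweep grid points; caps at 2**31 stay far away for
#: the ensemble sizes used here.
_GRID_STRIDE = 100_003


def replicate_seed(base_seed: int, replicate_index: int, grid_index: int = 0) -> int:
    """Deterministic per-replicate seed: base + grid offset + replicate index."""
    return int(base_seed) + grid_index * _GRID_STRIDE + replicate_index


def run_replicates(
    params: SimulationParams,
    n_replicates: int,
    *,
    grid_index: int = 0,
    **run_kwargs,
) -> list[SimulationResult]:
    """Run ``n_replicates`` independent simulations with derived seeds."""
    out = []
    for i in range(n_replicates):
        p = params.replace(rng_seed=replicate_seed(params.rng_seed, i, grid_index))
        out.append(run_simulation(p, **run_kwargs))
    return out


def _c_bar_at_first_induction(result: SimulationResult) -> float:
    for k, c in zip(result.log.k_t, result.log.c_bar):
        if k > 0:
            return c
    return np.nan


def summarize_replicates(
    results: list[SimulationResult],
    chi_levels: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> EnsembleSummary:
    """Aggregate replicate results into one :class:`EnsembleSummary`.

    Censored replicates (no first induction, or chi level never reached)
    are excluded from the corresponding mean and counted.  c_bar is the
    colony-mean concentration at the first-induction step, after the
    cascade resolved.
    """
    n = len(results)
    mean_t, sd_t, n_cens = mfpt(results)

    it_chi: dict[float, tuple[float, float, int]] = {}
    for level in chi_levels:
        times = np.array(
            [induction_time_at_fraction(r.log, level) for r in results]
        )
        ok = times[~np.isnan(times)]
        it_chi[level] = (
            float(ok.mean()) if ok.size else np.nan,
            float(ok.std(ddof=1)) if ok.size > 1 else (0.0 if ok.size else np.nan),
            int(np.isnan(times).sum()),
        )

    cbars = np.array([_c_bar_at_first_induction(r) for r in results])
    cbars_ok = cbars[~np.isnan(cbars)]
    zetas = [relative_burst_size(r) for r in results]
    zetas_ok = [z.zeta for z in zetas if z is not None]
    clusters = [cluster_metrics_at_first_induction(r) for r in results]
    clusters_ok = [c for c in clusters if c is not None]

    return EnsembleSummary(
        n_replicates=n,
        n_censored=n_cens,
        mfpt_mean=mean_t,
        mfpt_sd=sd_t,
        it_chi=it_chi,
        c_bar_mean=float(cbars_ok.mean()) if cbars_ok.size else np.nan,
        c_bar_var=float(cbars_ok.var(ddof=1)) if cbars_ok.size > 1 else np.nan,
        zeta_mean=float(np.mean(zetas_ok)) if zetas_ok else np.nan,
        r_col_mean=float(np.mean([c.r_col for c in clusters_ok])) if clusters_ok else np.nan,
        n_col_mean=float(np.mean([c.n_col for c in clusters_ok])) if clusters_ok else np.nan,
    )


@dataclass(frozen=True)
class SweepSpec:
    """Cartesian parameter sweep over one or more axes.

    Axes may be any of alpha, eta, beta_thr, d_new, sigma_str; the last
    two replace the placement scenario wholesale.  Total runs =
    (product of axis lengths) x n_replicates.
    """

    base: SimulationParams
    axes: dict[str, tuple]
    n_replicates: int = 20
    chi_levels: tuple[float, ...] = (0.25, 0.5, 0.75)
    run_kwargs: dict = field(default_factory=dict)

    _ALLOWED = ("alpha", "eta", "beta_thr", "d_new", "sigma_str")

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("sweep needs at least one axis")
        for name, values in self.axes.items():
            if name not in self._ALLOWED:
                raise ValueError(f"unknown sweep axis {name!r}")
            if len(tuple(values)) == 0:
                raise ValueError(f"axis {name!r} is empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def grid(self) -> list[dict[str, float]]:
        names = list(self.axes)
        points: list[dict[str, float]] = [{}]
        for name in names:
            points = [
                {**pt, name: float(v)} for pt in points for v in self.axes[name]
            ]
        return points

    def params_at(self, point: dict[str, float]) -> SimulationParams:
        changes: dict = {}
        for name, value in point.items():
            if name == "d_new":
                changes["placement"] = PlacementScenario.fixed(value)
            elif name == "sigma_str":
                changes["placement"] = PlacementScenario.gaussian(value)
            else:
                changes[name] = value
        return self.base.replace(**changes)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Execute the sweep grid; one summary row per grid point."""
    rows = []
    for gi, point in enumerate(spec.grid()):
        params = spec.params_at(point)
        results = run_replicates(
            params, spec.n_replicates, grid_index=gi, **spec.run_kwargs
        )
        summ = summarize_replicates(results, spec.chi_levels)
        row: dict = {**point}
        row.update(
            mfpt_mean=summ.mfpt_mean,
            mfpt_sd=summ.mfpt_sd,
            c_bar_mean=summ.c_bar_mean,
            c_bar_var=summ.c_bar_var,
            zeta_mean=summ.zeta_mean,
            r_col_mean=summ.r_col_mean,
            n_col_mean=summ.n_col_mean,
            n_replicates=summ.n_replicates,
            n_censored=summ.n_censored,
        )
        for level, (m, sd, nc) in summ.it_chi.items():
            row[f"it_chi_{level:g}_mean"] = m
            row[f"it_chi_{level:g}_sd"] = sd
            row[f"it_chi_{level:g}_censored"] = nc
        rows.append(row)
    return pd.DataFrame(rows)
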