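"""Quantifiers of the induction process.

Covers per-trajectory series (chi, k_t, c_bar), first-passage
statistics (the mean first-induction time, abbreviated MFPT by analogy
with first-passage problems), the order parameter IT_chi (expected time
to reach a given induced fraction), burst detection with an
8-standard-deviation jump criterion, lineage/family statistics, cluster
geometry at first induction and the relative burst size zeta used to
characterise the eta-driven phase-transition-like behaviour.

Censoring: replicates that never reach the event in question are
excluded from means and reported as a count; nothing is imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colony import Colony, EventLog
from .growth import SimulationResult, seed_poisson_disk
from .params import SimulationParams

__all__ = [
    "BurstAnnotation",
    "ClusterMetrics",
    "BurstPhaseMetrics",
    "EnsembleSummary",
    "first_induction_time",
    "mfpt",
    "induction_time_at_fraction",
    "mean_concentration",
    "static_ensemble",
    "detect_bursts",
    "family_stats",
    "induction_histogram",
    "cluster_metrics_at_first_induction",
    "relative_burst_size",
]

CENSORED = math.nan


@dataclass(frozen=True)
class BurstAnnotation:
    """One flagged induction burst: a step whose k_t jumps far above recent history."""

    step: int
    t: float
    size: int
    member_ids: np.ndarray
    label: int  # chronological ordinal (0 = first burst)


@dataclass(frozen=True)
class ClusterMetrics:
    """Span and size of the first-induced lineage cluster."""

    lineage: int
    r_col: float  # largest member distance to the cluster center of mass, um
    n_col: int


@dataclass(frozen=True)
class BurstPhaseMetrics:
    """Relative size of the first cascade: zeta = k_t / colony size at that step."""

    zeta: float
    burst_cells: int
    colony_size: int


@dataclass(frozen=True)
class EnsembleSummary:
    """Replicate-aggregated statistics at one parameter point."""

    n_replicates: int
    n_censored: int
    mfpt_mean: float
    mfpt_sd: float
    it_chi: dict  # chi level -> (mean, sd, n_censored)
    c_bar_mean: float
    c_bar_var: float
    zeta_mean: float
    r_col_mean: float
    n_col_mean: float


# --------------------------------------------------------------------- times

def first_induction_time(log: EventLog) -> float:
    """Earliest time (min) with k_t > 0, or NaN when the run stayed quiescent."""
    for t, k in zip(log.t, log.k_t):
        if k > 0:
            return t
    return CENSORED


def mfpt(logs) -> tuple[float, float, int]:
    """Mean and sample SD of first-induction times over uncensored replicates.

    Accepts EventLogs, SimulationResults or raw times (NaN = censored).
    Returns (mean, sd, n_censored); all-censored ensembles yield NaN
    mean/sd with the censored count equal to the replicate count.
    """
    times = []
    for item in logs:
        if isinstance(item, SimulationResult):
            times.append(first_induction_time(item.log))
        elif isinstance(item, EventLog):
            times.append(first_induction_time(item))
        else:
            times.append(float(item))
    times = np.asarray(times, dtype=float)
    ok = times[~np.isnan(times)]
    n_censored = int(np.isnan(times).sum())
    if ok.size == 0:
        return CENSORED, CENSORED, n_censored
    sd = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    return float(ok.mean()), sd, n_censored


def induction_time_at_fraction(log: EventLog, chi_target: float) -> float:
    """Earliest time at which chi >= chi_target (the IT_chi order parameter).

    NaN when the target fraction is never reached before termination.
    """
    if not 0.0 < chi_target < 1.0:
        raise ValueError("chi_target must be in (0, 1)")
    chi = np.asarray(log.chi)
    t = np.asarray(log.t)
    hits = np.flatnonzero(chi >= chi_target)
    return float(t[hits[0]]) if hits.size else CENSORED


# -------------------------------------------------------------- concentration

def mean_concentration(colony: Colony) -> float:
    """Arithmetic mean perceived concentration over all cells (threshold units)."""
    if colony.n == 0:
        raise ValueError("empty colony")
    return float(colony.concentrations.mean())


def static_ensemble(
    params: SimulationParams,
    alphas,
    n_runs: int,
    *,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Mean and unbiased sample variance of c_bar over static seed configurations.

    For each alpha, draws ``n_runs`` fresh Poisson-disk configurations
    (no growth, no induction) and evaluates the colony-mean perceived
    concentration.  Returns a frame with columns alpha, c_bar_mean,
    c_bar_var, n_runs.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 for a sample variance")
    seed0 = params.rng_seed if base_seed is None else base_seed
    rows = []
    for alpha in np.atleast_1d(alphas):
        p = params.replace(alpha=float(alpha))
        vals = np.empty(n_runs)
        for k in range(n_runs):
            rng = np.random.default_rng(seed0 + k)
            colony = seed_poisson_disk(p, rng)
            while colony.n == 0:  # variance of c_bar needs a non-empty draw
                colony = seed_poisson_disk(p, rng)
            vals[k] = mean_concentration(colony)
        rows.append(
            {
                "alpha": float(alpha),
                "c_bar_mean": float(vals.mean()),
                "c_bar_var": float(vals.var(ddof=1)),
                "n_runs": n_runs,
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- bursts

def detect_bursts(
    log: EventLog,
    *,
    n_sd: float = 8.0,
    s_min: float = 1.0,
    min_sample: int = 5,
) -> list[BurstAnnotation]:
    """Flag steps whose k_t exceeds the running mean by ``n_sd`` standard deviations.

    The running mean and SD of k_t are taken over all division steps
    since the last flagged burst; flagging resets the sample.  The SD is
    floored at ``s_min`` (one cell) and at least ``min_sample`` steps of
    history are required before a step can be flagged, which keeps the
    degenerate zero-variance start of a trajectory from triggering.
    """
    bursts: list[BurstAnnotation] = []
    sample: list[int] = []
    for step, t, k in zip(log.step, log.t, log.k_t):
        if len(sample) >= min_sample:
            m = float(np.mean(sample))
            s = max(float(np.std(sample)), s_min)
            if k > m + n_sd * s:
                bursts.append(
                    BurstAnnotation(
                        step=step,
                        t=t,
                        size=int(k),
                        member_ids=log.burst_members.get(step, np.empty(0, dtype=np.int64)),
                        label=len(bursts),
                    )
                )
                sample = []
                continue
        sample.append(int(k))
    return bursts


# ------------------------------------------------------------------ lineages

def family_stats(colony: Colony) -> pd.DataFrame:
    """Per-lineage family size n_i and induced fraction chi_i."""
    df = pd.DataFrame({"lineage": colony.lineage, "induced": colony.induced})
    out = (
        df.groupby("lineage")
        .agg(n_i=("induced", "size"), n_induced=("induced", "sum"))
        .reset_index()
    )
    out["chi_i"] = out["n_induced"] / out["n_i"]
    return out


def induction_histogram(
    logs,
    times,
    bins=10,
) -> pd.DataFrame:
    """Ensemble histogram of the induced fraction chi at the requested times.

    For each replicate the chi value at time tp is the last logged value
    with t <= tp.  Returns one row per (time, bin) with counts over
    replicates, plus the per-time ensemble mean of chi.
    """
    edges = np.histogram_bin_edges([], bins=bins, range=(0.0, 1.0))
    rows = []
    for tp in times:
        chis = []
        for log in logs:
            log = log.log if isinstance(log, SimulationResult) else log
            t = np.asarray(log.t)
            idx = np.searchsorted(t, tp, side="right") - 1
            chis.append(log.chi[idx] if idx >= 0 else 0.0)
        counts, _ = np.histogram(chis, bins=edges)
        mean_chi = float(np.mean(chis))
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {"t_min": tp, "chi_lo": lo, "chi_hi": hi, "count": int(c), "mean_chi": mean_chi}
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ clusters

def cluster_metrics_at_first_induction(result: SimulationResult) -> ClusterMetrics | None:
    """Span and size of the lineage cluster containing the first induced cell.

    Evaluated on the colony snapshot at the first-induction step: the
    cluster is every cell sharing the first induced cell's lineage
    label, r_col its largest distance to the cluster center of mass.
    Returns None for censored runs.
    """
    fi = result.first_induction
    if fi is None:
        return None
    lead = int(fi.newly_induced_ids[0])
    lin = int(fi.lineage[lead])
    members = fi.lineage == lin
    mx, my = fi.x[members], fi.y[members]
    cx, cy = mx.mean(), my.mean()
    r_col = float(np.hypot(mx - cx, my - cy).max())
    return ClusterMetrics(lineage=lin, r_col=r_col, n_col=int(members.sum()))


def relative_burst_size(result: SimulationResult) -> BurstPhaseMetrics | None:
    """zeta for the first cascade: cells induced / colony size at that moment.

    None for censored runs (no induction before termination).
    """
    fi = result.first_induction
    if fi is None:
        return None
    k = int(fi.newly_induced_ids.size)
    return BurstPhaseMetrics(zeta=k / fi.n, burst_cells=k, colony_size=fi.n)
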