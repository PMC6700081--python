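import numpy as np
import pytest
from scipy.integrate import quad

from quorumsim import (
    Colony,
    FieldSpec,
    PlacementScenario,
    SimulationParams,
    Termination,
)


def k0_integral(x: float) -> float:
    """Independent high-precision K0 via its integral representation.

    K0(x) = integral_0^inf exp(-x * cosh(t)) dt; evaluated by adaptive
    quadrature, entirely independent of scipy.special.k0.  The upper
    limit is cut where the integrand underflows double precision.
    """
    t_max = np.arccosh(745.0 / x) if x < 745.0 else 1.0
    val, _ = quad(
        lambda t: np.exp(-x * np.cosh(t)), 0.0, t_max, limit=400, epsabs=0.0, epsrel=1e-13
    )
    return val


@pytest.fixture
def default_params() -> SimulationParams:
    return SimulationParams(
        alpha=0.05,
        placement=PlacementScenario.fixed(10.0),
        termination=Termination.max_time(240.0),
        rng_seed=1,
        eta=1.0,
    )


def make_colony(x, y, *, alpha=0.04, r_c=2.5, eta=0.0, include_self=True, lineage=None):
    x = np.asarray(x, dtype=float)
    lineage = np.arange(x.size) if lineage is None else lineage
    return Colony(
        x,
        np.asarray(y, dtype=float),
        lineage,
        spec=FieldSpec(alpha=alpha, r_c=r_c),
        eta=eta,
        include_self=include_self,
    )


def random_colony(rng, n, *, extent=50.0, alpha=0.04, eta=2.0, beta=None):
    x = rng.uniform(-extent, extent, n)
    y = rng.uniform(-extent, extent, n)
    return make_colony(x, y, alpha=alpha, eta=eta)


def brute_force_closure(colony: Colony, beta_thr: float) -> np.ndarray:
    """Minimal superset of the induced set closed under the threshold rule.

    Enumerates all 2^n induction-state vectors (n <= ~14), keeps those
    that (a) contain the current induced set and (b) are closed: every
    cell whose perceived concentration under that state reaches the
    threshold is a member.  Monotonicity of the field in the induced
    set makes the minimal closed superset unique.
    """
    from quorumsim.field import c_single

    n = colony.n
    assert n <= 14, "brute force is exponential"
    # pairwise unit-contribution matrix, with or without the self term
    C = np.empty((n, n))
    for i in range(n):
        d = np.hypot(colony.x - colony.x[i], colony.y - colony.y[i])
        C[i] = c_single(d, colony.spec)
        if not colony.include_self:
            C[i, i] = 0.0
    base = colony.induced.astype(bool)
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # (2^n, n)
    masks = masks.astype(bool)
    supersets = masks[np.all(masks | ~base, axis=1)]
    W = 1.0 + colony.eta * supersets
    conc = W @ C.T  # (m, n) perceived concentration per state per cell
    over = conc >= beta_thr
    closed = np.all(~over | supersets, axis=1)
    candidates = supersets[closed]
    sizes = candidates.sum(axis=1)
    best = candidates[np.argmin(sizes)]
    # uniqueness sanity: exactly one closed set of minimal size
    assert (sizes == sizes.min()).sum() == 1
    return np.flatnonzero(best & ~base)


def async_cascade(colony: Colony, beta_thr: float, rng) -> np.ndarray:
    """One-cell-at-a-time cascade resolution in random order (oracle).

    Returns the sorted ids induced; mutates the colony like
    resolve_cascade does.
    """
    induced: list[int] = []
    while True:
        over = np.flatnonzero(~colony.induced & (colony.concentrations >= beta_thr))
        if over.size == 0:
            break
        pick = int(rng.choice(over))
        colony.induce(np.array([pick]), colony.t)
        induced.append(pick)
    return np.sort(np.asarray(induced, dtype=np.int64))
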