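# Methods

This document describes the model implemented by `quorumsim`, the units
and defaults, the numerical choices that affect results, and how the
implementation is validated.

## 1. Model

### 1.1 Cells and geometry

Cells are points on a 2D substrate (positions in µm). They do not move,
do not exclude volume, and never die. Each cell carries a lineage label
(the index of its seed ancestor), an induction flag, and — if induced —
the time of induction. The cell radius `r_c` (default 2.5 µm) enters
only through the touching distance `2·r_c` used to normalize the field.

### 1.2 Autoinducer field

AI is produced at a constant rate, diffuses with coefficient `D`, and
degrades at rate `delta`. In 2D the steady-state field of a point
source is proportional to the modified Bessel function `K0`. The
simulator works with the dimensionless concentration

```
c(r) = K0(r·sqrt(alpha)) / K0(2·r_c·sqrt(alpha)),   alpha = delta / D
```

so that `c(2·r_c) = 1`: one touching neighbour contributes exactly one
"touching-cell unit". Because `K0` diverges logarithmically at the
origin, the profile is truncated to 1 for `r ≤ 2·r_c`; overlapping
cells (possible since there is no volume exclusion) contribute at the
contact level. `alpha` has units 1/µm² and `1/sqrt(alpha)` is the
signal range — the typical distance an AI molecule diffuses before
degrading. The implemented range of interest is `alpha` from 1e-3
(range ≈ 32 µm) to 1e3 (range ≈ 0.03 µm); `FieldSpec` raises if
`K0(2·r_c·sqrt(alpha))` underflows.

The perceived concentration of cell *i* is the linear superposition

```
C_i = sum_j w_j · c(d_ij),   w_j = 1 + eta if j is induced else 1,
```

including the self term `j = i` (`c(0) = 1` by truncation; the
`include_self` switch exists for static analyses). `eta ≥ 0` is the
surplus emission of induced cells and is the feedback knob of the
model.

### 1.3 Seeding

Three seeding modes:

- `poisson_disk` (default): the number of seeds is
  `n ~ Poisson(rho·pi·R²)` and positions are area-uniform in the disk
  of radius `R` (`r = R·sqrt(u)`). Defaults `rho = 0.0025`/µm²,
  `R = 100` µm give a mean of ≈ 78.5 seeds; `R = 200` µm gives ≈ 314.
  A draw of `n = 0` is redrawn in static ensembles.
- `grid`: `grid_n` cells (a perfect square, or 1) on a centred square
  lattice with spacing `grid_spacing` (default 100 cells, 200 µm) —
  deterministic, used to study lineage mixing.
- `grid_n = 1`: a single seed at the origin, used for the burst-size
  phase transition.

### 1.4 Growth and time

Division is modelled at the mean-field Gillespie level: with `n` cells
each dividing at rate `gamma` (default 1/60 min⁻¹), the time to the
next division is taken as its expectation `1/(gamma·n)` (deterministic
increment), and the mother is chosen uniformly at random. The colony
clock after the k-th division from `n0` seeds is therefore the harmonic
sum `(1/gamma)·sum_{m=n0}^{n0+k-1} 1/m`, i.e. exact exponential growth
at rate `gamma` in the continuum limit. Making the waiting time
deterministic removes one noise source; the placement and mother-choice
randomness dominate the spatial statistics this package studies.

The mother keeps her position; the daughter is placed by one of two
scenarios:

- `fixed(d_new)`: at exact distance `d_new` in a uniform random
  direction (models daughters pushed to the colony edge),
- `gaussian(sigma_str)`: at independent per-axis Gaussian offsets with
  standard deviation `sigma_str` (models streaming/mixing; larger
  `sigma_str` spreads lineages over the substrate).

Termination is one of `max_time` (default 240 min; the step that would
exceed the bound is not taken), `full_induction`, or `max_cells`.

### 1.5 Induction cascade

After every division (and once at `t = 0` for the seed configuration)
all perceived concentrations are updated and every non-induced cell
with `C_i ≥ beta_thr` (inclusive) induces. Because induced cells emit
`1 + eta`, new inductions can push further cells over threshold; the
check is iterated in synchronous sweeps until no new cell crosses.
Induction is irreversible.

The sweep operator is monotone (concentrations only increase as cells
induce), so the iteration converges to the *least* fixed point above
the current state, which is unique and independent of update order.
The test suite verifies this against an exhaustive enumeration of all
2ⁿ induction sets (n ≤ 12) and against a randomized one-at-a-time
(asynchronous) cascade on colonies up to 200 cells.

`beta_thr` is expressed in touching-cell units: the default 30 means
"the combined contact-level contribution of 30 touching cells".

### 1.6 Observables

- **First-induction time** (MFPT analog): clock time of the first
  cascade; ensemble mean ± sample SD (ddof = 1) over replicates.
  Replicates that never induce are censored and reported as a count —
  they are never silently dropped into the mean.
- **IT_χ**: first time the induced fraction `chi` reaches a given
  level (0.25/0.5/0.75 by default).
- **Bursts**: step `t` is flagged when its cascade size `k_t` exceeds
  the running mean of the `k` history since the last burst by 8 SD
  (population SD with a floor `s_min = 1`, at least 5 steps of history
  required; the history resets after each flag). The 8-SD rule
  separates avalanche-like collective inductions from the steady
  trickle of single inductions.
- **Relative burst size** `zeta`: size of the very first cascade
  divided by the colony size at that moment (single-seed colonies).
  `zeta(eta)` rises sigmoidally from ≈ 0 to ≈ 1 — a percolation-like
  transition in the feedback strength.
- **Lineage/cluster statistics**: per-family sizes and induced
  fractions; radius and size of the first-induced lineage cluster.
- **Static ensembles**: colony-mean perceived concentration of seed
  configurations without growth, versus `alpha` (mean and sample
  variance across configurations).

## 2. Parameters, units, defaults

| name          | unit   | default | meaning                                   |
|---------------|--------|---------|-------------------------------------------|
| `alpha`       | 1/µm²  | —       | `delta/D`; inverse squared signal range    |
| `r_c`         | µm     | 2.5     | cell radius; contact distance `2·r_c`      |
| `R`           | µm     | 100     | seeding disk radius                        |
| `rho`         | 1/µm²  | 0.0025  | seed density                               |
| `gamma`       | 1/min  | 1/60    | division rate                              |
| `phi`         | —      | 1       | basal emission (scale of one cell)         |
| `eta`         | —      | 0       | surplus emission of induced cells          |
| `beta_thr`    | —      | 30      | threshold in touching-cell units           |
| `d_new`       | µm     | —       | fixed daughter distance (scenario A)       |
| `sigma_str`   | µm     | —       | Gaussian per-axis spread (scenario B)      |

Exactly one of `d_new`/`sigma_str` must be given. `D` and `delta` may
be supplied instead of (or alongside) `alpha`; consistency is checked.
All parameters live in a frozen `SimulationParams`; `validate_params`
builds one from a plain dict (or YAML via the CLI) and rejects unknown
keys.

## 3. Reproducibility and RNG contract

Each replicate uses exactly one `numpy.random.default_rng(rng_seed)`.
Draw order is fixed: Poisson seed count, seed radii, seed angles, then
per division step the mother index followed by the placement draws.
No draw depends on the induction state, so at a fixed seed the colony
geometry — and hence the first-induction time — is **bit-identical**
across `eta` (induced cells do not change where cells are, only when
they induce). Replicate *i* of an ensemble uses `rng_seed + i`; sweep
grid point *g* additionally offsets by `g · 100003` so that no two grid
points share a replicate seed.

## 4. Numerical choices

- `scipy.special.k0` evaluates the field; it is cross-validated in the
  tests against an independent `quad` integration of the integral
  representation `K0(x) = ∫₀^∞ exp(-x·cosh t) dt` (cut off at
  `t = arccosh(745/x)` to stay in double range) at rel. tol 1e-10.
- Perceived concentrations are maintained **incrementally**: adding a
  cell or inducing a set of cells updates all cached values in O(n),
  making a full run O(N²) instead of O(N³). A from-scratch O(n²)
  oracle (`perceived_concentration`) is kept for validation; cache and
  oracle agree to 1e-12 in the tests.
- Threshold comparison is inclusive (`≥`), applied to the cached
  concentrations; the cascade mutates the colony only through
  `induce`, which is also where the `eta` surplus enters the cache.
- Percent-decay distances use `brentq` with geometric bracketing,
  rtol 1e-10.
- Default problem sizes (240 min at `gamma = 1/60` from ≈ 78 seeds →
  ≈ 4000–5000 cells) run in seconds on one CPU; the slowest regime
  exercised by the tests (`sigma_str = 100` µm, long runs to ≈ 270 min)
  stays under a minute per 20-replicate ensemble.

## 5. Validation strategy

Every nontrivial computation has an independent second route:

1. field: `scipy.special.k0` vs direct quadrature of the integral
   representation;
2. perceived concentration: incremental cache vs from-scratch
   superposition (n up to 500);
3. cascade: synchronous fixed point vs exhaustive 2ⁿ closure (n ≤ 12)
   and vs randomized asynchronous updates (n ≤ 200);
4. growth clock: simulated times vs the closed-form harmonic sum;
5. seeding: sample moments and isotropy vs analytic values
   (Poisson mean, `E[r] = 2R/3`, chi-square uniformity of angles);
6. end-to-end: ensemble orderings (first-induction time increases with
   `alpha`, with `sigma_str`, and for separated lineage grids; static
   mean concentration and its variance decrease with `alpha`) and the
   `zeta(eta)` phase transition, each over 15–20 replicates.

One design decision worth recording: lattice "randomization" during
growth is verified through the coefficient of variation of
nearest-neighbour distances (exactly 0 for the initial lattice,
> 0.5 after a few generations), not through the raw NN-distance
variance — the variance is not monotone because the mean NN distance
shrinks as the colony densifies.

## 6. Known limitations

- No volume exclusion or cell motility; positions are points and may
  overlap. The `r ≤ 2·r_c` truncation keeps overlapping contributions
  finite and at the contact level.
- The AI field is quasi-static: the steady-state profile is assumed to
  equilibrate instantly relative to the division timescale (valid when
  `D/L² ≫ gamma` for colony scale `L`).
- Division waiting times are deterministic mean-field increments, so
  population-size trajectories carry no demographic noise; only
  spatial randomness (seeding, mother choice, placement) fluctuates.
- Induction is a sharp, irreversible threshold — no gene-expression
  noise, delay, or reversal.
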