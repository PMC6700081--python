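import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import chisquare

from quorumsim import (
    PlacementScenario,
    Termination,
    division_step,
    first_induction_time,
    place_daughter,
    run_simulation,
    seed_grid,
    seed_poisson_disk,
)

from conftest import make_colony


class TestPoissonDiskSeeding:
    def test_mean_seed_count_matches_poisson_intensity(self, default_params):
        # empirical mean over 2000 draws within 3 standard errors of rho*pi*R^2
        rng = np.random.default_rng(0)
        counts = [seed_poisson_disk(default_params, rng).n for _ in range(2000)]
        mean = default_params.rho * np.pi * default_params.R**2  # ~78.5
        se = np.sqrt(mean / len(counts))
        assert abs(np.mean(counts) - mean) < 3 * se

    def test_zero_density_gives_empty_colony(self, default_params):
        p = default_params.replace(rho=0.0)
        col = seed_poisson_disk(p, np.random.default_rng(1))
        assert col.n == 0

    def test_seeds_uniform_in_disk(self, default_params):
        rng = np.random.default_rng(2)
        col = seed_poisson_disk(default_params.replace(rho=0.25), rng)
        r = np.hypot(col.x, col.y)
        assert r.max() <= default_params.R
        # area-uniform placement has E[r] = 2R/3
        se = default_params.R * 0.25 / np.sqrt(col.n)
        assert abs(r.mean() - 2 * default_params.R / 3) < 4 * se

    def test_distinct_lineages(self, default_params):
        col = seed_poisson_disk(default_params, np.random.default_rng(3))
        assert len(set(col.lineage)) == col.n


class TestGridSeeding:
    def test_lattice_spacing_exact(self, default_params):
        col = seed_grid(100, 200.0, params=default_params)
        assert col.n == 100
        tree = cKDTree(np.c_[col.x, col.y])
        d, _ = tree.query(np.c_[col.x, col.y], k=2)
        assert np.all(d[:, 1] == 200.0)

    def test_single_seed_at_origin(self, default_params):
        col = seed_grid(1, 200.0, params=default_params)
        assert col.n == 1
        assert col.x[0] == 0.0 and col.y[0] == 0.0

    def test_two_by_two_geometry(self, default_params):
        col = seed_grid(4, 10.0, params=default_params)
        d = np.hypot(
            col.x[:, None] - col.x[None, :], col.y[:, None] - col.y[None, :]
        )
        assert d.max() == pytest.approx(10.0 * np.sqrt(2))

    @pytest.mark.parametrize("n,spacing", [(5, 10.0), (100, 0.0), (0, 10.0)])
    def test_rejects_bad_grid(self, n, spacing, default_params):
        with pytest.raises(ValueError):
            seed_grid(n, spacing, params=default_params)


class TestPlacement:
    def test_fixed_mode_distance_exact_every_draw(self):
        rng = np.random.default_rng(4)
        sc = PlacementScenario.fixed(10.0)
        for _ in range(200):
            x, y = place_daughter((3.0, -2.0), sc, rng)
            assert np.hypot(x - 3.0, y + 2.0) == pytest.approx(10.0, rel=1e-14)

    @pytest.mark.parametrize(
        "sc", [PlacementScenario.fixed(0.0), PlacementScenario.gaussian(0.0)]
    )
    def test_zero_spread_coincides_with_mother(self, sc):
        rng = np.random.default_rng(5)
        assert place_daughter((1.0, 2.0), sc, rng) == (1.0, 2.0)

    def test_gaussian_mode_moments(self):
        rng = np.random.default_rng(6)
        sc = PlacementScenario.gaussian(20.0)
        pts = np.array([place_daughter((0.0, 0.0), sc, rng) for _ in range(20000)])
        n = pts.shape[0]
        # per-axis SD 20 within 3 SE; mean offset 0 within 3 SE
        se_sd = 20.0 / np.sqrt(2 * n)
        se_mean = 20.0 / np.sqrt(n)
        for axis in (0, 1):
            assert abs(pts[:, axis].std() - 20.0) < 3 * se_sd
            assert abs(pts[:, axis].mean()) < 3 * se_mean

    def test_fixed_mode_isotropy(self):
        rng = np.random.default_rng(7)
        sc = PlacementScenario.fixed(10.0)
        pts = np.array([place_daughter((0.0, 0.0), sc, rng) for _ in range(100000)])
        angles = np.arctan2(pts[:, 1], pts[:, 0])
        counts, _ = np.histogram(angles, bins=36, range=(-np.pi, np.pi))
        assert chisquare(counts).pvalue > 0.001


class TestDivisionLoop:
    def test_time_increment_is_reciprocal_population(self, default_params):
        col = seed_grid(1, 10.0, params=default_params)
        for _ in range(77):
            col.add_cell(0.0, 0.0, 0)
        rng = np.random.default_rng(8)
        rec = division_step(col, default_params, rng)
        assert rec["t"] == pytest.approx(60.0 / 78.0)  # 1/(gamma*n), n = 78
        assert rec["n"] == 79

    def test_clock_equals_harmonic_sum(self, default_params):
        p = default_params.replace(termination=Termination.max_cells(300), beta_thr=1e9)
        res = run_simulation(p)
        n0 = res.log.n[0]
        expected = (1 / p.gamma) * np.sum(1.0 / np.arange(n0, res.colony.n))
        assert res.colony.t == pytest.approx(expected, rel=1e-12)

    def test_cell_count_increments_once_per_step(self, default_params):
        p = default_params.replace(termination=Termination.max_cells(150))
        res = run_simulation(p)
        n = np.asarray(res.log.n)
        assert np.all(np.diff(n) == 1)
        assert res.colony.step == len(res.log) - 1  # minus the t=0 row

    def test_lineages_partition_the_colony(self, default_params):
        p = default_params.replace(termination=Termination.max_cells(250))
        res = run_simulation(p)
        seeds = res.log.n[0]
        labels, sizes = np.unique(res.colony.lineage, return_counts=True)
        assert len(labels) == seeds
        assert sizes.sum() == res.colony.n


class TestRunSimulation:
    def test_bit_identical_logs_for_identical_params(self, default_params):
        p = default_params.replace(termination=Termination.max_cells(200))
        a = run_simulation(p)
        b = run_simulation(p)
        for fieldname in ("t", "k_t", "chi", "c_bar", "mother_id", "daughter_id"):
            assert getattr(a.log, fieldname) == getattr(b.log, fieldname)
        np.testing.assert_array_equal(a.colony.x, b.colony.x)

    def test_first_induction_time_independent_of_eta(self, default_params):
        times = []
        for eta in (0.0, 1.0, 3.0):
            p = default_params.replace(eta=eta, rng_seed=42)
            res = run_simulation(p, stop_after_first_induction=True)
            times.append(first_induction_time(res.log))
        assert times[0] == times[1] == times[2]  # bit-identical

    def test_max_cells_termination(self, default_params):
        p = default_params.replace(termination=Termination.max_cells(120))
        res = run_simulation(p)
        assert res.colony.n == max(120, res.log.n[0])

    def test_max_time_never_exceeded(self, default_params):
        p = default_params.replace(termination=Termination.max_time(30.0))
        res = run_simulation(p)
        assert res.colony.t <= 30.0

    def test_full_induction_termination(self, default_params):
        p = default_params.replace(
            termination=Termination("full_induction"),
            beta_thr=2.0,
            eta=3.0,
            alpha=0.01,
            rho=0.01,
            R=30.0,
        )
        res = run_simulation(p)
        assert res.colony.chi == 1.0

    def test_super_threshold_seed_configuration_inducts_at_time_zero(self, default_params):
        pair = make_colony([0.0, 5.0], [0.0, 0.0], alpha=0.05, eta=1.0)
        p = default_params.replace(beta_thr=2.0, termination=Termination.max_cells(3))
        res = run_simulation(p, initial_colony=pair)
        assert first_induction_time(res.log) == 0.0

    def test_empty_colony_terminates_immediately(self, default_params):
        p = default_params.replace(rho=0.0)
        res = run_simulation(p)
        assert res.colony.n == 0
        assert len(res.log) == 0

    def test_snapshots_taken_at_requested_times(self, default_params):
        p = default_params.replace(termination=Termination.max_time(40.0))
        res = run_simulation(p, snapshot_times=(10.0, 20.0))
        assert set(res.snapshots) == {10.0, 20.0}
        assert res.snapshots[10.0].n <= res.snapshots[20.0].n

    def test_grid_seeding_randomizes_under_gaussian_spread(self, default_params):
        # regular seeds lose their lattice order: nearest-neighbour-distance
        # variance grows over the first generations of growth
        p = default_params.replace(
            seeding="grid",
            grid_n=25,
            grid_spacing=50.0,
            placement=PlacementScenario.gaussian(5.0),
            beta_thr=1e9,
            rng_seed=3,
        )
        cvs = []
        for factor in (1, 2, 4, 8):
            q = p.replace(termination=Termination.max_cells(25 * factor))
            res = run_simulation(q)
            pts = np.c_[res.colony.x, res.colony.y]
            d, _ = cKDTree(pts).query(pts, k=2)
            nn = d[:, 1]
            cvs.append(nn.std() / nn.mean())
        # perfect lattice: zero dispersion; after growth the relative
        # spread of nearest-neighbour distances is large and stays large
        assert cvs[0] == 0.0
        assert all(cv > 0.5 for cv in cvs[1:])
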