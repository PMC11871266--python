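import numpy as np
import pytest
from scipy import stats

from ventcausal.grid import optimal_threshold_path
from ventcausal.trajectory import (TrajectoryConfig, simulate_trajectory,
                                   trajectory_report)

from test_grid import make_grid


@pytest.fixture
def random_grid():
    rng = np.random.default_rng(3)
    return make_grid(rng.standard_normal((40, 20)),
                     thresholds=[float(t) for t in range(2, 42, 2)])


class TestSimulateTrajectory:
    def test_no_noise_reproduces_argmin_path(self, random_grid):
        cfg = TrajectoryConfig(initial_mp=40.0, noise_level=0.0,
                               horizon_hours=40, seed=0)
        res = simulate_trajectory(random_grid, cfg)
        path = optimal_threshold_path(random_grid)
        t = res.table
        assert (t["realized_mp"] == t["ideal_mp"]).all()
        assert not t["was_perturbed"].any()
        np.testing.assert_allclose(t["ideal_mp"].iloc[1:], path[1:40])
        assert t["ideal_mp"].iloc[0] == 40.0

    def test_perturbed_fraction_binomial(self):
        rng = np.random.default_rng(9)
        long_grid = make_grid(rng.standard_normal((1000, 15)),
                              thresholds=[float(t) for t in range(5, 35, 2)])
        cfg = TrajectoryConfig(initial_mp=20.0, noise_level=0.4,
                               horizon_hours=1000, perturbation_range=(5, 34),
                               seed=4)
        res = simulate_trajectory(long_grid, cfg)
        k = int(res.table["was_perturbed"].sum())
        n_trials = 999   # hour 0 is never perturbed
        lo = stats.binom.ppf(0.005, n_trials, 0.4)
        hi = stats.binom.ppf(0.995, n_trials, 0.4)
        assert lo <= k <= hi

    def test_forced_perturbation_degenerate_range(self, random_grid):
        cfg = TrajectoryConfig(initial_mp=20.0, noise_level=1.0,
                               horizon_hours=30, perturbation_range=(18.0, 18.0),
                               seed=1)
        res = simulate_trajectory(random_grid, cfg)
        assert (res.table["realized_mp"].iloc[1:] == 18.0).all()

    def test_horizon_exceeding_grid(self, random_grid):
        with pytest.raises(ValueError, match="horizon"):
            simulate_trajectory(random_grid,
                                TrajectoryConfig(horizon_hours=41, seed=0))

    def test_initial_mp_snapped_and_logged(self, random_grid):
        cfg = TrajectoryConfig(initial_mp=7.3, noise_level=0.0,
                               horizon_hours=5, seed=0)
        res = simulate_trajectory(random_grid, cfg)
        assert res.table["ideal_mp"].iloc[0] in random_grid.thresholds
        assert any("snapped" in w for w in res.warnings)

    def test_undefined_hour_carried_forward(self):
        mask = np.zeros((4, 3), bool)
        mask[2, :] = True
        g = make_grid(np.ones((4, 3)), mask=mask, thresholds=[10., 20., 30.])
        res = simulate_trajectory(g, TrajectoryConfig(
            initial_mp=30.0, noise_level=0.0, horizon_hours=4, seed=0))
        t = res.table
        assert t["ideal_mp"].iloc[2] == t["ideal_mp"].iloc[1]
        assert any("carried forward" in w for w in res.warnings)

    def test_seed_changes_only_perturbed_hours(self, random_grid):
        cfg_a = TrajectoryConfig(initial_mp=20.0, noise_level=0.3,
                                 horizon_hours=40, seed=10)
        cfg_b = TrajectoryConfig(initial_mp=20.0, noise_level=0.3,
                                 horizon_hours=40, seed=11)
        ta = simulate_trajectory(random_grid, cfg_a).table
        tb = simulate_trajectory(random_grid, cfg_b).table
        same_ideal = (ta["ideal_mp"] == tb["ideal_mp"]).all()
        assert same_ideal
        differs = ta["realized_mp"] != tb["realized_mp"]
        assert (ta["was_perturbed"] | tb["was_perturbed"])[differs].all()

    def test_ideal_path_beats_fixed_mp_paths(self):
        # per-hour argmin implies cumulative optimality on injury surfaces
        rng = np.random.default_rng(21)
        for _ in range(20):
            g = make_grid(rng.standard_normal((15, 8)),
                          thresholds=[float(t) for t in range(10, 26, 2)])
            path = optimal_threshold_path(g)
            ideal_sum = sum(g.estimates[i, g.thresholds.index(path[i])]
                            for i in range(15))
            for j in range(8):
                fixed_sum = g.estimates[:, j].sum()
                assert ideal_sum <= fixed_sum + 1e-12


class TestTrajectoryReport:
    def test_zero_surface_zero_cumulative(self):
        g = make_grid(np.zeros((10, 4)), thresholds=[10., 20., 30., 40.])
        res = simulate_trajectory(g, TrajectoryConfig(
            initial_mp=10.0, noise_level=0.0, horizon_hours=10, seed=0))
        rep = trajectory_report(res)
        assert rep["cumulative_cate"] == 0.0

    def test_single_hour_summary(self):
        g = make_grid(np.full((1, 2), 1.5), thresholds=[10., 20.])
        res = simulate_trajectory(g, TrajectoryConfig(
            initial_mp=10.0, noise_level=0.0, horizon_hours=1, seed=0))
        rep = trajectory_report(res)
        assert rep["n_hours"] == 1
        assert rep["cumulative_cate"] == pytest.approx(1.5)

    def test_cumulative_matches_summation_oracle(self, random_grid=None):
        rng = np.random.default_rng(2)
        g = make_grid(rng.standard_normal((20, 6)),
                      thresholds=[float(t) for t in range(10, 22, 2)])
        res = simulate_trajectory(g, TrajectoryConfig(
            initial_mp=14.0, noise_level=0.5, horizon_hours=20, seed=8))
        rep = trajectory_report(res)
        manual = sum(v for v in res.table["cate_at_realized"] if not np.isnan(v))
        assert rep["cumulative_cate"] == pytest.approx(manual)
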