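import numpy as np
import pytest

import ventcausal as vc
from ventcausal.grid import (CATEGrid, fit_grid, grid_from_long_frame,
                             grid_to_long_frame, optimal_threshold_path,
                             read_grid, write_grid)
from ventcausal.synthetic import SimConfig


def make_grid(estimates, thresholds=None, hours=None, mask=None):
    est = np.asarray(estimates, dtype=float)
    hours = tuple(range(est.shape[0])) if hours is None else tuple(hours)
    thresholds = tuple(map(float, range(est.shape[1]))) \
        if thresholds is None else tuple(thresholds)
    mask = np.zeros(est.shape, bool) if mask is None else np.asarray(mask)
    est = est.copy()
    est[mask] = np.nan
    return CATEGrid(cohort="all", hours=hours, thresholds=thresholds,
                    estimates=est, se=np.full(est.shape, 0.1),
                    mask=mask, n_matrix=np.full(est.shape, 100))


@pytest.fixture(scope="module")
def step_cohort():
    return vc.generate_cohort(SimConfig(
        n_admissions=800, seed=41, mp_threshold_true=17.0, true_pf_effect=-1.5))


@pytest.fixture(scope="module")
def step_grid(step_cohort):
    return fit_grid(step_cohort.hourly, step_cohort.admissions,
                    hours=range(0, 24, 2), thresholds=range(8, 31, 2),
                    min_cell_n=40, seed=0)


class TestFitGrid:
    def test_shape_and_masking_contract(self, step_grid):
        assert step_grid.estimates.shape == (12, 12)
        assert np.all(np.isnan(step_grid.estimates[step_grid.mask]))
        unmasked_n = step_grid.n_matrix[~step_grid.mask]
        assert (unmasked_n >= 2 * 40).all()   # both arms meet the cell minimum

    def test_change_point_visible(self, step_grid):
        # cells at/above the true 17 J/min threshold see the harmful hinge
        thr = np.asarray(step_grid.thresholds)
        ok = ~step_grid.mask
        hi = step_grid.estimates[:, thr >= 17][ok[:, thr >= 17]]
        lo = step_grid.estimates[:, thr < 17][ok[:, thr < 17]]
        assert hi.size and lo.size
        assert hi.mean() < lo.mean() < 0.5   # hinge leaks into low cells too

    def test_full_grid_shape_default(self, step_cohort):
        g = fit_grid(step_cohort.hourly, step_cohort.admissions,
                     hours=range(41), thresholds=range(41), min_cell_n=40)
        assert g.estimates.shape == (41, 41)

    def test_tiny_cohort_fully_masked(self, step_cohort):
        adm = step_cohort.admissions.head(10)
        h = step_cohort.hourly[
            step_cohort.hourly["admission_id"].isin(adm["admission_id"])]
        g = fit_grid(h, adm, hours=range(5), thresholds=range(10, 20),
                     min_cell_n=50)
        assert g.mask.all()

    def test_horizon_filter_error(self, step_cohort):
        with pytest.raises(ValueError, match="intubated"):
            fit_grid(step_cohort.hourly, step_cohort.admissions,
                     hours=range(5), thresholds=range(10, 20),
                     min_intubation_hours=10_000)

    def test_cell_independence(self, step_cohort):
        # a cell estimated alone equals the same cell inside a larger grid
        g_one = fit_grid(step_cohort.hourly, step_cohort.admissions,
                         hours=[6], thresholds=[18.0], min_cell_n=40,
                         min_intubation_hours=25)
        g_big = fit_grid(step_cohort.hourly, step_cohort.admissions,
                         hours=range(4, 10, 2), thresholds=[14.0, 18.0, 22.0],
                         min_cell_n=40, min_intubation_hours=25)
        i = g_big.hours.index(6)
        j = g_big.thresholds.index(18.0)
        assert g_one.estimates[0, 0] == pytest.approx(
            g_big.estimates[i, j], rel=1e-12)

    def test_null_effect_type_i_control(self):
        coh = vc.generate_cohort(SimConfig(n_admissions=600, seed=43,
                                           true_pf_effect=0.0))
        g = fit_grid(coh.hourly, coh.admissions, hours=range(0, 20, 2),
                     thresholds=range(10, 28, 2), min_cell_n=40)
        ok = ~g.mask
        z = np.abs(g.estimates[ok] / g.se[ok])
        assert (z > 2).mean() <= 0.10


class TestOptimalPath:
    def test_argmin_column(self):
        g = make_grid([[0.5, -0.2, -0.9, -0.1]], thresholds=[10., 20., 30., 40.])
        assert optimal_threshold_path(g)[0] == 30.0

    def test_tie_breaks_to_lowest_mp(self):
        g = make_grid([[0.0, -1.0, 0.2, -1.0, 0.4]],
                      thresholds=[5., 15., 20., 25., 35.])
        assert optimal_threshold_path(g)[0] == 15.0

    def test_masked_hour_undefined(self):
        g = make_grid([[1.0, 2.0], [3.0, 4.0]],
                      mask=np.array([[True, True], [False, False]]))
        path = optimal_threshold_path(g)
        assert np.isnan(path[0]) and path[1] == 0.0

    def test_matches_bruteforce_argmin_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            vals = rng.standard_normal((41, 41))
            mask = rng.random((41, 41)) < 0.2
            g = make_grid(vals, mask=mask)
            path = optimal_threshold_path(g)
            for i in range(41):
                cols = [(v, t) for t, (v, m) in
                        enumerate(zip(vals[i], mask[i])) if not m]
                if not cols:
                    assert np.isnan(path[i])
                else:
                    best = min(v for v, _ in cols)
                    expect = min(t for v, t in cols if v == best)
                    assert path[i] == float(expect)


class TestGridIO:
    def test_long_frame_round_trip(self, step_grid):
        frame = grid_to_long_frame(step_grid)
        back = grid_from_long_frame(frame)
        np.testing.assert_allclose(back.estimates, step_grid.estimates)
        assert (back.mask == step_grid.mask).all()
        assert (back.n_matrix == step_grid.n_matrix).all()

    def test_csv_round_trip(self, step_grid, tmp_path):
        p = tmp_path / "grid.csv"
        write_grid(step_grid, p, tmp_path / "dense.csv")
        back = read_grid(p)
        np.testing.assert_allclose(back.estimates, step_grid.estimates)
        assert back.hours == step_grid.hours
        assert back.thresholds == step_grid.thresholds
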