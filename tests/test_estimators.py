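import numpy as np
import pandas as pd
import pytest

import ventcausal as vc
from ventcausal.estimators import (DegenerateThresholdError, NoOverlapError,
                                   RankDeficientError, backdoor_linear_ate,
                                   binary_effect_at_threshold, build_design,
                                   cate_by_subgroup, dml_ate,
                                   estimates_to_frame)
from ventcausal.pipeline import build_admission_table
from ventcausal.synthetic import SimConfig

from conftest import make_linear_frame


def normal_equations_coef(y, X):
    """Independent textbook solve: beta = (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


ADJ = ["apache_ii", "age_band", "admission_type", "diagnosis_group"]


class TestBackdoorLinear:
    def test_matches_normal_equations_oracle(self):
        d = make_linear_frame(n=300, seed=1, effect=2.0)
        est = backdoor_linear_ate(d, "t", "y", ["x"], n_boot=50, seed=0)
        X = np.column_stack([np.ones(len(d)), d["t"], d["x"]])
        beta = normal_equations_coef(d["y"].to_numpy(), X)
        assert est.point == pytest.approx(beta[1], abs=1e-8)

    def test_matches_oracle_with_categoricals(self, analysis_table):
        est = backdoor_linear_ate(analysis_table, "mp_median", "vfd28", ADJ,
                                  n_boot=50, seed=0)
        Z, _ = build_design(analysis_table, ADJ)
        X = np.column_stack([np.ones(len(analysis_table)),
                             analysis_table["mp_median"].to_numpy(), Z])
        beta = normal_equations_coef(analysis_table["vfd28"].to_numpy(), X)
        assert est.point == pytest.approx(beta[1], abs=1e-8)

    def test_recovers_generator_truth(self):
        coh = vc.generate_cohort(SimConfig(n_admissions=5000, seed=17))
        tab = build_admission_table(coh.admissions, coh.hourly)
        est = backdoor_linear_ate(tab, "mp_median", "vfd28", ADJ,
                                  n_boot=200, seed=17)
        assert abs(est.point - (-0.15)) < 2 * est.se
        assert est.ci_low <= est.point <= est.ci_high

    def test_rank_deficiency_names_columns(self):
        d = make_linear_frame(n=100, seed=2)
        d["x_dup"] = d["x"]
        with pytest.raises(RankDeficientError, match="x"):
            backdoor_linear_ate(d, "t", "y", ["x", "x_dup"], n_boot=10, seed=0)

    def test_too_small_n(self):
        d = make_linear_frame(n=3, seed=3)
        with pytest.raises(ValueError, match="too small"):
            backdoor_linear_ate(d, "t", "y", ["x"], n_boot=10, seed=0)


class TestDML:
    def test_linear_dgp_recovery(self):
        coh = vc.generate_cohort(SimConfig(n_admissions=5000, seed=19))
        tab = build_admission_table(coh.admissions, coh.hourly)
        est = dml_ate(tab, "mp_median", "vfd28", ADJ, learner_kind="generic",
                      n_boot=100, seed=19)
        assert abs(est.point - (-0.15)) < 2 * est.se

    def test_converges_to_backdoor_on_linear_dgp(self):
        # partialling-out with linear learners targets the same estimand
        coh = vc.generate_cohort(SimConfig(n_admissions=8000, seed=23))
        tab = build_admission_table(coh.admissions, coh.hourly)
        lr = backdoor_linear_ate(tab, "mp_median", "vfd28", ADJ,
                                 n_boot=100, seed=23)
        dm = dml_ate(tab, "mp_median", "vfd28", ADJ, learner_kind="generic",
                     n_boot=100, seed=23)
        joint_se = np.hypot(lr.se, dm.se)
        assert abs(lr.point - dm.point) < 3 * joint_se

    def test_constant_outcome_gives_exact_zero(self):
        d = make_linear_frame(n=200, seed=4)
        d["y"] = 5.0
        est = dml_ate(d, "t", "y", ["x"], learner_kind="generic",
                      n_boot=50, seed=0)
        assert est.point == 0.0

    def test_no_overlap_error(self):
        d = make_linear_frame(n=200, seed=5)
        d["t"] = 3.0    # treatment constant: fully explained by confounders
        with pytest.raises(NoOverlapError):
            dml_ate(d, "t", "y", ["x"], learner_kind="generic",
                    n_boot=50, seed=0)

    def test_k_folds_validated(self):
        d = make_linear_frame(n=50, seed=6)
        with pytest.raises(ValueError, match="k_folds"):
            dml_ate(d, "t", "y", ["x"], k_folds=1, seed=0)

    def test_seeded_determinism(self, analysis_table):
        a = dml_ate(analysis_table, "mp_median", "vfd28", ADJ,
                    learner_kind="forest", n_boot=50, seed=5)
        b = dml_ate(analysis_table, "mp_median", "vfd28", ADJ,
                    learner_kind="forest", n_boot=50, seed=5)
        assert a.point == b.point and a.ci_low == b.ci_low


class TestCateBySubgroup:
    def test_single_group_equals_ate_bit_for_bit(self, analysis_table):
        d = analysis_table.copy()
        d["grp"] = "everyone"
        ate = backdoor_linear_ate(d, "mp_median", "vfd28", ADJ,
                                  n_boot=100, seed=9)
        cates = cate_by_subgroup(d, "grp", "mp_median", "vfd28", ADJ,
                                 n_boot=100, seed=9)
        assert len(cates) == 1
        assert cates[0].point == ate.point
        assert cates[0].ci_low == ate.ci_low and cates[0].ci_high == ate.ci_high

    def test_small_group_suppressed(self, analysis_table):
        d = analysis_table.copy()
        d["grp"] = np.where(np.arange(len(d)) < 30, "tiny", "rest")
        cates = cate_by_subgroup(d, "grp", "mp_median", "vfd28", ADJ,
                                 min_n=50, n_boot=50, seed=0)
        by = {e.subgroup: e for e in cates}
        assert by["tiny"].suppressed and np.isnan(by["tiny"].point)
        assert not by["rest"].suppressed

    def test_unknown_grouping_column(self, analysis_table):
        with pytest.raises(ValueError, match="grouping"):
            cate_by_subgroup(analysis_table, "nope", "mp_median", "vfd28", ADJ)


class TestBinaryThreshold:
    def test_step_effect_recovery(self):
        cfg = SimConfig(n_admissions=4000, seed=29, vfd_effect_mode="step",
                        true_ate_vfd=-2.0, mp_threshold_true=17.0)
        coh = vc.generate_cohort(cfg)
        tab = build_admission_table(coh.admissions, coh.hourly)
        est = binary_effect_at_threshold(tab, 17.0, "mp_median", "vfd28", ADJ,
                                         n_boot=200, seed=29)
        assert abs(est.point - (-2.0)) < 2 * est.se
        assert est.treatment_coding == "binary_threshold(17)"

    def test_degenerate_threshold(self, analysis_table):
        low = analysis_table["mp_median"].min() - 1
        with pytest.raises(DegenerateThresholdError):
            binary_effect_at_threshold(analysis_table, low, "mp_median",
                                       "vfd28", ADJ, seed=0)

    def test_coding_antisymmetry(self, analysis_table):
        d = analysis_table.copy()
        est = binary_effect_at_threshold(d, 17.0, "mp_median", "vfd28", ADJ,
                                         n_boot=50, seed=3)
        d["mp_neg"] = -d["mp_median"]
        # flipping the indicator: above(-mp, -17) = 1 - above(mp, 17) on
        # continuous data, so the OLS coefficient negates
        flipped = binary_effect_at_threshold(d, -17.0, "mp_neg", "vfd28", ADJ,
                                             n_boot=50, seed=3)
        assert flipped.point == pytest.approx(-est.point, abs=1e-10)


class TestPermutationNull:
    def test_permuted_treatment_drives_points_to_zero(self, analysis_table):
        rng = np.random.default_rng(1)
        d = analysis_table.copy()
        d["mp_perm"] = rng.permutation(d["mp_median"].to_numpy())
        for call in (
            lambda: backdoor_linear_ate(d, "mp_perm", "vfd28", ADJ,
                                        n_boot=100, seed=1),
            lambda: dml_ate(d, "mp_perm", "vfd28", ADJ, learner_kind="generic",
                            n_boot=100, seed=1),
        ):
            est = call()
            assert abs(est.point) < 2.5 * est.se


def test_estimates_frame_round_trip(analysis_table, tmp_path):
    ests = [backdoor_linear_ate(analysis_table, "mp_median", "vfd28", ADJ,
                                n_boot=20, seed=0)]
    frame = estimates_to_frame(ests)
    p = tmp_path / "est.csv"
    frame.to_csv(p, index=False)
    back = pd.read_csv(p)
    assert list(back.columns) == list(frame.columns)
    assert back["point"].iloc[0] == pytest.approx(ests[0].point)
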