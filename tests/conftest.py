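import numpy as np
import pandas as pd
import pytest

import ventcausal as vc
from ventcausal.pipeline import apply_inclusion, build_admission_table


@pytest.fixture(scope="session")
def small_cohort():
    """A modest linear cohort shared by read-only tests."""
    return vc.generate_cohort(vc.SimConfig(n_admissions=600, seed=11))


@pytest.fixture(scope="session")
def analysis_table(small_cohort):
    adm, hourly, _ = apply_inclusion(small_cohort.admissions, small_cohort.hourly)
    return build_admission_table(adm, hourly)


ADJUSTMENT = ["apache_ii", "age_band", "admission_type", "diagnosis_group"]


@pytest.fixture(scope="session")
def adjustment():
    return list(ADJUSTMENT)


@pytest.fixture
def confounder_triangle():
    """X -> T, X -> Y, T -> Y: the textbook backdoor case."""
    return vc.build_dag(
        nodes=[("X", True, "covariate"), ("T", True, "exposure"),
               ("Y", True, "outcome")],
        edges=[("X", "T"), ("X", "Y"), ("T", "Y")],
        exposure="T", outcome="Y")


def make_linear_frame(n=400, seed=0, effect=2.0):
    """Tiny fully-linear frame with one confounder, for closed-form checks."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    t = 0.8 * x + rng.standard_normal(n)
    y = effect * t + 1.5 * x + rng.standard_normal(n)
    return pd.DataFrame({"x": x, "t": t, "y": y})
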