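"""ATE/CATE estimation: backdoor linear regression and double machine learning.

Both estimators target the effect of a treatment column (continuous
mechanical power, or a binary above-threshold indicator) on an outcome
column, adjusting for a backdoor-valid covariate set.

``backdoor_linear_ate`` fits outcome ~ treatment + adjustment by least
squares on a design matrix built in-package (categoricals dummy-coded,
reference level dropped) and reads the treatment coefficient; its CI is an
admission-level nonparametric percentile bootstrap.

``dml_ate`` is cross-fitted partialling-out: admissions are split into K
folds, nuisance regressions E[Y|Z] and E[T|Z] are fit out-of-fold, and the
effect is the residual-on-residual slope

    theta = sum(rT * rY) / sum(rT**2)

over out-of-fold residuals.  Orthogonality to nuisance estimation error is
what lets flexible learners (tree ensembles) absorb nonlinear confounding
without biasing theta.  CIs come from the influence-function variance
(primary) and from a residual-pair bootstrap (reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .dag import AdjustmentSet

__all__ = [
    "EffectEstimate", "backdoor_linear_ate", "dml_ate", "cate_by_subgroup",
    "binary_effect_at_threshold", "build_design", "RankDeficientError",
    "NoOverlapError", "DegenerateThresholdError", "estimates_to_frame",
]

DEFAULT_MIN_CELL = 50


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


class NoOverlapError(ValueError):
    """Treatment is (numerically) fully explained by the confounders."""


class DegenerateThresholdError(ValueError):
    """A threshold leaves one treatment arm empty or below the minimum size."""


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with CI for an ATE or subgroup CATE."""

    estimand: str                 # "ATE" | "CATE"
    estimator_tag: str            # backdoor_lr | dml_forest | dml_generic
    treatment_var: str
    treatment_coding: str         # "continuous" | "binary_threshold(<theta>)"
    outcome_var: str
    subgroup: str
    point: float
    ci_low: float
    ci_high: float
    n: int
    adjustment_set: tuple = ()
    se: float = float("nan")
    suppressed: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.suppressed and not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _adjustment_columns(adjustment) -> list:
    if adjustment is None:
        return []
    if isinstance(adjustment, AdjustmentSet):
        return sorted(adjustment.variables)
    return list(adjustment)


def build_design(data: pd.DataFrame, columns) -> tuple[np.ndarray, list]:
    """Numeric design block for the given columns; categoricals dummy-coded."""
    if not columns:
        return np.empty((len(data), 0)), []
    blocks, names = [], []
    for col in columns:
        s = data[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            dummies = dummies[sorted(dummies.columns)]
            blocks.append(dummies.to_numpy())
            names.extend(dummies.columns)
        else:
            blocks.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
    return np.hstack(blocks), names


def _check_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = sla.qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
        bad = [names[p] for p in piv[np.sum(d > tol):]]
        raise RankDeficientError(f"collinear design columns: {sorted(bad)}")


def _ols_treatment_coef(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def backdoor_linear_ate(
    data: pd.DataFrame,
    treatment: str,
    outcome: str,
    adjustment,
    *,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    subgroup: str = "all",
    estimand: str = "ATE",
    treatment_coding: str = "continuous",
) -> EffectEstimate:
    """Backdoor-adjusted OLS treatment effect with bootstrap percentile CI."""
    adj_cols = _adjustment_columns(adjustment)
    d = data.dropna(subset=[treatment, outcome] + adj_cols)
    n = len(d)
    if n <= len(adj_cols) + 2:
        raise ValueError(f"n={n} too small for {len(adj_cols)} adjustment variables")
    Z, z_names = build_design(d, adj_cols)
    t = d[treatment].to_numpy(dtype=float)
    y = d[outcome].to_numpy(dtype=float)
    X = np.hstack([np.ones((n, 1)), t[:, None], Z])
    names = ["intercept", treatment] + z_names
    _check_rank(X, names)
    point = float(_ols_treatment_coef(y, X)[1])

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _ols_treatment_coef(y[idx], X[idx])[1]
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    lo, hi = min(lo, point), max(hi, point)
    return EffectEstimate(
        estimand=estimand, estimator_tag="backdoor_lr", treatment_var=treatment,
        treatment_coding=treatment_coding, outcome_var=outcome, subgroup=subgroup,
        point=point, ci_low=float(lo), ci_high=float(hi), n=n,
        adjustment_set=tuple(adj_cols), se=float(np.std(boots, ddof=1)),
        extras={"boot_ci": (float(lo), float(hi))},
    )


def _default_learner(learner_kind: str, seed: int):
    if learner_kind == "forest":
        return RandomForestRegressor(
            n_estimators=100, min_samples_leaf=10, max_features=0.8,
            random_state=seed, n_jobs=1)
    return LinearRegression()


def dml_ate(
    data: pd.DataFrame,
    treatment: str,
    outcome: str,
    adjustment,
    *,
    learner_kind: str = "forest",
    learner_factory=None,
    k_folds: int = 5,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    subgroup: str = "all",
    estimand: str = "ATE",
    treatment_coding: str = "continuous",
) -> EffectEstimate:
    """Cross-fitted partialling-out DML estimate of the treatment effect."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    adj_cols = _adjustment_columns(adjustment)
    d = data.dropna(subset=[treatment, outcome] + adj_cols)
    n = len(d)
    Z, _ = build_design(d, adj_cols)
    t = d[treatment].to_numpy(dtype=float)
    y = d[outcome].to_numpy(dtype=float)

    r_t = np.empty(n)
    r_y = np.empty(n)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**31))
    make = learner_factory or (lambda: _default_learner(learner_kind, seed % (2**31)))
    for train, test in kf.split(Z):
        if Z.shape[1] == 0:
            r_t[test] = t[test] - t[train].mean()
            r_y[test] = y[test] - y[train].mean()
            continue
        mt = make().fit(Z[train], t[train])
        my = make().fit(Z[train], y[train])
        r_t[test] = t[test] - mt.predict(Z[test])
        r_y[test] = y[test] - my.predict(Z[test])

    den = float(r_t @ r_t)
    if den <= 1e-10 * n * max(1.0, float(np.var(t))):
        raise NoOverlapError("treatment residual variance ~ 0: no overlap/variation")
    theta = float(r_t @ r_y) / den

    psi = r_t * (r_y - theta * r_t)
    var_if = float(np.mean(psi**2)) / (float(np.mean(r_t**2)) ** 2 * n)
    se = float(np.sqrt(var_if))
    zq = 1.959963984540054
    lo_if, hi_if = theta - zq * se, theta + zq * se

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bt, by = r_t[idx], r_y[idx]
        dd = float(bt @ bt)
        boots[b] = float(bt @ by) / dd if dd > 0 else theta
    blo, bhi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    tag = "dml_forest" if (learner_factory is None and learner_kind == "forest") \
        else "dml_generic"
    return EffectEstimate(
        estimand=estimand, estimator_tag=tag, treatment_var=treatment,
        treatment_coding=treatment_coding, outcome_var=outcome, subgroup=subgroup,
        point=theta, ci_low=float(min(lo_if, theta)), ci_high=float(max(hi_if, theta)),
        n=n, adjustment_set=tuple(adj_cols), se=se,
        extras={"if_ci": (float(lo_if), float(hi_if)),
                "boot_ci": (float(blo), float(bhi))},
    )


ESTIMATORS = {"backdoor_lr": backdoor_linear_ate, "dml_forest": dml_ate,
              "dml_generic": dml_ate}


def _run_estimator(tag: str, data, treatment, outcome, adjustment, seed,
                   n_boot, **kw) -> EffectEstimate:
    if tag == "backdoor_lr":
        return backdoor_linear_ate(data, treatment, outcome, adjustment,
                                   seed=seed, n_boot=n_boot, **kw)
    if tag in ("dml_forest", "dml_generic"):
        kind = "forest" if tag == "dml_forest" else "generic"
        return dml_ate(data, treatment, outcome, adjustment, learner_kind=kind,
                       seed=seed, n_boot=n_boot, **kw)
    raise ValueError(f"unknown estimator tag: {tag!r}")


def cate_by_subgroup(
    data: pd.DataFrame,
    grouping: str,
    treatment: str,
    outcome: str,
    adjustment,
    *,
    estimator: str = "backdoor_lr",
    min_n: int = DEFAULT_MIN_CELL,
    seed: int = 0,
    n_boot: int = 500,
    **kw,
) -> list:
    """One CATE per level of the grouping column; small groups suppressed."""
    if grouping not in data.columns:
        raise ValueError(f"unknown grouping column: {grouping!r}")
    out = []
    for label in sorted(data[grouping].dropna().unique()):
        sub = data[data[grouping] == label]
        if len(sub) < min_n:
            out.append(EffectEstimate(
                estimand="CATE", estimator_tag=estimator, treatment_var=treatment,
                treatment_coding=kw.get("treatment_coding", "continuous"),
                outcome_var=outcome, subgroup=str(label), point=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"), n=len(sub),
                adjustment_set=tuple(_adjustment_columns(adjustment)),
                suppressed=True))
            continue
        est = _run_estimator(estimator, sub, treatment, outcome, adjustment,
                             seed, n_boot, **kw)
        out.append(replace(est, estimand="CATE", subgroup=str(label)))
    return out


def binary_effect_at_threshold(
    data: pd.DataFrame,
    threshold: float,
    treatment: str,
    outcome: str,
    adjustment,
    *,
    estimator: str = "backdoor_lr",
    min_arm_n: int = DEFAULT_MIN_CELL,
    seed: int = 0,
    n_boot: int = 500,
    **kw,
) -> EffectEstimate:
    """Effect of being above vs at-or-below an MP threshold (days or P/F units)."""
    adj_cols = _adjustment_columns(adjustment)
    d = data.dropna(subset=[treatment, outcome] + adj_cols).copy()
    ind = (d[treatment] > threshold).astype(float)
    n_hi, n_lo = int(ind.sum()), int((1 - ind).sum())
    if n_hi < min_arm_n or n_lo < min_arm_n:
        raise DegenerateThresholdError(
            f"threshold {threshold}: arm sizes above={n_hi}, below={n_lo} "
            f"(minimum {min_arm_n} per arm)")
    tcol = f"_above_{threshold:g}"
    d[tcol] = ind
    est = _run_estimator(estimator, d, tcol, outcome, adjustment, seed, n_boot, **kw)
    return replace(est, treatment_var=treatment,
                   treatment_coding=f"binary_threshold({threshold:g})")


ESTIMATE_COLUMNS = [
    "estimand", "estimator_tag", "treatment_var", "treatment_coding",
    "outcome_var", "subgroup", "point", "ci_low", "ci_high", "se", "n",
    "adjustment_set", "suppressed",
]


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Tidy one-row-per-estimate table with a documented, stable column order."""
    rows = []
    for e in estimates:
        rows.append({
            "estimand": e.estimand, "estimator_tag": e.estimator_tag,
            "treatment_var": e.treatment_var, "treatment_coding": e.treatment_coding,
            "outcome_var": e.outcome_var, "subgroup": e.subgroup, "point": e.point,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "se": e.se, "n": e.n,
            "adjustment_set": "|".join(e.adjustment_set), "suppressed": e.suppressed,
        })
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
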