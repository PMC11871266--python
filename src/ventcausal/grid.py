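"""Hour × MP-threshold CATE surface and its optimal-threshold path.

For each post-intubation hour h and candidate threshold theta, one model
estimates the effect of ventilating above vs at-or-below theta J/min at
hour h on next-interval oxygenation (P/F at h+lead), adjusting for the
previous hour's observed state (labs, vitals, prior P/F) plus admission
covariates.  Each cell is an independent binary-treatment regression;
cells whose treatment arms fall below the minimum size are masked rather
than reported as zeros.  Stacked over a 0-40 h × 0-40 J/min lattice this
yields the per-cohort effect heatmaps, and the per-hour argmin over
unmasked cells traces the least-injury ("optimal MP") trajectory, ties
broken toward the lowest MP (least-energy principle).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import mechanics
from .estimators import build_design

__all__ = ["CATEGrid", "fit_grid", "optimal_threshold_path",
           "grid_to_long_frame", "grid_from_long_frame"]

DEFAULT_HOURS = tuple(range(41))
DEFAULT_THRESHOLDS = tuple(float(t) for t in range(41))
HOURLY_COVARIATES = ("wbc", "temperature", "ph", "map", "paco2")


@dataclass
class CATEGrid:
    """Effect surface over (hour, threshold) with suppression mask and cell n."""

    cohort: str
    hours: tuple
    thresholds: tuple
    estimates: np.ndarray       # hours x thresholds, NaN where masked
    se: np.ndarray
    mask: np.ndarray            # True = suppressed
    n_matrix: np.ndarray
    estimator_tag: str = "ols_binary"
    seed: int = 0
    min_cell_n: int = 50

    def __post_init__(self) -> None:
        shape = (len(self.hours), len(self.thresholds))
        for name in ("estimates", "se", "mask", "n_matrix"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if not np.all(np.isnan(self.estimates[self.mask])):
            raise ValueError("masked cells must carry no estimate")


def _cell_ols(y: np.ndarray, t: np.ndarray, Z: np.ndarray) -> tuple[float, float]:
    """Treatment coefficient and its classical SE for one grid cell."""
    n = len(y)
    X = np.hstack([np.ones((n, 1)), t[:, None], Z])
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = n - X.shape[1]
    if dof <= 0 or rank < X.shape[1]:
        return float(beta[1]), float("nan")
    resid = y - X @ beta
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    return float(beta[1]), float(np.sqrt(s2 * xtx_inv[1, 1]))


def fit_grid(
    hourly: pd.DataFrame,
    admissions: pd.DataFrame,
    *,
    cohort: str = "all",
    cohort_column: str | None = None,
    hours=DEFAULT_HOURS,
    thresholds=DEFAULT_THRESHOLDS,
    outcome_lead: int = 1,
    min_cell_n: int = 50,
    min_intubation_hours: int | None = None,
    adjustment_admission=("apache_ii", "age_band", "admission_type"),
    seed: int = 0,
) -> CATEGrid:
    """Fit one binary-effect model per (hour, threshold) cell.

    ``cohort``/``cohort_column`` restrict admissions to a subgroup (e.g.
    ``cohort_column='admission_type', cohort='medical'``).  Admissions are
    further restricted to those intubated at least ``min_intubation_hours``
    (default: long enough to cover the grid horizon plus the outcome lead),
    so every cell sees the same admission population.
    """
    hours = tuple(int(h) for h in hours)
    thresholds = tuple(float(t) for t in thresholds)
    adm = admissions
    if cohort_column is not None and cohort != "all":
        adm = adm[adm[cohort_column] == cohort]
    horizon = max(hours) + outcome_lead
    if min_intubation_hours is None:
        min_intubation_hours = horizon + 1
    adm = adm[adm["intubation_duration_hours"] >= min_intubation_hours]
    if adm.empty:
        raise ValueError(
            f"no admissions intubated >= {min_intubation_hours} h in cohort {cohort!r}")
    ids = set(adm["admission_id"])
    h = hourly[hourly["admission_id"].isin(ids)].copy()
    h["mp"] = mechanics.hourly_mp(h)
    pivots = {
        col: h.pivot_table(index="admission_id", columns="hour", values=col,
                           aggfunc="first")
        for col in ("mp", "pao2", "fio2", *HOURLY_COVARIATES)
    }
    pf = pivots["pao2"] / pivots["fio2"]
    adm_idx = adm.set_index("admission_id").loc[pivots["mp"].index]
    Z_adm, _ = build_design(adm_idx.reset_index(), list(adjustment_admission))

    shape = (len(hours), len(thresholds))
    est = np.full(shape, np.nan)
    se = np.full(shape, np.nan)
    mask = np.ones(shape, dtype=bool)
    n_mat = np.zeros(shape, dtype=int)

    for i, hr in enumerate(hours):
        prev = max(hr - 1, 0)
        cols = {"t_mp": pivots["mp"].get(hr), "y_pf": pf.get(hr + outcome_lead),
                "pf_prev": pf.get(prev)}
        for c in HOURLY_COVARIATES:
            cols[c] = pivots[c].get(prev)
        if any(v is None for v in cols.values()):
            continue
        frame = pd.DataFrame(cols).dropna()
        if frame.empty:
            continue
        Zrows = Z_adm[pivots["mp"].index.get_indexer(frame.index)]
        Z = np.hstack([Zrows, frame[["pf_prev", *HOURLY_COVARIATES]].to_numpy()])
        mp_col = frame["t_mp"].to_numpy()
        y = frame["y_pf"].to_numpy()
        for j, theta in enumerate(thresholds):
            t = (mp_col > theta).astype(float)
            n_hi = int(t.sum())
            n_lo = len(t) - n_hi
            n_mat[i, j] = len(t)
            if n_hi < min_cell_n or n_lo < min_cell_n:
                continue
            point, cell_se = _cell_ols(y, t, Z)
            est[i, j] = point
            se[i, j] = cell_se
            mask[i, j] = False

    return CATEGrid(cohort=cohort, hours=hours, thresholds=thresholds,
                    estimates=est, se=se, mask=mask, n_matrix=n_mat,
                    estimator_tag="ols_binary", seed=seed, min_cell_n=min_cell_n)


def optimal_threshold_path(grid: CATEGrid) -> np.ndarray:
    """Per-hour threshold minimising the estimated effect (lowest-MP tie-break).

    Hours whose cells are all masked yield NaN (undefined), not an error.
    Minimising the effect on injury-sign surfaces selects the least-injury
    setting; ties go to the lowest MP so no excess energy is delivered.
    """
    thr = np.asarray(grid.thresholds, dtype=float)
    path = np.full(len(grid.hours), np.nan)
    for i in range(len(grid.hours)):
        col = grid.estimates[i]
        ok = ~grid.mask[i]
        if not ok.any():
            continue
        vals = col[ok]
        cand = thr[ok]
        best = np.min(vals)
        path[i] = cand[vals == best].min()
    return path


LONG_COLUMNS = ["cohort", "hour", "threshold", "estimate", "ci_low", "ci_high",
                "se", "n", "masked"]
_Z95 = 1.959963984540054


def grid_to_long_frame(grid: CATEGrid) -> pd.DataFrame:
    """Lossless long-format export (one row per cell; masked rows carry NaN)."""
    rows = []
    for i, hr in enumerate(grid.hours):
        for j, th in enumerate(grid.thresholds):
            e, s = grid.estimates[i, j], grid.se[i, j]
            rows.append({
                "cohort": grid.cohort, "hour": hr, "threshold": th,
                "estimate": e, "ci_low": e - _Z95 * s, "ci_high": e + _Z95 * s,
                "se": s, "n": grid.n_matrix[i, j], "masked": bool(grid.mask[i, j]),
            })
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def grid_from_long_frame(frame: pd.DataFrame, *, estimator_tag: str = "ols_binary",
                         seed: int = 0, min_cell_n: int = 50) -> CATEGrid:
    """Rebuild a :class:`CATEGrid` from its long-format export."""
    hours = tuple(sorted(frame["hour"].unique()))
    thresholds = tuple(sorted(frame["threshold"].unique()))
    shape = (len(hours), len(thresholds))
    est = np.full(shape, np.nan)
    se = np.full(shape, np.nan)
    mask = np.ones(shape, dtype=bool)
    n_mat = np.zeros(shape, dtype=int)
    hi = {h: i for i, h in enumerate(hours)}
    ti = {t: j for j, t in enumerate(thresholds)}
    for _, row in frame.iterrows():
        i, j = hi[row["hour"]], ti[row["threshold"]]
        n_mat[i, j] = int(row["n"])
        if not row["masked"]:
            est[i, j] = row["estimate"]
            se[i, j] = row["se"]
            mask[i, j] = False
    cohort = str(frame["cohort"].iloc[0]) if len(frame) else "all"
    return CATEGrid(cohort=cohort, hours=hours, thresholds=thresholds,
                    estimates=est, se=se, mask=mask, n_matrix=n_mat,
                    estimator_tag=estimator_tag, seed=seed, min_cell_n=min_cell_n)


def write_grid(grid: CATEGrid, long_path, matrix_path=None) -> None:
    """Write the long CSV and, optionally, the dense estimate matrix CSV."""
    grid_to_long_frame(grid).to_csv(long_path, index=False)
    if matrix_path is not None:
        dense = pd.DataFrame(grid.estimates, index=list(grid.hours),
                             columns=[f"{t:g}" for t in grid.thresholds])
        dense.index.name = "hour"
        dense.to_csv(matrix_path)


def read_grid(long_path, **kw) -> CATEGrid:
    return grid_from_long_frame(pd.read_csv(Path(long_path)), **kw)
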