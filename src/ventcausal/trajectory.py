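"""Counterfactual MP-trajectory simulation over a fitted CATE surface.

Starting from a chosen initial mechanical power, the simulator follows the
per-hour optimal (least-injury) MP given by the grid's argmin path, while
at each hour an independent clinical disturbance replaces the setting with
a uniform draw from a predefined range with probability ``noise_level`` —
emulating unplanned events (suctioning, agitation, transport) that knock
ventilator settings off target.  The realized path's cumulative effect is
read off the surface, quantifying the oxygenation cost of the disturbances
relative to the ideal trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CATEGrid, optimal_threshold_path

__all__ = ["TrajectoryConfig", "TrajectoryResult", "simulate_trajectory",
           "trajectory_report"]


@dataclass(frozen=True)
class TrajectoryConfig:
    initial_mp: float = 40.0
    noise_level: float = 0.0
    horizon_hours: int = 40
    perturbation_range: tuple = (5.0, 40.0)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise_level must lie in [0, 1]")
        lo, hi = self.perturbation_range
        if not lo < hi and not (self.noise_level in (0.0, 1.0) and lo == hi):
            raise ValueError("perturbation_range must satisfy low < high")
        if self.horizon_hours < 1:
            raise ValueError("horizon_hours must be >= 1")


@dataclass
class TrajectoryResult:
    """Per-hour ideal vs realized MP with the surface effect at the realized value."""

    table: pd.DataFrame            # hour, ideal_mp, realized_mp, was_perturbed, cate_at_realized
    config: TrajectoryConfig
    seed: int
    warnings: list = field(default_factory=list)


def _snap(value: float, axis: np.ndarray) -> float:
    return float(axis[np.argmin(np.abs(axis - value))])


def simulate_trajectory(grid: CATEGrid, config: TrajectoryConfig) -> TrajectoryResult:
    """Follow the optimal path under i.i.d. per-hour perturbations.

    Hour 0 realizes the configured initial MP (snapped to the threshold
    axis); later hours realize the path's ideal value unless perturbed.
    Hours where the path is undefined carry the previous ideal value
    forward, with a logged warning.  Deterministic given the config seed.
    """
    config.validate()
    axis = np.asarray(grid.thresholds, dtype=float)
    path = optimal_threshold_path(grid)
    if config.horizon_hours > len(grid.hours):
        raise ValueError(
            f"horizon {config.horizon_hours} exceeds grid hours ({len(grid.hours)})")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    warnings: list = []
    init = _snap(config.initial_mp, axis)
    if init != config.initial_mp:
        warnings.append(f"initial_mp {config.initial_mp} snapped to grid value {init}")

    rows = []
    prev_ideal = init
    for hr in range(config.horizon_hours):
        if hr == 0:
            ideal = init
        elif np.isnan(path[hr]):
            ideal = prev_ideal
            warnings.append(f"hour {hr}: optimal path undefined, carried forward")
        else:
            ideal = float(path[hr])
        perturbed = bool(rng.random() < config.noise_level) if hr > 0 else False
        if perturbed:
            lo, hi = config.perturbation_range
            realized = _snap(float(rng.uniform(lo, hi)), axis)
        else:
            realized = ideal
        j = int(np.argmin(np.abs(axis - realized)))
        i = min(hr, len(grid.hours) - 1)
        cate = float(grid.estimates[i, j]) if not grid.mask[i, j] else float("nan")
        rows.append({"hour": hr, "ideal_mp": ideal, "realized_mp": realized,
                     "was_perturbed": perturbed, "cate_at_realized": cate})
        prev_ideal = ideal
    table = pd.DataFrame(rows, columns=["hour", "ideal_mp", "realized_mp",
                                        "was_perturbed", "cate_at_realized"])
    return TrajectoryResult(table=table, config=config, seed=config.seed,
                            warnings=warnings)


def trajectory_report(result: TrajectoryResult) -> dict:
    """Cumulative effect along the realized path plus perturbation accounting.

    The per-hour table is suitable for heatmap overlays (ideal hours plotted
    white, perturbed hours red, following the surface-plot legend).
    """
    t = result.table
    if t.empty:
        raise ValueError("empty trajectory result")
    n_pert = int(t["was_perturbed"].sum())
    return {
        "cumulative_cate": float(t["cate_at_realized"].sum(skipna=True)),
        "n_hours": int(len(t)),
        "n_perturbed": n_pert,
        "fraction_perturbed": n_pert / len(t),
        "table": t,
    }
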