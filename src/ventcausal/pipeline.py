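"""End-to-end cohort pipeline: I/O schemas, inclusion, descriptives, estimation.

The on-disk interchange format is two plain CSVs:

* hourly (one row per admission-hour): ``admission_id, hour, vt_ml, rr,
  peep, p_peak, fio2, spo2, pao2, paco2, ph, wbc, temperature, map,
  mode_spontaneous`` — tidal volume stored in mL, converted to litres at
  read time for the mechanics formulas;
* admissions: ``admission_id, age_band, admission_type, diagnosis_group,
  apache_ii, intubation_duration_hours, death_day`` (empty death_day =
  alive/censored at day 28).

``run_full_pipeline`` orchestrates: inclusion filtering -> descriptive
table (t-test / Mann-Whitney / chi-square comparisons, descriptive
p-values, no multiplicity correction) -> ATEs of median/max/min MP on
VFD28 under each configured estimator -> subgroup CATEs (admission type,
diagnosis group, P/F strata <200 / 200-300 / >=300) -> optional dynamic
grid and trajectory simulation.  Every artifact echoes the config and
seed so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import configparser
import io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import mechanics
from .estimators import (DEFAULT_MIN_CELL, cate_by_subgroup, estimates_to_frame,
                         _run_estimator)
from .grid import fit_grid, optimal_threshold_path, write_grid
from .synthetic import SimConfig, generate_cohort, inject_missingness
from .trajectory import TrajectoryConfig, simulate_trajectory, trajectory_report

__all__ = [
    "read_hourly_csv", "write_hourly_csv", "read_admissions_csv",
    "write_admissions_csv", "apply_inclusion", "build_admission_table",
    "table_one", "run_full_pipeline", "map_external_schema", "SchemaError",
    "PipelineError", "AGE_BANDS", "DIAGNOSIS_GROUPS",
]

AGE_BANDS = ("18-39", "40-49", "50-59", "60-69", "70-79", "80+")
DIAGNOSIS_GROUPS = ("cardiothoracic_surgery", "neurosurgery", "vascular_surgery",
                    "trauma", "cardiac", "respiratory_failure", "infection",
                    "shock", "other")

HOURLY_CSV_COLUMNS = ["admission_id", "hour", "vt_ml", "rr", "peep", "p_peak",
                      "fio2", "spo2", "pao2", "paco2", "ph", "wbc",
                      "temperature", "map", "mode_spontaneous"]
ADMISSION_CSV_COLUMNS = ["admission_id", "age_band", "admission_type",
                         "diagnosis_group", "apache_ii",
                         "intubation_duration_hours", "death_day"]


class SchemaError(ValueError):
    """An input table violates the documented CSV schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

def write_hourly_csv(hourly: pd.DataFrame, path) -> None:
    out = hourly.copy()
    out["vt_ml"] = out.pop("vt") * 1000.0
    out[HOURLY_CSV_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_hourly_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(HOURLY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"hourly CSV missing columns: {sorted(missing)}")
    df["vt"] = df.pop("vt_ml") / 1000.0
    return df


def write_admissions_csv(admissions: pd.DataFrame, path) -> None:
    admissions[ADMISSION_CSV_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_admissions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ADMISSION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"admission CSV missing columns: {sorted(missing)}")
    bad = set(df["age_band"].dropna()) - set(AGE_BANDS)
    if bad:
        raise SchemaError(f"unknown age bands: {sorted(bad)}")
    bad = set(df["diagnosis_group"].dropna()) - set(DIAGNOSIS_GROUPS)
    if bad:
        raise SchemaError(f"unknown diagnosis groups: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Inclusion / exclusion
# ---------------------------------------------------------------------------

def apply_inclusion(
    admissions: pd.DataFrame,
    hourly: pd.DataFrame,
    *,
    min_complete_hours: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Apply the study's inclusion/exclusion cascade; returns step counts.

    Steps: (adult age, only when a raw ``age`` column is present — age
    bands already imply adulthood), then admissions lacking
    ``min_complete_hours`` hours with all four MP inputs, then removal of
    spontaneous-mode hours with admissions left below the completeness bar
    dropped.  Step counts are non-increasing by construction.
    """
    steps = [("initial", len(admissions))]
    adm = admissions
    if "age" in adm.columns:
        adm = adm[adm["age"] >= 18]
        steps.append(("adult", len(adm)))
    h = hourly[hourly["admission_id"].isin(set(adm["admission_id"]))]

    def complete_ids(frame):
        ok = frame[list(mechanics.MP_INPUT_COLUMNS)].notna().all(axis=1)
        counts = frame.loc[ok, "admission_id"].value_counts()
        return set(counts[counts >= min_complete_hours].index)

    keep = complete_ids(h)
    adm = adm[adm["admission_id"].isin(keep)]
    h = h[h["admission_id"].isin(keep)]
    steps.append(("mp_complete", len(adm)))

    h = h[h["mode_spontaneous"] == 0]
    keep = complete_ids(h)
    adm = adm[adm["admission_id"].isin(keep)]
    h = h[h["admission_id"].isin(keep)]
    steps.append(("non_spontaneous", len(adm)))

    counts = [c for _, c in steps]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    return adm.reset_index(drop=True), h.reset_index(drop=True), steps


# ---------------------------------------------------------------------------
# Admission-level analysis table
# ---------------------------------------------------------------------------

def build_admission_table(
    admissions: pd.DataFrame,
    hourly: pd.DataFrame,
    *,
    window_hours: int = 24,
) -> pd.DataFrame:
    """Merge admission covariates with windowed ventilator aggregates and VFD28.

    Adds ``mp_median/mp_max/mp_min`` (J/min over complete hours in the first
    ``window_hours``), driving-pressure and minute-ventilation means, mean
    P/F over the window, and the VFD28 composite outcome.
    """
    win = hourly[hourly["hour"] < window_hours]
    complete = win[win[list(mechanics.MP_INPUT_COLUMNS)].notna().all(axis=1)].copy()
    complete["mp"] = mechanics.mechanical_power(
        complete["vt"].to_numpy(), complete["rr"].to_numpy(),
        complete["peep"].to_numpy(), complete["p_peak"].to_numpy())
    complete["dp"] = complete["p_peak"] - complete["peep"]
    complete["mv"] = complete["vt"] * complete["rr"]
    g = complete.groupby("admission_id")
    agg = pd.DataFrame({
        "mp_median": g["mp"].median(), "mp_max": g["mp"].max(),
        "mp_min": g["mp"].min(), "driving_pressure_mean": g["dp"].mean(),
        "minute_ventilation_mean": g["mv"].mean(), "n_hours_used": g["mp"].size(),
    })
    pf = win.dropna(subset=["pao2", "fio2"]).copy()
    pf["pf_ratio"] = pf["pao2"] / pf["fio2"]
    agg = agg.join(pf.groupby("admission_id")["pf_ratio"].mean().rename("pf_mean"))
    out = admissions.merge(agg, left_on="admission_id", right_index=True, how="inner")
    out["vfd28"] = mechanics.vfd28_series(out["intubation_duration_hours"],
                                          out["death_day"])
    strata = pd.cut(out["pf_mean"], bins=[-np.inf, 200, 300, np.inf],
                    labels=["<200", "200-300", ">=300"], right=False)
    out["pf_stratum"] = strata.astype(object)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Descriptive table
# ---------------------------------------------------------------------------

_TABLE_ONE_CONTINUOUS = [
    ("map_mean", "Mean arterial pressure", "t"),
    ("pao2_mean", "PaO2", "t"),
    ("spo2_mean", "SpO2", "t"),
    ("fio2_mean", "FiO2 (%)", "t"),
    ("temperature_mean", "Temperature", "t"),
    ("apache_ii", "APACHE II", "t"),
    ("mp_mean", "Mechanical power", "t"),
    ("rr_mean", "Respiratory rate", "t"),
    ("vt_ml_mean", "Tidal volume (mL)", "t"),
    ("minute_ventilation_mean", "Minute ventilation", "t"),
    ("peep_mean", "PEEP", "t"),
    ("p_peak_mean", "Peak pressure", "t"),
    ("driving_pressure_mean", "Driving pressure", "t"),
    ("intubation_duration_hours", "Intubation duration (h)", "mw"),
]


def table_one(
    admissions: pd.DataFrame,
    hourly: pd.DataFrame,
    *,
    window_hours: int = 24,
    group_column: str = "admission_type",
) -> pd.DataFrame:
    """Descriptive characteristics in the first analysis window, by group.

    Continuous variables report mean (SD) and a two-sample t-test (or
    Mann-Whitney U for the marked skewed ones); categoricals report n (%)
    and a chi-square test.  P-values are descriptive, not corrected.
    """
    if admissions.empty:
        raise ValueError("table_one requires a non-empty admission table")
    win = hourly[hourly["hour"] < window_hours].copy()
    win["mp"] = mechanics.hourly_mp(win)
    win["driving_pressure"] = win["p_peak"] - win["peep"]
    win["minute_ventilation"] = win["vt"] * win["rr"]
    win["vt_ml"] = win["vt"] * 1000.0
    win["fio2_pct"] = win["fio2"] * 100.0
    means = win.groupby("admission_id").agg(
        map_mean=("map", "mean"), pao2_mean=("pao2", "mean"),
        spo2_mean=("spo2", "mean"), fio2_mean=("fio2_pct", "mean"),
        temperature_mean=("temperature", "mean"), mp_mean=("mp", "mean"),
        rr_mean=("rr", "mean"), vt_ml_mean=("vt_ml", "mean"),
        minute_ventilation_mean=("minute_ventilation", "mean"),
        peep_mean=("peep", "mean"), p_peak_mean=("p_peak", "mean"),
        driving_pressure_mean=("driving_pressure", "mean"))
    d = admissions.merge(means, left_on="admission_id", right_index=True, how="left")
    groups = sorted(d[group_column].dropna().unique())

    def fmt(x, sd):
        return f"{x:.1f} ({sd:.1f})"

    rows = []
    for col, label, test in _TABLE_ONE_CONTINUOUS:
        if col not in d.columns:
            continue
        series = [d.loc[d[group_column] == g, col].dropna() for g in groups]
        overall = d[col].dropna()
        if any(len(s) < 2 for s in series):
            pval, test_name = float("nan"), "NA (group n < 2)"
        elif test == "t" and len(groups) == 2:
            pval = float(stats.ttest_ind(*series, equal_var=False).pvalue)
            test_name = "t-test"
        elif test == "mw" and len(groups) == 2:
            pval = float(stats.mannwhitneyu(*series).pvalue)
            test_name = "mann-whitney"
        else:
            pval = float(stats.kruskal(*series).pvalue)
            test_name = "kruskal-wallis"
        row = {"variable": label, "overall": fmt(overall.mean(), overall.std()),
               "test": test_name, "p_value": pval}
        for g, s in zip(groups, series):
            row[str(g)] = fmt(s.mean(), s.std())
        rows.append(row)

    for col in ("age_band", "diagnosis_group"):
        if col not in d.columns:
            continue
        tab = pd.crosstab(d[col], d[group_column])
        if tab.shape[0] > 1 and tab.shape[1] > 1 and (tab.values.sum(axis=0) > 0).all():
            pval = float(stats.chi2_contingency(tab.values).pvalue)
            test_name = "chi-square"
        else:
            pval, test_name = float("nan"), "NA (degenerate table)"
        for k, level in enumerate(tab.index):
            row = {"variable": f"{col}: {level}",
                   "overall": f"{int(tab.loc[level].sum())} "
                              f"({100 * tab.loc[level].sum() / len(d):.1f})",
                   "test": test_name if k == 0 else "",
                   "p_value": pval if k == 0 else float("nan")}
            for g in groups:
                cnt = int(tab.loc[level, g]) if g in tab.columns else 0
                denom = max(int((d[group_column] == g).sum()), 1)
                row[str(g)] = f"{cnt} ({100 * cnt / denom:.1f})"
            rows.append(row)
    cols = ["variable", "overall", *[str(g) for g in groups], "test", "p_value"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# External schema mapping (stub for access-gated source databases)
# ---------------------------------------------------------------------------

REQUIRED_HOURLY_MAP = ("admission_id", "hour", "vt", "rr", "peep", "p_peak")
REQUIRED_ADMISSION_MAP = ("admission_id", "admission_type",
                          "intubation_duration_hours")
_UNIT_CONVERTERS = {"ml": lambda s: s / 1000.0, "percent": lambda s: s / 100.0,
                    "identity": lambda s: s}


def map_external_schema(mapping_path, hourly_raw: pd.DataFrame,
                        admissions_raw: pd.DataFrame):
    """Rename/unit-convert third-party tables into the standard schema.

    The mapping file has ``[hourly]`` and ``[admissions]`` sections of
    ``standard_column = source_column [unit]`` lines, where ``unit`` is one
    of ``ml`` (stored mL -> litres), ``percent`` (-> fraction) or omitted.
    Missing required mappings raise :class:`SchemaError` listing the gaps.
    """
    cp = configparser.ConfigParser()
    cp.read(str(mapping_path))
    out = {}
    for section, raw, required in (("hourly", hourly_raw, REQUIRED_HOURLY_MAP),
                                   ("admissions", admissions_raw,
                                    REQUIRED_ADMISSION_MAP)):
        spec = dict(cp[section]) if cp.has_section(section) else {}
        gaps = [c for c in required if c not in spec]
        if gaps:
            raise SchemaError(f"[{section}] mapping missing required columns: {gaps}")
        frame = pd.DataFrame(index=raw.index)
        for std, rhs in spec.items():
            parts = rhs.split()
            src, unit = parts[0], (parts[1] if len(parts) > 1 else "identity")
            if src not in raw.columns:
                raise SchemaError(f"[{section}] source column {src!r} not in table")
            if unit not in _UNIT_CONVERTERS:
                raise SchemaError(f"[{section}] unknown unit {unit!r}")
            col = raw[src]
            frame[std] = _UNIT_CONVERTERS[unit](col) if col.dtype.kind in "fib" \
                else col
        out[section] = frame
    return out["hourly"], out["admissions"]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

_SIM_KEYS = {
    "n_admissions": int, "frac_medical": float, "true_ate_vfd": float,
    "true_pf_effect": float, "mp_threshold_true": float, "missing_rate": float,
    "max_hours": int, "seed": int, "policy_strength": float,
    "nonlinear_confounding": lambda s: s.lower() in ("1", "true", "yes"),
    "vfd_effect_mode": str, "frac_spontaneous": float, "mp_window_hours": int,
}
VALID_ESTIMATORS = ("backdoor_lr", "dml_forest", "dml_generic")
# admission_type is deliberately absent: the diagnosis vocabulary is nested
# within admission type (only "other" spans both arms), so including both
# makes subgroup designs exactly collinear whenever a subgroup lacks an
# "other" admission in one arm; given APACHE II, age band and diagnosis,
# admission type closes no additional backdoor path to VFD28.
DEFAULT_ADJUSTMENT = ("apache_ii", "age_band", "diagnosis_group")


def _parse_config(path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    read = cp.read(str(path))
    if not read:
        raise PipelineError(f"config: cannot read {path}")
    return cp


def run_full_pipeline(config_path, out_dir, *, seed: int | None = None) -> dict:
    """Execute the configured analysis end to end; returns the report dict.

    Any stage failure raises :class:`PipelineError` naming the stage.
    Outputs (``report.txt``, ``estimates.csv``, ``table_one.csv``, optional
    grid/trajectory exports) are byte-identical across reruns with the
    same config and seed.
    """
    cp = _parse_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_file": str(config_path)}

    # -- stage: configuration validation ---------------------------------
    est_tags = [s.strip() for s in
                cp.get("estimate", "estimators", fallback="backdoor_lr").split(",")]
    for tag in est_tags:
        if tag not in VALID_ESTIMATORS:
            raise PipelineError(f"config: unknown estimator tag {tag!r}")
    aggregates = [s.strip() for s in
                  cp.get("estimate", "aggregates",
                         fallback="mp_median,mp_max,mp_min").split(",")]
    n_boot = cp.getint("estimate", "n_boot", fallback=200)
    min_n = cp.getint("estimate", "min_n", fallback=DEFAULT_MIN_CELL)
    window = cp.getint("estimate", "window_hours", fallback=24)

    # -- stage: data -----------------------------------------------------
    try:
        if cp.has_section("simulate"):
            kwargs = {k: conv(cp.get("simulate", k))
                      for k, conv in _SIM_KEYS.items() if cp.has_option("simulate", k)}
            if seed is not None:
                kwargs["seed"] = seed
            sim = SimConfig(**kwargs)
            cohort = generate_cohort(sim)
            if sim.missing_rate > 0:
                cohort = inject_missingness(cohort, sim.missing_rate, sim.seed + 1)
            admissions, hourly = cohort.admissions, cohort.hourly
            report["truth"] = cohort.truth
            master_seed = sim.seed
        else:
            hourly = read_hourly_csv(cp.get("data", "hourly"))
            admissions = read_admissions_csv(cp.get("data", "admissions"))
            master_seed = seed if seed is not None else cp.getint(
                "data", "seed", fallback=0)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"data: {exc}") from exc
    report["seed"] = master_seed

    # -- stage: inclusion ------------------------------------------------
    try:
        admissions, hourly, steps = apply_inclusion(admissions, hourly)
    except Exception as exc:
        raise PipelineError(f"inclusion: {exc}") from exc
    report["inclusion_steps"] = steps

    # -- stage: descriptives ---------------------------------------------
    try:
        t1 = table_one(admissions, hourly, window_hours=window)
        t1.to_csv(out_dir / "table_one.csv", index=False, float_format="%.6g")
    except Exception as exc:
        raise PipelineError(f"table_one: {exc}") from exc

    # -- stage: effect estimation ----------------------------------------
    try:
        table = build_admission_table(admissions, hourly, window_hours=window)
        adjustment = [c for c in DEFAULT_ADJUSTMENT if c in table.columns]
        estimates = []
        for tag in est_tags:
            for agg in aggregates:
                estimates.append(_run_estimator(
                    tag, table, agg, "vfd28", adjustment, master_seed, n_boot))
        cate_est = cp.get("estimate", "cate_estimator", fallback="backdoor_lr")
        for grouping in ("admission_type", "diagnosis_group", "pf_stratum"):
            estimates.extend(cate_by_subgroup(
                table, grouping, "mp_median", "vfd28", adjustment,
                estimator=cate_est, min_n=min_n, seed=master_seed, n_boot=n_boot))
        est_frame = estimates_to_frame(estimates)
        est_frame.to_csv(out_dir / "estimates.csv", index=False, float_format="%.8g")
    except Exception as exc:
        raise PipelineError(f"estimation: {exc}") from exc
    report["n_ate_rows"] = len(est_tags) * len(aggregates)
    report["n_estimates"] = len(est_frame)

    # -- stage: dynamic grid (optional) ----------------------------------
    the_grid = None
    if cp.getboolean("grid", "enabled", fallback=False):
        try:
            hours = range(cp.getint("grid", "hours_max", fallback=40) + 1)
            thresholds = range(cp.getint("grid", "thresholds_max", fallback=40) + 1)
            the_grid = fit_grid(
                hourly, admissions, hours=hours, thresholds=thresholds,
                min_cell_n=cp.getint("grid", "min_cell_n", fallback=DEFAULT_MIN_CELL),
                seed=master_seed)
            write_grid(the_grid, out_dir / "grid_long.csv",
                       out_dir / "grid_matrix.csv")
            report["grid_models"] = int(np.prod([len(the_grid.hours),
                                                 len(the_grid.thresholds)]))
        except Exception as exc:
            raise PipelineError(f"grid: {exc}") from exc

    # -- stage: trajectory (optional) ------------------------------------
    if cp.getboolean("trajectory", "enabled", fallback=False):
        try:
            if the_grid is None:
                raise ValueError("trajectory requires the grid stage enabled")
            tc = TrajectoryConfig(
                initial_mp=cp.getfloat("trajectory", "initial_mp", fallback=40.0),
                noise_level=cp.getfloat("trajectory", "noise_level", fallback=0.4),
                horizon_hours=cp.getint("trajectory", "horizon_hours",
                                        fallback=len(the_grid.hours)),
                seed=master_seed)
            res = simulate_trajectory(the_grid, tc)
            res.table.to_csv(out_dir / "trajectory.csv", index=False,
                             float_format="%.8g")
            rep = trajectory_report(res)
            report["trajectory_cumulative_cate"] = rep["cumulative_cate"]
            report["trajectory_fraction_perturbed"] = rep["fraction_perturbed"]
        except Exception as exc:
            raise PipelineError(f"trajectory: {exc}") from exc

    # -- stage: report ---------------------------------------------------
    buf = io.StringIO()
    buf.write("# ventcausal pipeline report\n")
    for key in sorted(k for k in report if k not in ("inclusion_steps",)):
        buf.write(f"{key} = {report[key]}\n")
    for name, count in report["inclusion_steps"]:
        buf.write(f"inclusion.{name} = {count}\n")
    buf.write("\n## estimates\n")
    est_frame.to_csv(buf, index=False, float_format="%.8g")
    (out_dir / "report.txt").write_text(buf.getvalue())
    report["estimates"] = est_frame
    report["table_one"] = t1
    if the_grid is not None:
        report["grid"] = the_grid
        report["optimal_path"] = optimal_threshold_path(the_grid)
    return report
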