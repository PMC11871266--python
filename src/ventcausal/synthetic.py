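"""Synthetic ICU cohort generator with known ground-truth causal effects.

Real hourly ventilator data of the kind this package analyses sit behind
access-gated clinical databases, so every downstream stage is exercised on
synthetic cohorts drawn from structural equations that follow the package's
clinical DAG (:mod:`ventcausal.dag`):

    demographics + diagnosis  ->  severity (APACHE II, observed)
    severity                  ->  labs/vitals (WBC, temperature, pH, MAP, PaCO2)
    severity + clinician policy -> ventilator settings (RR, Ppeak, PEEP, Vt) -> MP
    lagged MP + severity      ->  hourly P/F trajectory
    severity + median MP      ->  ventilation duration, 28-day mortality -> VFD28

Clinician-policy confounding is the crux: sicker patients receive higher
mechanical power AND have worse outcomes, so naive regressions are biased
and the backdoor machinery has something real to correct.  The observed
APACHE II score carries the severity signal that reaches the ventilator
settings, so adjusting for {apache_ii, age_band, admission_type,
diagnosis_group} identifies the effect by construction; an additional
latent severity term perturbs outcomes and labs but never the settings.

Marginal distributions (MP means/SDs per arm, RR, peak pressure, tidal
volume, APACHE II, age-band frequencies) are calibrated loosely to typical
mixed medical/surgical ICU populations; exact marginals are not a contract.

The hourly P/F effect of mechanical power is a hinge: each J/min above
``mp_threshold_true`` depresses next-hour P/F by ``|true_pf_effect|`` units,
with no effect below the threshold — giving the dynamic-grid machinery a
recoverable change point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SyntheticCohort", "generate_cohort", "inject_missingness",
           "write_cohort", "ConfigError"]

AGE_BANDS = ("18-39", "40-49", "50-59", "60-69", "70-79", "80+")
AGE_PROBS = (0.078, 0.078, 0.165, 0.286, 0.293, 0.100)

MEDICAL_DIAGNOSES = {"shock": 0.45, "respiratory_failure": 0.25,
                     "infection": 0.15, "cardiac": 0.10, "other": 0.05}
SURGICAL_DIAGNOSES = {"cardiothoracic_surgery": 0.69, "neurosurgery": 0.12,
                      "vascular_surgery": 0.10, "trauma": 0.06, "other": 0.03}

# severity offsets per diagnosis group (standardised units)
_DIAG_SEV = {"shock": 0.5, "respiratory_failure": 0.4, "infection": 0.3,
             "cardiac": 0.2, "trauma": 0.1, "cardiothoracic_surgery": -0.3,
             "neurosurgery": -0.1, "vascular_surgery": -0.1, "other": 0.0}

DEFAULT_NOISE_SD = {"vfd": 2.5, "pf": 15.0, "rr": 2.8, "p_peak": 4.0,
                    "peep": 1.8, "vt_ml": 85.0}


class ConfigError(ValueError):
    """A SimConfig field is out of its admissible range."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Effects are on the analysis scales: ``true_ate_vfd`` in days of VFD28
    per J/min of first-24h median MP (or days per threshold crossing when
    ``vfd_effect_mode='step'``); ``true_pf_effect`` in P/F units per J/min
    above ``mp_threshold_true`` on next-hour P/F.
    """

    n_admissions: int = 1000
    frac_medical: float = 0.42
    diagnosis_mix: dict = field(default_factory=lambda: {
        "medical": dict(MEDICAL_DIAGNOSES), "surgical": dict(SURGICAL_DIAGNOSES)})
    true_ate_vfd: float = -0.15
    true_cate_map: dict | None = None
    true_pf_effect: float = -1.5
    mp_threshold_true: float = 17.0
    noise_sd_map: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    missing_rate: float = 0.0
    max_hours: int = 72
    seed: int = 0
    policy_strength: float = 1.0
    nonlinear_confounding: bool = False
    vfd_effect_mode: str = "linear"   # linear | step
    frac_spontaneous: float = 0.0
    mp_window_hours: int = 24

    def validate(self) -> None:
        if self.n_admissions < 1:
            raise ConfigError("n_admissions must be >= 1")
        if not 0.0 <= self.frac_medical <= 1.0:
            raise ConfigError("frac_medical must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.frac_spontaneous <= 1.0:
            raise ConfigError("frac_spontaneous must lie in [0, 1]")
        if self.max_hours < 1:
            raise ConfigError("max_hours must be >= 1")
        if self.mp_window_hours < 1:
            raise ConfigError("mp_window_hours must be >= 1")
        if self.vfd_effect_mode not in ("linear", "step"):
            raise ConfigError("vfd_effect_mode must be 'linear' or 'step'")
        for arm in ("medical", "surgical"):
            mix = self.diagnosis_mix.get(arm)
            if mix is None:
                raise ConfigError(f"diagnosis_mix missing arm {arm!r}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"diagnosis_mix[{arm!r}] proportions must sum to 1")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"diagnosis_mix[{arm!r}] has a negative proportion")
        if any(sd < 0 for sd in self.noise_sd_map.values()):
            raise ConfigError("noise_sd_map entries must be >= 0")

    def truth(self) -> dict:
        return {
            "true_ate_vfd": self.true_ate_vfd,
            "true_cate_map": dict(self.true_cate_map) if self.true_cate_map else None,
            "true_pf_effect": self.true_pf_effect,
            "mp_threshold_true": self.mp_threshold_true,
            "vfd_effect_mode": self.vfd_effect_mode,
            "seed": self.seed,
        }


@dataclass
class SyntheticCohort:
    """Generated admission + hourly tables with their ground truth attached.

    ``hourly`` carries one row per admission-hour (``vt`` in litres);
    ``admissions`` one row per admission.  ``truth`` echoes the effect
    parameters used, so tests can compare estimates against them.
    """

    admissions: pd.DataFrame
    hourly: pd.DataFrame
    truth: dict
    seed_used: int


def _streams(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a cohort from the structural equations; deterministic given seed."""
    config.validate()
    n = config.n_admissions
    T = config.max_hours
    sd = {**DEFAULT_NOISE_SD, **config.noise_sd_map}
    (rg_cov, rg_vent, rg_hour, rg_pf, rg_labs, rg_out) = _streams(config.seed, 6)

    # --- admission-level covariates -------------------------------------
    is_med = rg_cov.random(n) < config.frac_medical
    admission_type = np.where(is_med, "medical", "surgical")
    diagnosis = np.empty(n, dtype=object)
    for arm, mask in (("medical", is_med), ("surgical", ~is_med)):
        mix = config.diagnosis_mix[arm]
        labels, probs = zip(*sorted(mix.items()))
        k = int(mask.sum())
        if k:
            diagnosis[mask] = rg_cov.choice(labels, size=k, p=np.asarray(probs))
    age_idx = rg_cov.choice(len(AGE_BANDS), size=n, p=np.asarray(AGE_PROBS))
    age_band = np.asarray(AGE_BANDS, dtype=object)[age_idx]

    apache = np.where(is_med, 22.7 + 7.6 * rg_cov.standard_normal(n),
                      17.2 + 5.9 * rg_cov.standard_normal(n))
    apache = np.clip(np.round(apache), 4, 50)
    z = (apache - 19.5) / 7.2                    # observed severity signal
    latent = 0.7 * rg_cov.standard_normal(n)     # outcome-only latent severity
    diag_sev = np.vectorize(_DIAG_SEV.__getitem__)(diagnosis).astype(float)

    # --- ventilator policy (the confounding pathway) --------------------
    pol = z + (0.9 * (z**2 - 1.0) if config.nonlinear_confounding else 0.0)
    ps = config.policy_strength
    rr_adm = np.where(is_med, 18.8, 16.5) + 1.6 * ps * pol \
        + sd["rr"] * rg_vent.standard_normal(n)
    rr_adm = np.clip(rr_adm, 8, 35)
    ppeak_adm = np.where(is_med, 24.0, 19.0) + 2.5 * ps * pol \
        + sd["p_peak"] * rg_vent.standard_normal(n)
    ppeak_adm = np.clip(ppeak_adm, 12, 45)
    peep_adm = np.where(is_med, 8.8, 6.8) + 0.8 * ps * pol \
        + sd["peep"] * rg_vent.standard_normal(n)
    peep_adm = np.clip(peep_adm, 3, np.minimum(ppeak_adm - 4.0, 18.0))
    vt_adm = np.clip(481 + sd["vt_ml"] * rg_vent.standard_normal(n), 250, 750)

    # --- hourly ventilator settings and MP (n x T) ----------------------
    rr_h = np.clip(rr_adm[:, None] + 1.2 * rg_hour.standard_normal((n, T)), 6, 40)
    ppeak_h = ppeak_adm[:, None] + 1.5 * rg_hour.standard_normal((n, T))
    peep_h = np.clip(peep_adm[:, None] + 0.6 * rg_hour.standard_normal((n, T)), 0, None)
    ppeak_h = np.maximum(ppeak_h, peep_h + 2.0)
    vt_h = np.clip(vt_adm[:, None] + 25 * rg_hour.standard_normal((n, T)), 200, 800)
    mp_h = 0.098 * (vt_h / 1000.0) * rr_h * ppeak_h

    win = min(config.mp_window_hours, T)
    mp_median = np.median(mp_h[:, :win], axis=1)

    # --- outcome: latent VFD target -> duration / mortality -------------
    if config.vfd_effect_mode == "step":
        effect = config.true_ate_vfd * (mp_median > config.mp_threshold_true)
    else:
        slope = np.full(n, config.true_ate_vfd)
        if config.true_cate_map:
            for labels in (diagnosis, admission_type):
                for i, lab in enumerate(labels):
                    if lab in config.true_cate_map:
                        slope[i] = config.true_cate_map[lab]
        effect = slope * mp_median
    base = 20.0 - 2.0 * z - 0.8 * diag_sev - 0.25 * (age_idx - 2.5) + 0.8 * latent
    if config.nonlinear_confounding:
        base = base - 2.2 * (z**2 - 1.0)
    v_target = base + effect + sd["vfd"] * rg_out.standard_normal(n)

    dies = v_target < 1.0
    death_day = np.where(dies, rg_out.integers(1, 29, size=n), np.nan)
    # duration floor = the MP window, so the settings that drove the outcome
    # are always on record (clinically: extubation decisions lag by a day)
    v_cap = 28.0 - win / 24.0
    duration = 24.0 * (28.0 - np.clip(v_target, 0.04, v_cap))
    hours_rec = np.minimum(np.ceil(duration).astype(int), T)
    hours_rec = np.maximum(hours_rec, 1)

    # --- hourly P/F (AR(1) around a severity baseline, hinge MP effect) --
    pf_base = np.where(is_med, 230.0, 280.0) - 18.0 * z - 10.0 * latent
    hinge = config.true_pf_effect * np.maximum(0.0, mp_h - config.mp_threshold_true)
    eps = sd["pf"] * rg_pf.standard_normal((n, T))
    pf = np.empty((n, T))
    pf[:, 0] = pf_base + eps[:, 0]
    phi = 0.6
    for t in range(1, T):
        pf[:, t] = pf_base + phi * (pf[:, t - 1] - pf_base) + hinge[:, t - 1] + eps[:, t]
    pf = np.clip(pf, 50.0, None)

    fio2 = np.clip(np.where(is_med, 0.506, 0.456)[:, None] + 0.03 * z[:, None]
                   + 0.08 * rg_pf.standard_normal((n, T)), 0.25, 1.0)
    pao2 = pf * fio2
    spo2 = np.clip(97.8 - 0.5 * z[:, None] + 1.5 * rg_pf.standard_normal((n, T)), 75, 100)

    # --- hourly labs/vitals driven by severity --------------------------
    sev = z + 0.5 * latent
    wbc = np.clip((11.0 + 1.8 * sev)[:, None] + 1.0 * rg_labs.standard_normal((n, T)), 1, None)
    temp = np.where(is_med, 35.3, 36.1)[:, None] + 0.2 * latent[:, None] \
        + 0.3 * rg_labs.standard_normal((n, T))
    ph_a = np.clip((7.38 - 0.04 * sev)[:, None] + 0.02 * rg_labs.standard_normal((n, T)),
                   6.9, 7.7)
    map_a = np.clip((np.where(is_med, 77.3, 74.5) - 3.0 * sev)[:, None]
                    + 6.0 * rg_labs.standard_normal((n, T)), 40, 140)
    paco2 = np.clip((40.0 + 2.5 * sev)[:, None] + 2.0 * rg_labs.standard_normal((n, T)),
                    20, 90)

    spont = rg_out.random(n) < config.frac_spontaneous

    # --- assemble long-format hourly table, truncated at duration -------
    keep = np.arange(T)[None, :] < hours_rec[:, None]
    adm_ids = np.array([f"adm{i:06d}" for i in range(n)], dtype=object)
    row_adm = np.repeat(adm_ids, hours_rec)
    row_hour = np.concatenate([np.arange(h) for h in hours_rec])

    def flat(a):
        return a[keep]

    hourly = pd.DataFrame({
        "admission_id": row_adm,
        "hour": row_hour,
        "vt": flat(vt_h) / 1000.0,
        "rr": flat(rr_h),
        "peep": flat(peep_h),
        "p_peak": flat(ppeak_h),
        "fio2": flat(fio2),
        "spo2": flat(spo2),
        "pao2": flat(pao2),
        "paco2": flat(paco2),
        "ph": flat(ph_a),
        "wbc": flat(wbc),
        "temperature": flat(temp),
        "map": flat(map_a),
        "mode_spontaneous": np.repeat(spont, hours_rec).astype(int),
    })
    admissions = pd.DataFrame({
        "admission_id": adm_ids,
        "age_band": age_band,
        "admission_type": admission_type,
        "diagnosis_group": diagnosis,
        "apache_ii": apache.astype(int),
        "intubation_duration_hours": duration,
        "death_day": death_day,
    })
    return SyntheticCohort(admissions=admissions, hourly=hourly,
                           truth=config.truth(), seed_used=config.seed)


def inject_missingness(cohort: SyntheticCohort, rate: float, seed: int) -> SyntheticCohort:
    """Independently blank each ventilator field with probability ``rate``.

    Emulates the incomplete charting that real exclusion criteria must
    drop; the cohort's truth record is untouched.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError("missingness rate must lie in [0, 1)")
    hourly = cohort.hourly.copy()
    if rate > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        for col in ("vt", "rr", "peep", "p_peak"):
            mask = rng.random(len(hourly)) < rate
            hourly.loc[mask, col] = np.nan
    return SyntheticCohort(admissions=cohort.admissions.copy(), hourly=hourly,
                           truth=dict(cohort.truth), seed_used=cohort.seed_used)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write hourly/admission CSVs (external schema, Vt in mL) + truth sidecar."""
    from .pipeline import write_hourly_csv, write_admissions_csv
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hourly": outdir / "hourly.csv",
        "admissions": outdir / "admissions.csv",
        "truth": outdir / "truth.txt",
    }
    write_hourly_csv(cohort.hourly, paths["hourly"])
    write_admissions_csv(cohort.admissions, paths["admissions"])
    lines = [f"{k} = {v}" for k, v in cohort.truth.items() if not isinstance(v, dict)]
    if cohort.truth.get("true_cate_map"):
        for k, v in sorted(cohort.truth["true_cate_map"].items()):
            lines.append(f"true_cate_map.{k} = {v}")
    lines.append(f"seed_used = {cohort.seed_used}")
    paths["truth"].write_text("\n".join(lines) + "\n")
    return paths
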