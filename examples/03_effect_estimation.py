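"""Estimate the ATE and subgroup CATEs of median MP on VFD28.

Backdoor OLS and cross-fitted double machine learning are run on the same
cohort; with a linear data-generating process both should recover the
generator's truth of -0.15 ventilator-free days per J/min.
"""

import ventcausal as vc
from ventcausal.pipeline import apply_inclusion, build_admission_table

ADJ = ["apache_ii", "age_band", "admission_type", "diagnosis_group"]

cohort = vc.generate_cohort(vc.SimConfig(n_admissions=4000, seed=3))
adm, hourly, steps = apply_inclusion(cohort.admissions, cohort.hourly)
table = build_admission_table(adm, hourly)
print("inclusion cascade:", steps)

for name, est in [
    ("backdoor OLS", vc.backdoor_linear_ate(table, "mp_median", "vfd28", ADJ,
                                            n_boot=200, seed=3)),
    ("DML (forest)", vc.dml_ate(table, "mp_median", "vfd28", ADJ,
                                learner_kind="forest", n_boot=100, seed=3)),
]:
    print(f"{name}: ATE = {est.point:+.3f} days per J/min "
          f"(95% CI {est.ci_low:+.3f} to {est.ci_high:+.3f}, n={est.n})")

for e in vc.cate_by_subgroup(table, "admission_type", "mp_median", "vfd28",
                             ["apache_ii", "age_band", "diagnosis_group"],
                             n_boot=200, seed=3):
    print(f"CATE[{e.subgroup}] = {e.point:+.3f} "
          f"({e.ci_low:+.3f}, {e.ci_high:+.3f}, n={e.n})")
# Points near -0.15 bracket the truth; each extra J/min of median MP in the
# first day costs about a seventh of a ventilator-free day.
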