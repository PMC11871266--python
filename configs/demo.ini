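# Demo pipeline configuration: small synthetic cohort, grid/trajectory off.
[simulate]
n_admissions = 500
frac_medical = 0.42
true_ate_vfd = -0.15
seed = 0

[estimate]
estimators = backdoor_lr, dml_forest, dml_generic
aggregates = mp_median, mp_max, mp_min
n_boot = 200
min_n = 50
window_hours = 24

[grid]
enabled = false

[trajectory]
enabled = false
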