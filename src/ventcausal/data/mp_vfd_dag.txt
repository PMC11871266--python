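# Clinical DAG for the mechanical-power -> ventilator-free-days question.
# Labs/vitals and demographics feed a disease-severity score; severity drives
# the ventilator settings behind mechanical power (clinician policy) and the
# oxygenation (P/F) trajectory, which shapes ventilator-free days.  Lung
# compliance and residual frailty are unmeasured (grey) nodes.
node mechanical_power observed exposure
node pf_ratio observed intermediary
node vent_free_days observed outcome
node disease_score observed covariate
node wbc observed covariate
node temperature observed covariate
node ph observed covariate
node map observed covariate
node paco2 observed covariate
node age observed covariate
node admission_type observed covariate
node diagnosis observed covariate
node resp_rate observed covariate
node peak_pressure observed covariate
node lung_compliance unobserved covariate
node frailty unobserved covariate

wbc -> disease_score
temperature -> disease_score
ph -> disease_score
map -> disease_score
paco2 -> disease_score
age -> disease_score
admission_type -> disease_score
diagnosis -> disease_score
frailty -> disease_score
frailty -> vent_free_days
disease_score -> resp_rate
disease_score -> peak_pressure
disease_score -> pf_ratio
disease_score -> vent_free_days
resp_rate -> mechanical_power
peak_pressure -> mechanical_power
lung_compliance -> mechanical_power
mechanical_power -> pf_ratio
pf_ratio -> vent_free_days
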