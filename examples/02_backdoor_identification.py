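"""Identify backdoor adjustment sets on the packaged clinical DAG.

The graph encodes how severity drives both ventilator policy (mechanical
power) and outcomes; backdoor sets are the covariate sets that block every
confounding path without touching descendants of the exposure.
"""

import ventcausal as vc

dag = vc.default_dag()
print(f"exposure: {dag.exposure}; outcomes: {dag.outcomes}")
print(f"unobserved nodes: {sorted(set(dag.nodes) - dag.observed_nodes())}")

for s in vc.backdoor_sets(dag, outcome="vent_free_days"):
    print("minimal adjustment set:", s.sorted_variables())
# {disease_score} suffices because every backdoor path from MP runs through
# the severity score; {peak_pressure, resp_rate} works too, blocking the
# policy pathway at the ventilator settings instead.

print("d-separated(MP, VFD | disease_score, pf_ratio)? ",
      vc.d_separated(dag, "mechanical_power", "vent_free_days",
                     {"disease_score", "pf_ratio"}))
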