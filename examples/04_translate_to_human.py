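"""Translate the rat dose-response to individual patients and plan doses.

Uses the published rat Hill parameters for k_i and three patients with
different baseline uptake rates; computes each patient's maximal allowed
dose for a chosen normal-function limit and compares it with the drug's
minimal required dose.
"""

from gadopk import (
    DosePlanningConfig,
    PatientBaseline,
    TABLE_1A_TRUTH,
    plan_dose,
)
from gadopk.io import decision_table

rat_ki = TABLE_1A_TRUTH["k_i"]
patients = [
    PatientBaseline("P1", k_i_human=4.1e-3),
    PatientBaseline("P2", k_i_human=2.5e-3),
    PatientBaseline("P3", k_i_human=1.4e-3),
]
# normal-function lower limit (s^-1) comes from a reference healthy cohort
# and is a required input; the minimal required dose is a drug property.
cfg = DosePlanningConfig(normal_lower_limit=1.15e-3, minimal_required_dose=28.0)

results = [plan_dose(p, rat_ki, cfg) for p in patients]
table = decision_table(results)
print(table.to_string(index=False))
print(f"\nnote: {table.attrs['disclaimer']}")

# Patients with higher baseline uptake tolerate more inhibition before
# crossing the normal-function limit, so their maximal allowed dose is
# higher; the drug is usable only when that exceeds the minimal required
# dose (28 mg/kg here).
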