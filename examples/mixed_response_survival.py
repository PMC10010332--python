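"""Mixed-response classification and survival comparison on a cohort.

Simulates a 503-patient cohort across four cancer types with planted
response groups, classifies every patient from lesion trajectories in
the first six months, summarises mixed-response frequencies, and
compares PFS across groups with Kaplan-Meier and the log-rank test.
"""

from lesionscope import SimConfig, cohort_summary, survival_by_group
from lesionscope.io import load_patient_records
from lesionscope.simulate import sim_cohort

lesions, patients, truth = sim_cohort(SimConfig(seed=0))
records = load_patient_records(lesions, patients)
summary = cohort_summary(records)

pooled = summary["pooled"]
print(f"{summary['n_patients']} patients; "
      f"{pooled['counts']['mixed_responder']} mixed responders "
      f"({pooled['percent']['mixed_responder']}%)")
for ctype, row in sorted(summary["by_cancer_type"].items()):
    print(f"  {ctype}: {row['counts']['mixed_responder']}/{row['n']} "
          f"({row['percent']['mixed_responder']}%)")
local = summary["mixed_local_therapy"]
print(f"local therapy among mixed responders: "
      f"{local['n_local_therapy']}/{local['n_mixed']} ({local['percent']}%)")

surv = survival_by_group(records, endpoint="pfs")
for group, fit in sorted(surv["km"].items()):
    print(f"  median PFS [{group}]: {fit.median:.0f} days")
lr = surv["logrank"]
print(f"log-rank: chi2 = {lr.statistic:.1f}, df = {lr.df}, "
      f"p = {lr.p_value:.3g}")
print("# mixed responders sit between responders and nonresponders in PFS;")
print("# the log-rank test rejects a common hazard across the three groups")
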