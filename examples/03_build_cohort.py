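"""Run the full pipeline: tables -> lines -> eligible cohort -> outcomes.

Eligibility mirrors the study design: bevacizumab in the first line, index
date (first bevacizumab administration) inside the accrual window, and at
least 12 months of follow-up for patients alive at the cutoff.
"""

from collections import Counter

from carelines import SimConfig, run_pipeline, simulate_cohort

sim = simulate_cohort(SimConfig(n_patients=400, seed=11))
res = run_pipeline(sim.patients, sim.dispenses, sim.infusions,
                   sim.surgeries, sim.labs, sim.dictionary)

print(f"cohort members: {len(res.members)}  "
      f"(excluded: {len(res.exclusions)})")
groups = Counter(m.group for m in res.members)
print(f"surgery group: {groups['surgery']}, non-surgery: {groups['non_surgery']}")
backbones = Counter(m.first_line_backbone for m in res.members)
print(f"first-line backbones: {dict(backbones)}")
meds = Counter(cat for m in res.members for cat in m.regular_meds)
print(f"regular non-oncology medication users: {dict(meds)}")
print(f"flagged for manual review: {sum(m.review_flag for m in res.members)}")

df = res.outcomes_frame()
print()
print(f"median observed OS  {df['os_months'].median():.1f} months "
      f"({int(df['os_event'].sum())} deaths)")
print(f"median observed DOT {df['dot_months'].median():.1f} months "
      f"(first-line bevacizumab-containing treatment)")
print()
print("Each member carries an index date, group label, regular-medication")
print("flags, baseline labs and OS/DOT with event indicators.")
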