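"""Generate a small synthetic claims cohort and look at the six tables.

The generator emits HMO-style tables (patients, dispenses, infusions,
surgeries, labs, drug dictionary) for a first-line-bevacizumab mCRC cohort,
together with the per-patient ground truth used to validate the pipeline.
"""

from carelines import SimConfig, simulate_cohort

sim = simulate_cohort(SimConfig(n_patients=100, seed=42))

print(f"patients:  {len(sim.patients):>6} rows")
print(f"dispenses: {len(sim.dispenses):>6} rows (pharmacy purchases)")
print(f"infusions: {len(sim.infusions):>6} rows (hospital claims)")
print(f"surgeries: {len(sim.surgeries):>6} rows")
print(f"labs:      {len(sim.labs):>6} rows")
print()
p = sim.patients[0]
print(f"first patient: {p.patient_id}, {p.sex}, born {p.birth_date}, "
      f"died {p.death_date}, registries {sorted(p.registry_flags)}")
t = sim.truth[0]
print(f"ground truth:  {t.n_lines} therapy line(s), group={t.group}, "
      f"first-line backbone {t.first_line_backbone}, "
      f"OS {t.os_months:.1f} months ({'death' if t.os_event else 'censored'})")
print()
print("The tables are what a real claims extract would look like; the truth")
print("object is what the pipeline must recover from them.")
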