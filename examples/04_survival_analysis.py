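"""Kaplan-Meier, log-rank and the age/sex-adjusted Cox covariate screen.

The generator plants hazard ratios for some non-oncology medication
categories (narcotics/corticosteroids on survival; narcotics, diuretics and
proton-pump inhibitors on treatment duration); the screen should surface
them and leave the null category (antiemetics) unranked.
"""

from carelines import (
    SimConfig,
    km_fit,
    logrank,
    run_pipeline,
    screen_covariates,
    simulate_cohort,
)

sim = simulate_cohort(SimConfig(n_patients=1500, seed=3))
res = run_pipeline(sim.patients, sim.dispenses, sim.infusions,
                   sim.surgeries, sim.labs, sim.dictionary)
df = res.outcomes_frame()

for group, sdf in df.groupby("group"):
    km = km_fit(sdf["os_months"], sdf["os_event"].astype(bool))
    med = (f"{km.median_months:.1f} months "
           f"(95% CI {km.median_ci_95[0]:.1f}-{km.median_ci_95[1]:.1f})"
           if km.median_reached else "not reached")
    print(f"{group:12s} n={len(sdf):4d}  median OS {med}  "
          f"5-year survival {100 * km.survival_at[60.0]:.0f}%")

stat, p = logrank({g: (s["os_months"], s["os_event"].astype(bool))
                   for g, s in df.groupby("group")})
print(f"log-rank surgery vs non-surgery: chi2={stat:.1f}, p={p:.2g}")
print()

screened = [c for c in df.columns if c.startswith("med_")]
screen = screen_covariates(df, "dot_months", "dot_event", screened,
                           backbone_col="first_line_backbone")
print("age/sex-adjusted Cox screen on DOT (ranked by p):")
for _, row in screen.iterrows():
    star = " *" if row["significant"] else ""
    print(f"  {row['covariate']:20s} HR {row['hazard_ratio']:.2f} "
          f"({row['ci_lower']:.2f}-{row['ci_upper']:.2f})  p={row['p_value']:.2g}"
          f"  p_strat={row['p_value_stratified']:.2g}{star}")
print()
print("Starred rows are significant at alpha=0.05; p_strat refits the model")
print("stratified by chemotherapy backbone.")
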