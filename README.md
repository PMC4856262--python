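# carelines

Therapy-line inference and survival analysis for oncology claims data,
with a fully synthetic, ground-truthed test cohort.

Large HMO databases record dispenses, infusions, surgeries and labs — but
not treatment *lines*. `carelines` reconstructs per-patient treatment
timelines from such tables for the metastatic colorectal cancer (mCRC)
setting: patients starting a bevacizumab-containing first-line regimen
with a fluoropyrimidine backbone (FP alone, FP + oxaliplatin = FP-O, or
FP + irinotecan = FP-I).  It is aimed at pharmacoepidemiologists and
real-world-evidence analysts who need reproducible line segmentation,
cohort construction and outcome analyses from claims-shaped inputs.

The pipeline:

1. **Exposure intervals** — each record covers a nominal window (1 day per
   infusion, 30 days per oral dispense); per agent, gaps ≤ 30 days merge.
2. **Therapy lines** — a new line starts when a biologic is omitted or
   replaced or the chemotherapy backbone changes; terminating some agents
   while the rest of the regimen continues (FP-O→FP, FP-I→FP, or
   biologic-only maintenance) stays in-line; >30-day treatment-free gaps
   open a (flagged) resumption line.
3. **Cohort** — first-line bevacizumab, index at first administration,
   ≥ 12 months follow-up for survivors; Surgery vs Non-surgery by
   metastasectomy/definitive-RT claims; regular non-oncology medication
   use = purchases in ≥ 4 distinct months within a 12-month window;
   baseline labs from a 6-month pre-index window.
4. **Endpoints & statistics** — overall survival (OS, index→death) and
   duration of first-line treatment (DOT, pre-surgery portion for Surgery
   patients), analysed with Kaplan–Meier (median + 95% CI via log-log
   bounds), log-rank, Cox proportional hazards (Efron ties) screened one
   covariate at a time adjusted for age and sex, and ANOVA + Bonferroni.

A synthetic-cohort generator emits all six claims tables with known
ground truth (lines, groups, covariate flags, planted hazard ratios), so
every stage is testable without access to any real records.  See
`docs/methods.md` for the model and its assumptions, `docs/formats.md`
for table schemas.

## Worked example

```python
from carelines import SimConfig, simulate_cohort, run_pipeline, km_fit

sim = simulate_cohort(SimConfig(n_patients=1500, seed=3))
res = run_pipeline(sim.patients, sim.dispenses, sim.infusions,
                   sim.surgeries, sim.labs, sim.dictionary)
df = res.outcomes_frame()
for group, sdf in df.groupby("group"):
    km = km_fit(sdf["os_months"], sdf["os_event"].astype(bool))
    print(group, len(sdf), round(km.median_months, 1), km.median_ci_95)
```

prints (from `examples/04_survival_analysis.py`):

```
non_surgery  n=1273  median OS 17.0 months (95% CI 15.5-18.6)  5-year survival 7%
surgery      n= 227  median OS 43.9 months (95% CI 38.8-52.6)  5-year survival 39%
log-rank surgery vs non-surgery: chi2=112.6, p=2.6e-26

age/sex-adjusted Cox screen on DOT (ranked by p):
  med_gi_ppi           HR 1.35 (1.21-1.51)  p=1e-07  p_strat=5.3e-08 *
  med_narcotic         HR 1.39 (1.23-1.58)  p=2.6e-07  p_strat=3.3e-07 *
  med_diuretic         HR 1.29 (1.15-1.45)  p=2e-05  p_strat=9e-06 *
  med_corticosteroid   HR 1.17 (1.02-1.34)  p=0.025  p_strat=0.027 *
  med_antiemetic       HR 0.98 (0.88-1.10)  p=0.77  p_strat=0.84
```

The Surgery group lives far longer (resectable disease), and the screen
recovers the hazard ratios the generator planted on proton-pump
inhibitors, narcotics and diuretics for treatment duration while leaving
the null category (antiemetics) flat — the qualitative pattern such
real-world screens report.  Each `examples/0*.py` script demonstrates one
capability (simulation, segmentation, cohort building, survival analysis,
reporting) and prints what its numbers mean.

## Command line

```bash
carelines simulate --n 500 --seed 7 --out data/
carelines segment  --input-dir data/ --gap-days 30 --out lines.csv
carelines cohort   --input-dir data/ --out cohort.csv
carelines analyze  --cohort cohort.csv --out report/
carelines report   --cohort cohort.csv --out report/
carelines query    --cohort cohort.csv --expr "group == 'surgery'"
```

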