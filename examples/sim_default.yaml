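# Default synthetic-cohort configuration for `carelines simulate --config`.
# Every key is optional; omitted keys keep the package defaults shown here,
# which reproduce the shape of the real-world first-line-bevacizumab mCRC
# cohort the pipeline targets (~15% surgery, FP-O-heavy surgery group,
# older FP-only subgroup absent by backbone mix, 68% reaching second line).

n_patients: 500
seed: 0
window_start: 2006-09-01
window_end: 2012-12-31
cutoff: 2013-12-31

surgery_prob: 0.154
backbone_mix_surgery:     {FP: 0.0,   FP_O: 0.698, FP_I: 0.302}
backbone_mix_non_surgery: {FP: 0.072, FP_O: 0.341, FP_I: 0.587}

os_median_surgery: 60.0          # months, baseline (no covariate effects)
os_median_non_surgery: 18.7
dot_median_months: 11.4          # baseline treatment-stop hazard median
presurgery_dot_median_months: 6.1
later_line_median_months: 5.0
survival_dist: exponential       # or: weibull (see weibull_shape)

p_second_line: 0.68
p_third_line: 0.35
p_anti_egfr_second: 0.39
p_post_surgery_resumption: 0.80
p_maintenance: 0.40

covariate_prevalence: {narcotic: 0.20, corticosteroid: 0.15, diuretic: 0.25,
                       gi_ppi: 0.30, antiemetic: 0.35}
registry_prevalence: {diabetes: 0.24, hypertension: 0.53, cvd: 0.17}
# planted log hazard ratios (natural log); defaults mirror the qualitative
# screening findings this kind of study reports
log_hr_os: {narcotic: 0.4054651081, corticosteroid: 0.3364722366}
log_hr_dot: {narcotic: 0.3364722366, diuretic: 0.4054651081, gi_ppi: 0.4054651081}

infusion_cadence_days: 14
oral_cadence_days: 30
oral_fp_prob: 0.3
dropout_rate: 0.05
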