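"""Synthetic claims-cohort generator with known ground truth.

Emits the six claims tables (patients, dispenses, infusions, surgeries,
labs, drug dictionary) for a configurable metastatic-CRC-style cohort
treated with first-line bevacizumab, together with the per-patient ground
truth (therapy-line plan, Surgery/Non-surgery group, covariate flags, and
event times), so that every pipeline stage can be tested without real data.

The generative model, per patient:

* covariates (non-oncology medication categories, comorbidity registries,
  age, sex) are independent Bernoulli/Gaussian draws;
* overall survival is exponential (optionally Weibull) with the group
  baseline median scaled by ``exp(sum of planted covariate log-HRs)``;
* first-line duration is an independent exponential draw (its own planted
  log-HRs) truncated at survival — treatment cannot outlast the patient;
* the line plan places bevacizumab plus a chemotherapy backbone in line 1,
  optional bevacizumab-only maintenance at the line's tail, later lines with
  switched backbone and optionally an anti-EGFR biologic, and for Surgery
  patients a mid-first-line operation followed (usually) by a post-surgery
  resumption after a gap longer than the bridging threshold;
* infusions are emitted on a fixed cadence inside each treated interval,
  oral fluoropyrimidine and non-oncology dispenses monthly, baseline labs in
  the pre-index window; everything is truncated at death/dropout/cutoff.

All randomness flows from a single seeded :class:`numpy.random.Generator`
in fixed patient order, so a given config is byte-reproducible.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._dates import DAYS_PER_MONTH
from .data_model import (
    DispenseEvent,
    DrugDictionary,
    InfusionEvent,
    LabResult,
    Patient,
    SurgeryClaim,
)

MED_CATEGORIES = ("narcotic", "corticosteroid", "diuretic", "gi_ppi", "antiemetic")

# synthetic ATC-like codes; the canonical editable copy ships as
# carelines/data/drug_dict.csv
_DEFAULT_DICT = {
    "ONC-FPO-01": ("FP_oral", "other"),
    "ONC-FPV-01": ("FP_iv", "other"),
    "ONC-OXA-01": ("oxaliplatin", "other"),
    "ONC-IRI-01": ("irinotecan", "other"),
    "ONC-BEV-01": ("bevacizumab", "other"),
    "ONC-CET-01": ("cetuximab", "other"),
    "ONC-PAN-01": ("panitumumab", "other"),
    "NON-NAR-01": ("non_oncology", "narcotic"),
    "NON-COR-01": ("non_oncology", "corticosteroid"),
    "NON-DIU-01": ("non_oncology", "diuretic"),
    "NON-PPI-01": ("non_oncology", "gi_ppi"),
    "NON-ANT-01": ("non_oncology", "antiemetic"),
    "NON-OTH-01": ("non_oncology", "other"),
}
_CODE_BY_CLASS = {cls: code for code, (cls, _) in _DEFAULT_DICT.items()
                  if cls != "non_oncology"}
_CODE_BY_CATEGORY = {cat: code for code, (cls, cat) in _DEFAULT_DICT.items()
                     if cls == "non_oncology"}

LAB_PROFILES = {
    # test: (normal mean, elevated threshold)
    "platelets": (250.0, 400.0),
    "leukocytes": (7.0, 11.0),
    "cholesterol": (180.0, 240.0),
    "ldl": (110.0, 160.0),
    "urine_protein": (8.0, 30.0),
    "cea": (2.5, 5.0),
}


def default_dictionary() -> DrugDictionary:
    return DrugDictionary(dict(_DEFAULT_DICT))


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the shape of the real-world bevacizumab cohort this
    package targets: ~15% Surgery patients, first-line backbone mix of
    roughly 0.40 FP-O / 0.54 FP-I / 0.06 FP overall, OS medians of about 60
    (Surgery) and 18.7 (Non-surgery) months, a first-line DOT median of 11.4
    months (6.1 pre-surgery), 68% of Non-surgery patients proceeding to a
    second line, and 39% of those receiving anti-EGFR therapy.  Planted
    covariate log-hazard-ratios mirror the qualitative screening findings
    (narcotics/corticosteroids on OS; narcotics, diuretics and PPIs on DOT).
    """

    n_patients: int = 500
    seed: int = 0
    window_start: dt.date = dt.date(2006, 9, 1)
    window_end: dt.date = dt.date(2012, 12, 31)
    cutoff: dt.date = dt.date(2013, 12, 31)
    surgery_prob: float = 0.154
    backbone_mix_surgery: dict[str, float] = field(
        default_factory=lambda: {"FP": 0.0, "FP_O": 0.698, "FP_I": 0.302})
    backbone_mix_non_surgery: dict[str, float] = field(
        default_factory=lambda: {"FP": 0.072, "FP_O": 0.341, "FP_I": 0.587})
    covariate_prevalence: dict[str, float] = field(
        default_factory=lambda: {"narcotic": 0.20, "corticosteroid": 0.15,
                                 "diuretic": 0.25, "gi_ppi": 0.30,
                                 "antiemetic": 0.35})
    registry_prevalence: dict[str, float] = field(
        default_factory=lambda: {"diabetes": 0.24, "hypertension": 0.53,
                                 "cvd": 0.17})
    log_hr_os: dict[str, float] = field(
        default_factory=lambda: {"narcotic": math.log(1.5),
                                 "corticosteroid": math.log(1.4)})
    log_hr_dot: dict[str, float] = field(
        default_factory=lambda: {"narcotic": math.log(1.4),
                                 "diuretic": math.log(1.5),
                                 "gi_ppi": math.log(1.5)})
    os_median_surgery: float = 60.0
    os_median_non_surgery: float = 18.7
    dot_median_months: float = 11.4
    presurgery_dot_median_months: float = 6.1
    later_line_median_months: float = 5.0
    survival_dist: str = "exponential"       # "exponential" | "weibull"
    weibull_shape: float = 1.3
    infusion_cadence_days: int = 14
    oral_cadence_days: int = 30
    oral_fp_prob: float = 0.3
    p_second_line: float = 0.68
    p_third_line: float = 0.35
    p_anti_egfr_second: float = 0.39
    p_post_surgery_resumption: float = 0.80
    p_maintenance: float = 0.40
    maintenance_frac: float = 0.60
    p_lab_elevated: float = 0.20
    dropout_rate: float = 0.05
    age_mean: float = 65.0
    age_sd: float = 11.0
    p_male: float = 0.55

    def validate(self) -> None:
        for name, mix in (("backbone_mix_surgery", self.backbone_mix_surgery),
                          ("backbone_mix_non_surgery", self.backbone_mix_non_surgery)):
            if set(mix) != {"FP", "FP_O", "FP_I"}:
                raise ConfigError(f"{name} must cover FP, FP_O, FP_I")
            if any(not 0 <= v <= 1 for v in mix.values()):
                raise ConfigError(f"{name} proportions must lie in [0, 1]")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        probs = [self.surgery_prob, self.oral_fp_prob, self.p_second_line,
                 self.p_third_line, self.p_anti_egfr_second,
                 self.p_post_surgery_resumption, self.p_maintenance,
                 self.p_lab_elevated, self.dropout_rate, self.p_male,
                 *self.covariate_prevalence.values(),
                 *self.registry_prevalence.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        for m in (self.os_median_surgery, self.os_median_non_surgery,
                  self.dot_median_months, self.presurgery_dot_median_months,
                  self.later_line_median_months):
            if m <= 0:
                raise ConfigError("medians must be positive")
        if self.survival_dist not in ("exponential", "weibull"):
            raise ConfigError("survival_dist must be exponential or weibull")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")


@dataclass
class TrueLine:
    start: dt.date
    end: dt.date                       # truncated at observation end
    backbone: str
    biologics: frozenset[str]
    resumption: bool = False
    chemo_end: dt.date | None = None   # before end when maintenance applies


@dataclass
class PatientTruth:
    patient_id: str
    group: str
    index_date: dt.date
    first_line_backbone: str
    lines: list[TrueLine]
    surgery_date: dt.date | None
    covariates: dict[str, bool]
    registry: dict[str, bool]
    age: float
    sex: str
    os_months_raw: float               # uncensored draw
    os_months: float                   # observed, mirrors the OS endpoint
    os_event: bool
    dot_months: float                  # planned first-line DOT (pre-emission)
    dot_event: bool
    anti_egfr_after_first: bool

    @property
    def n_lines(self) -> int:
        return len(self.lines)


@dataclass
class SimulatedData:
    patients: list[Patient]
    dispenses: list[DispenseEvent]
    infusions: list[InfusionEvent]
    surgeries: list[SurgeryClaim]
    labs: list[LabResult]
    dictionary: DrugDictionary
    truth: list[PatientTruth]
    config: SimConfig

    def tables(self) -> dict[str, list]:
        return {"dispenses": self.dispenses, "infusions": self.infusions,
                "surgeries": self.surgeries, "labs": self.labs}


def _draw_duration(rng: np.random.Generator, median: float, log_hr: float,
                   dist: str, shape: float) -> float:
    """Event-time draw (months) with hazard scaled by exp(log_hr)."""
    if dist == "exponential":
        lam = math.log(2) / median * math.exp(log_hr)
        return float(rng.exponential(1.0 / lam))
    # Weibull PH: S(t) = exp(-(t/b)^k * exp(log_hr))
    b = median / math.log(2) ** (1.0 / shape)
    u = float(rng.uniform())
    return float(b * (-math.log(u) / math.exp(log_hr)) ** (1.0 / shape))


def _months_to_days(months: float) -> int:
    return max(int(round(months * DAYS_PER_MONTH)), 1)


def _grid_end(start: dt.date, months: float, cadence_days: int) -> dt.date:
    """Line end aligned to the infusion grid: the day after the last cycle.

    Treatment periods end with their final administration, so planned line
    durations are realised as whole cycles; the half-open end is the last
    infusion date + 1 day.
    """
    days = _months_to_days(months)
    cycles = max(1, int(round((days - 1) / cadence_days)))
    return start + dt.timedelta(days=cadence_days * (cycles - 1) + 1)


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = sorted(mix)
    return str(rng.choice(keys, p=[mix[k] for k in keys]))


def simulate_cohort(config: SimConfig) -> SimulatedData:
    """Generate the six claims tables plus ground truth for ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    day = dt.timedelta(days=1)
    window_days = (config.window_end - config.window_start).days

    patients: list[Patient] = []
    dispenses: list[DispenseEvent] = []
    infusions: list[InfusionEvent] = []
    surgeries: list[SurgeryClaim] = []
    labs: list[LabResult] = []
    truth: list[PatientTruth] = []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 30, 92))
        sex = "male" if rng.uniform() < config.p_male else "female"
        registry = {k: bool(rng.uniform() < p)
                    for k, p in sorted(config.registry_prevalence.items())}
        covariates = {k: bool(rng.uniform() < config.covariate_prevalence[k])
                      for k in MED_CATEGORIES}
        lp_os = sum(config.log_hr_os.get(k, 0.0) for k, v in covariates.items() if v)
        lp_dot = sum(config.log_hr_dot.get(k, 0.0) for k, v in covariates.items() if v)

        index = config.window_start + day * int(rng.integers(0, window_days + 1))
        surgery = rng.uniform() < config.surgery_prob
        group = "surgery" if surgery else "non_surgery"
        backbone1 = _choice(rng, config.backbone_mix_surgery if surgery
                            else config.backbone_mix_non_surgery)
        os_median = (config.os_median_surgery if surgery
                     else config.os_median_non_surgery)
        os_raw = _draw_duration(rng, os_median, lp_os,
                                config.survival_dist, config.weibull_shape)
        os_raw = max(os_raw, 0.2)
        death_planned = index + day * _months_to_days(os_raw)

        # --- line plan (dates; truncation applied at emission) ------------
        # Line ends sit on the infusion grid (treatment ends with the last
        # cycle).  A switch that keeps the biologic follows after a short
        # gap bridged by segmentation; replacing the biologic follows a
        # longer treatment pause (re-staging / KRAS testing before an
        # anti-EGFR agent), read as a change plus gap by the line rules.
        cad = config.infusion_cadence_days
        plan: list[TrueLine] = []
        surgery_date: dt.date | None = None
        oral_fp = rng.uniform() < config.oral_fp_prob
        if surgery:
            pre = _draw_duration(rng, config.presurgery_dot_median_months,
                                 lp_dot, config.survival_dist, config.weibull_shape)
            pre = float(np.clip(pre, 1.0, max(0.6 * os_raw, 1.0)))
            line1_end = _grid_end(index, pre, cad)
            surgery_date = line1_end + day * int(rng.integers(7, 22))
            plan.append(TrueLine(index, line1_end, backbone1,
                                 frozenset({"bevacizumab"})))
            if rng.uniform() < config.p_post_surgery_resumption:
                start2 = surgery_date + day * int(rng.integers(45, 121))
                dur2 = _draw_duration(rng, config.later_line_median_months, 0.0,
                                      config.survival_dist, config.weibull_shape)
                end2 = _grid_end(start2, max(dur2, 0.5), cad)
                if end2 < death_planned:
                    plan.append(TrueLine(start2, end2, backbone1,
                                         frozenset({"bevacizumab"}),
                                         resumption=True))
            dot_planned = (line1_end - index).days / DAYS_PER_MONTH
        else:
            dot_raw = _draw_duration(rng, config.dot_median_months, lp_dot,
                                     config.survival_dist, config.weibull_shape)
            line1_end = _grid_end(index, min(max(dot_raw, 0.5), os_raw), cad)
            if backbone1 == "FP" and (line1_end - index).days < 31:
                oral_fp = False   # too short for an oral refill cycle: IV 5FU
            dot_planned = (line1_end - index).days / DAYS_PER_MONTH
            line1 = TrueLine(index, line1_end, backbone1,
                             frozenset({"bevacizumab"}))
            if (rng.uniform() < config.p_maintenance
                    and dot_planned > 4.0 and backbone1 != "FP"):
                line1.chemo_end = index + day * int(
                    round((line1_end - index).days * config.maintenance_frac))
            plan.append(line1)
            prev_end, prev_backbone = line1_end, backbone1
            prev_bio = "bevacizumab"
            for line_no, p_line in ((2, config.p_second_line),
                                    (3, config.p_third_line)):
                if rng.uniform() >= p_line:
                    break
                if prev_backbone == "FP":
                    backbone_n = "FP_O" if rng.uniform() < 0.5 else "FP_I"
                else:
                    backbone_n = "FP_I" if prev_backbone == "FP_O" else "FP_O"
                if line_no == 2 and rng.uniform() < config.p_anti_egfr_second:
                    bio = ("cetuximab" if rng.uniform() < 0.85 else "panitumumab")
                else:
                    bio = "bevacizumab"
                if bio == prev_bio:
                    gap = int(rng.integers(7, 29))      # bridged switch
                else:
                    gap = int(rng.integers(35, 91))     # pause before new biologic
                start_n = prev_end + day * gap
                dur_n = _draw_duration(rng, config.later_line_median_months, 0.0,
                                       config.survival_dist, config.weibull_shape)
                end_n = _grid_end(start_n, max(dur_n, 1.0), cad)
                if start_n + day * 7 >= death_planned:
                    break
                plan.append(TrueLine(start_n, end_n, backbone_n, frozenset({bio})))
                prev_end, prev_backbone, prev_bio = end_n, backbone_n, bio

        # --- observation end ----------------------------------------------
        died = death_planned <= config.cutoff
        death_date = death_planned if died else None
        if died:
            last_seen = death_planned
        elif rng.uniform() < config.dropout_rate:
            min_seen = index + day * _months_to_days(12.5)
            span = max((config.cutoff - min_seen).days, 1)
            last_seen = min_seen + day * int(rng.integers(0, span))
        else:
            last_seen = config.cutoff
        trunc = min(last_seen, config.cutoff)

        # --- emit oncology events -----------------------------------------
        observed_lines: list[TrueLine] = []
        for ln in plan:
            if ln.start >= trunc:
                continue
            end = min(ln.end, trunc)
            chemo_end = min(ln.chemo_end or end, end)
            cad = config.infusion_cadence_days
            # coverage end of the (possibly truncated) biologic infusion
            # grid; oral refills must not outlast it
            grid_covend = ln.start + day * (
                cad * (((end - ln.start).days - 1) // cad) + 1)
            oral_cap = min(chemo_end, grid_covend)
            agents_chemo: list[tuple[str, bool]] = []   # (class, oral?)
            if ln.backbone in ("FP", "FP_O", "FP_I"):
                agents_chemo.append(("FP_oral", True) if oral_fp
                                    else (("FP_iv", False)))
            if ln.backbone == "FP_O":
                agents_chemo.append(("oxaliplatin", False))
            elif ln.backbone == "FP_I":
                agents_chemo.append(("irinotecan", False))
            for cls, oral in agents_chemo:
                code = _CODE_BY_CLASS[cls]
                step = config.oral_cadence_days if oral else cad
                d = ln.start
                while d < chemo_end:
                    if oral:
                        # a refill is only purchased if its supplied days fit
                        # before the chemo stop; the nominal coverage window
                        # must not outlive the rest of the regimen
                        if d + day * step <= oral_cap:
                            dispenses.append(DispenseEvent(pid, d, code))
                    else:
                        infusions.append(InfusionEvent(pid, d, code))
                    d += day * step
            for bio in sorted(ln.biologics):
                code = _CODE_BY_CLASS[bio]
                d = ln.start
                while d < end:
                    infusions.append(InfusionEvent(pid, d, code))
                    d += day * cad
            observed_lines.append(replace(ln, end=end,
                                          chemo_end=None if ln.chemo_end is None
                                          else chemo_end))

        if surgery and surgery_date is not None and surgery_date <= trunc:
            proc = str(rng.choice(["liver_metastasectomy", "lung_metastasectomy",
                                   "definitive_rt"], p=[0.70, 0.25, 0.05]))
            surgeries.append(SurgeryClaim(pid, surgery_date, proc))
        observed_surgery = (surgery and surgery_date is not None
                            and surgery_date <= trunc)

        # --- non-oncology dispenses ---------------------------------------
        for cat in MED_CATEGORIES:
            code = _CODE_BY_CATEGORY[cat]
            if covariates[cat]:
                d = index - day * 180
                stop = min(trunc, index + day * 540)
                while d < stop:
                    dispenses.append(DispenseEvent(pid, d, code))
                    d += day * 30
            elif rng.uniform() < 0.4:
                for _ in range(int(rng.integers(1, 4))):
                    offset = int(rng.integers(-360, 361))
                    d = index + day * offset
                    if d < trunc:
                        dispenses.append(DispenseEvent(pid, d, code))

        # --- labs ----------------------------------------------------------
        for test, (normal, threshold) in LAB_PROFILES.items():
            elevated = rng.uniform() < config.p_lab_elevated
            if elevated:
                value = threshold * (1.1 + 0.5 * rng.uniform())
            else:
                value = normal * (0.7 + 0.5 * rng.uniform())
            labs.append(LabResult(pid, index - day * int(rng.integers(7, 151)),
                                  test, round(value, 1)))
            if rng.uniform() < 0.3:   # stale pre-window value, must be ignored
                labs.append(LabResult(pid, index - day * int(rng.integers(200, 320)),
                                      test, round(normal, 1)))

        birth = index - day * int(round(age * 365.25))
        patients.append(Patient(pid, sex, birth, death_date, last_seen,
                                frozenset(k for k, v in registry.items() if v)))

        os_obs = ((death_planned - index).days / DAYS_PER_MONTH if died
                  else (min(config.cutoff, last_seen) - index).days / DAYS_PER_MONTH)
        dot_end_planned = index + day * _months_to_days(dot_planned)
        dot_event = dot_end_planned <= trunc or died
        # the observable group label: surgery only if the claim was emitted
        # (a planned operation can fall beyond the observation end)
        observed_group = "surgery" if observed_surgery else "non_surgery"
        truth.append(PatientTruth(
            patient_id=pid, group=observed_group, index_date=index,
            first_line_backbone=backbone1,
            lines=observed_lines,
            surgery_date=surgery_date if observed_surgery else None,
            covariates=covariates, registry=registry, age=age, sex=sex,
            os_months_raw=os_raw, os_months=os_obs, os_event=died,
            dot_months=min(dot_planned, os_raw),
            dot_event=dot_event,
            anti_egfr_after_first=any(
                ln.biologics & {"cetuximab", "panitumumab"}
                for ln in observed_lines[1:]),
        ))

    dispenses.sort(key=lambda r: (r.patient_id, r.date, r.drug_code))
    infusions.sort(key=lambda r: (r.patient_id, r.date, r.agent_code))
    labs.sort(key=lambda r: (r.patient_id, r.date, r.test))
    return SimulatedData(patients, dispenses, infusions, surgeries, labs,
                         default_dictionary(), truth, config)


def simulate_outcomes(config: SimConfig, n: int,
                      seed: int | None = None) -> pd.DataFrame:
    """Outcome-level draws from the same generative model, without claims
    emission — for statistical simulations (coverage, type-I error, power).

    Returns one row per patient with age, sex (1 = male), the covariate
    flags, uncensored ``os_months`` (all events), and ``dot_months`` with
    death-before-treatment-end treated as censoring for the treatment-stop
    hazard (``dot_event`` = 0 when survival truncates the draw).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    flags = {k: (rng.uniform(size=n) < config.covariate_prevalence[k])
             for k in MED_CATEGORIES}
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 30, 92)
    male = rng.uniform(size=n) < config.p_male
    lp_os = sum(flags[k] * config.log_hr_os.get(k, 0.0) for k in MED_CATEGORIES)
    lp_dot = sum(flags[k] * config.log_hr_dot.get(k, 0.0) for k in MED_CATEGORIES)
    med_os = config.os_median_non_surgery
    if config.survival_dist == "exponential":
        os_m = rng.exponential(1.0, size=n) / (math.log(2) / med_os * np.exp(lp_os))
        dot_raw = rng.exponential(1.0, size=n) / (
            math.log(2) / config.dot_median_months * np.exp(lp_dot))
    else:
        k = config.weibull_shape
        b_os = med_os / math.log(2) ** (1.0 / k)
        b_dot = config.dot_median_months / math.log(2) ** (1.0 / k)
        os_m = b_os * (-np.log(rng.uniform(size=n)) / np.exp(lp_os)) ** (1.0 / k)
        dot_raw = b_dot * (-np.log(rng.uniform(size=n)) / np.exp(lp_dot)) ** (1.0 / k)
    df = pd.DataFrame({
        "age": age, "sex": male.astype(int),
        **{k: v.astype(int) for k, v in flags.items()},
        "os_months": os_m, "os_event": 1,
        "dot_months": np.minimum(dot_raw, os_m),
        "dot_event": (dot_raw <= os_m).astype(int),
    })
    return df


# --- controlled corruption -------------------------------------------------

@dataclass
class CorruptionLog:
    duplicates: dict[str, list[int]] = field(default_factory=dict)
    post_death: dict[str, list[int]] = field(default_factory=dict)


def corrupt(tables: dict[str, list], patients: Sequence[Patient],
            duplicate_rate: float = 0.0, post_death_rate: float = 0.0,
            seed: int = 0) -> tuple[dict[str, list], CorruptionLog]:
    """Inject controlled messiness to exercise the validators.

    ``duplicate_rate`` duplicates existing rows; ``post_death_rate`` adds,
    per deceased patient, an infusion dated after death.  Appended row
    indices (0-based, in the returned lists) are recorded in the log so
    validator output can be checked exactly.  All rates 0 is the identity.
    """
    for rate in (duplicate_rate, post_death_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {name: list(records) for name, records in tables.items()}
    log = CorruptionLog()
    if duplicate_rate > 0:
        for name in sorted(out):
            records = out[name]
            n = len(records)
            picks = np.flatnonzero(rng.uniform(size=n) < duplicate_rate)
            for idx in picks:
                records.append(records[int(idx)])
            if len(picks):
                log.duplicates[name] = list(range(n, n + len(picks)))
    if post_death_rate > 0 and "infusions" in out:
        records = out["infusions"]
        added: list[int] = []
        for pat in patients:
            if pat.death_date is None:
                continue
            if rng.uniform() < post_death_rate:
                records.append(InfusionEvent(
                    pat.patient_id,
                    pat.death_date + dt.timedelta(days=int(rng.integers(10, 90))),
                    _CODE_BY_CLASS["bevacizumab"]))
                added.append(len(records) - 1)
        if added:
            log.post_death["infusions"] = added
    return out, log
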