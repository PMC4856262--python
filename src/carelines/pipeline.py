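"""End-to-end orchestration: claims tables -> lines -> cohort -> outcomes.

Thin glue over the per-stage modules; this is what the CLI and the
validation scripts drive.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import cohort as cohort_mod
from .cohort import CohortMember, Exclusion, last_followup_date
from .data_model import (
    DispenseEvent,
    DrugDictionary,
    InfusionEvent,
    LabResult,
    Patient,
    SurgeryClaim,
)
from .line_segmentation import (
    DEFAULT_GAP_DAYS,
    DEFAULT_INFUSION_COVERAGE_DAYS,
    DEFAULT_ORAL_COVERAGE_DAYS,
    TherapyLine,
    events_from_claims,
    segment_patient,
)
from .outcomes import SurvivalOutcome, compute_outcomes
from .synthetic_data import MED_CATEGORIES


@dataclass
class StudyParams:
    window: tuple[dt.date, dt.date] = cohort_mod.DEFAULT_WINDOW
    cutoff: dt.date = cohort_mod.DEFAULT_CUTOFF
    min_followup_months: int = cohort_mod.DEFAULT_MIN_FOLLOWUP_MONTHS
    lab_lookback_days: int = cohort_mod.DEFAULT_LAB_LOOKBACK_DAYS
    policy_date: dt.date = cohort_mod.DEFAULT_POLICY_DATE
    gap_days: int = DEFAULT_GAP_DAYS
    oral_coverage_days: int = DEFAULT_ORAL_COVERAGE_DAYS
    infusion_coverage_days: int = DEFAULT_INFUSION_COVERAGE_DAYS
    med_categories: tuple[str, ...] = MED_CATEGORIES


@dataclass
class PipelineResult:
    lines_by_patient: dict[str, list[TherapyLine]]
    members: list[CohortMember]
    exclusions: list[Exclusion]
    outcomes: list[SurvivalOutcome]
    params: StudyParams
    patients_by_id: dict[str, Patient] = field(default_factory=dict)

    def outcomes_frame(self) -> pd.DataFrame:
        """Analysis table: one row per member with outcomes and covariates."""
        members = {m.patient_id: m for m in self.members}
        rows = []
        for out in self.outcomes:
            m = members[out.patient_id]
            pat = self.patients_by_id[out.patient_id]
            age_years = (m.index_date - pat.birth_date).days / 365.25
            row = {
                "patient_id": out.patient_id,
                "os_months": out.os_months, "os_event": int(out.os_event),
                "dot_months": out.dot_months, "dot_event": int(out.dot_event),
                "group": m.group, "first_line_backbone": m.first_line_backbone,
                "age": age_years, "sex": int(pat.sex == "male"),
                "max_line_number": m.max_line_number,
                "received_both_aggressive": int(m.received_both_aggressive),
                "anti_egfr_after_index": int(m.anti_egfr_after_index),
            }
            for cat in self.params.med_categories:
                row[f"med_{cat}"] = int(cat in m.regular_meds)
            for test, value in m.baseline_labs.items():
                row[f"lab_{test}"] = value
            rows.append(row)
        return pd.DataFrame(rows)


def segment_all(dispenses: Sequence[DispenseEvent],
                infusions: Sequence[InfusionEvent],
                dictionary: DrugDictionary,
                params: StudyParams = StudyParams(),
                ) -> dict[str, list[TherapyLine]]:
    events = events_from_claims(dispenses, infusions, dictionary,
                                params.oral_coverage_days,
                                params.infusion_coverage_days)
    by_patient: dict[str, list] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    return {pid: segment_patient(evs, params.gap_days, params.gap_days)
            for pid, evs in by_patient.items()}


def run_pipeline(patients: Sequence[Patient],
                 dispenses: Sequence[DispenseEvent],
                 infusions: Sequence[InfusionEvent],
                 surgeries: Sequence[SurgeryClaim],
                 labs: Sequence[LabResult],
                 dictionary: DrugDictionary,
                 params: StudyParams = StudyParams()) -> PipelineResult:
    lines_by_patient = segment_all(dispenses, infusions, dictionary, params)

    bev_dates: dict[str, list[dt.date]] = {}
    for inf in infusions:
        if dictionary.agent_class(inf.agent_code) == "bevacizumab":
            bev_dates.setdefault(inf.patient_id, []).append(inf.date)

    members, exclusions = cohort_mod.select_cohort(
        patients, lines_by_patient, bev_dates,
        window=params.window, cutoff=params.cutoff,
        min_followup_months=params.min_followup_months)

    patients_by_id = {p.patient_id: p for p in patients}
    surgeries_by_pid: dict[str, list[SurgeryClaim]] = {}
    for c in surgeries:
        surgeries_by_pid.setdefault(c.patient_id, []).append(c)
    labs_by_pid: dict[str, list[LabResult]] = {}
    for lab in labs:
        labs_by_pid.setdefault(lab.patient_id, []).append(lab)
    disp_by_pid: dict[str, list[DispenseEvent]] = {}
    for d in dispenses:
        disp_by_pid.setdefault(d.patient_id, []).append(d)

    outcomes: list[SurvivalOutcome] = []
    for m in members:
        pat = patients_by_id[m.patient_id]
        lines = lines_by_patient[m.patient_id]
        claims = surgeries_by_pid.get(m.patient_id, [])
        m.group, m.surgery_date, _ = cohort_mod.classify_surgery(m, claims)
        followup = last_followup_date(pat, params.cutoff)
        m.regular_meds = cohort_mod.regular_meds_for(
            m, disp_by_pid.get(m.patient_id, []), dictionary, followup,
            params.med_categories)
        m.baseline_labs = cohort_mod.baseline_labs(
            labs_by_pid.get(m.patient_id, []), m.index_date,
            params.lab_lookback_days)
        m.received_both_aggressive = cohort_mod.received_both_aggressive(lines)
        m.anti_egfr_after_index, m.anti_egfr_post_policy = \
            cohort_mod.anti_egfr_exposure(lines, params.policy_date)
        m.review_flag = cohort_mod.flag_for_review(pat, lines, claims)
        outcomes.append(compute_outcomes(m, pat, lines, params.cutoff))

    return PipelineResult(lines_by_patient, members, exclusions, outcomes,
                          params, patients_by_id)
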