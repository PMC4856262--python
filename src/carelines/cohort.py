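"""Cohort eligibility, surgery classification, and baseline covariates.

The study cohort is defined by treatment: patients whose first therapy line
contains bevacizumab, with the index date anchored at the first bevacizumab
administration, an index date inside the accrual window, and — for patients
alive at the study cutoff — a minimum follow-up from the index date.

Beyond eligibility this module derives the per-patient covariates used by
the analyses: Surgery vs Non-surgery classification, regular use of
non-oncology medication categories (purchase in at least 4 distinct calendar
months within some 12-consecutive-calendar-month window spanning one year
pre-index through last follow-up), most-recent baseline laboratory values in
a pre-index lookback window, sequential use of both aggressive backbones,
anti-EGFR exposure in later lines, and a manual-review flag for patients
with a long treatment-free tail and no liver-resection billing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._dates import add_months, month_index
from .data_model import (
    ANTI_EGFR_CLASSES,
    DispenseEvent,
    DrugDictionary,
    LabResult,
    Patient,
    SurgeryClaim,
)
from .line_segmentation import TherapyLine, first_line

DEFAULT_WINDOW = (dt.date(2006, 9, 1), dt.date(2012, 12, 31))
DEFAULT_CUTOFF = dt.date(2013, 12, 31)
DEFAULT_MIN_FOLLOWUP_MONTHS = 12
DEFAULT_LAB_LOOKBACK_DAYS = 183
DEFAULT_POLICY_DATE = dt.date(2008, 12, 1)
DEFAULT_REVIEW_GAP_MONTHS = 15

QUALIFYING_PROCEDURES = frozenset(
    {"liver_metastasectomy", "lung_metastasectomy", "definitive_rt"})


@dataclass
class CohortMember:
    patient_id: str
    index_date: dt.date
    group: str                               # "surgery" | "non_surgery"
    first_line_backbone: str
    surgery_date: dt.date | None = None
    regular_meds: set[str] = field(default_factory=set)
    baseline_labs: dict[str, float] = field(default_factory=dict)
    received_both_aggressive: bool = False
    anti_egfr_after_index: bool = False
    anti_egfr_post_policy: bool = False
    review_flag: bool = False
    max_line_number: int = 0


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


def index_date_for(lines: Sequence[TherapyLine],
                   bev_event_dates: Sequence[dt.date]) -> dt.date | None:
    """First bevacizumab administration date, if line 1 contains bevacizumab."""
    line1 = first_line(lines)
    if line1 is None or "bevacizumab" not in line1.biologics:
        return None
    dates = [d for d in bev_event_dates if line1.start <= d < line1.end]
    return min(dates) if dates else None


def select_cohort(patients: Iterable[Patient],
                  lines_by_patient: Mapping[str, Sequence[TherapyLine]],
                  bev_dates_by_patient: Mapping[str, Sequence[dt.date]],
                  window: tuple[dt.date, dt.date] = DEFAULT_WINDOW,
                  cutoff: dt.date = DEFAULT_CUTOFF,
                  min_followup_months: int = DEFAULT_MIN_FOLLOWUP_MONTHS,
                  ) -> tuple[list[CohortMember], list[Exclusion]]:
    """Apply the eligibility rules; returns members plus reason-coded exclusions.

    Inclusion requires: bevacizumab in line 1, index date (first bevacizumab
    administration) inside ``window``, and either death on or before
    ``cutoff`` or observation through ``index + min_followup_months``.
    """
    members: list[CohortMember] = []
    exclusions: list[Exclusion] = []
    for pat in patients:
        lines = lines_by_patient.get(pat.patient_id, [])
        line1 = first_line(lines)
        if line1 is None:
            exclusions.append(Exclusion(pat.patient_id, "no_systemic_therapy"))
            continue
        if "bevacizumab" not in line1.biologics:
            exclusions.append(Exclusion(pat.patient_id, "no_first_line_bevacizumab"))
            continue
        index = index_date_for(lines, bev_dates_by_patient.get(pat.patient_id, []))
        if index is None:
            exclusions.append(Exclusion(pat.patient_id, "no_first_line_bevacizumab"))
            continue
        if not (window[0] <= index <= window[1]):
            exclusions.append(Exclusion(pat.patient_id, "index_outside_window"))
            continue
        died_by_cutoff = pat.death_date is not None and pat.death_date <= cutoff
        if not died_by_cutoff:
            if pat.last_seen_date < add_months(index, min_followup_months):
                exclusions.append(Exclusion(pat.patient_id, "insufficient_followup"))
                continue
        members.append(CohortMember(
            patient_id=pat.patient_id,
            index_date=index,
            group="non_surgery",
            first_line_backbone=line1.backbone,
            max_line_number=max(ln.line_number for ln in lines),
        ))
    return members, exclusions


def classify_surgery(member: CohortMember,
                     surgery_claims: Sequence[SurgeryClaim],
                     ) -> tuple[str, dt.date | None, list[str]]:
    """Surgery iff a qualifying procedure occurs on or after the index date.

    Returns ``(group, surgery_date, warnings)``; ``surgery_date`` is the
    first qualifying claim.  Qualifying claims dated before the index are
    ignored with a warning.
    """
    warnings: list[str] = []
    qualifying = sorted(
        (c for c in surgery_claims
         if c.patient_id == member.patient_id and c.procedure in QUALIFYING_PROCEDURES),
        key=lambda c: c.date)
    post_index = [c for c in qualifying if c.date >= member.index_date]
    if any(c.date < member.index_date for c in qualifying):
        warnings.append("qualifying_surgery_before_index_ignored")
    if post_index:
        return "surgery", post_index[0].date, warnings
    return "non_surgery", None, warnings


def regular_med_flag(dispense_dates: Iterable[dt.date],
                     index_date: dt.date,
                     last_followup: dt.date) -> bool:
    """Regular use: >=4 distinct calendar months of purchase inside some
    window of 12 consecutive calendar months, starting no earlier than one
    year before the index and ending no later than last follow-up."""
    lo = month_index(add_months(index_date, -12))
    hi = month_index(last_followup)
    if hi - lo < 11:            # no complete 12-month window fits the span
        return False
    months = sorted({month_index(d) for d in dispense_dates if lo <= month_index(d) <= hi})
    if len(months) < 4:
        return False
    # window of 12 consecutive months <=> 4th-next distinct month within 11
    for i in range(len(months) - 3):
        if months[i + 3] - months[i] <= 11 and months[i] >= lo and months[i + 3] <= hi:
            return True
    return False


def regular_meds_for(member: CohortMember,
                     dispenses: Sequence[DispenseEvent],
                     dictionary: DrugDictionary,
                     last_followup: dt.date,
                     categories: Iterable[str]) -> set[str]:
    by_cat: dict[str, list[dt.date]] = {}
    for d in dispenses:
        if d.patient_id != member.patient_id:
            continue
        if dictionary.agent_class(d.drug_code) != "non_oncology":
            continue
        cat = dictionary.category(d.drug_code)
        by_cat.setdefault(cat, []).append(d.date)
    return {cat for cat in categories
            if regular_med_flag(by_cat.get(cat, []), member.index_date, last_followup)}


def baseline_labs(labs: Sequence[LabResult],
                  index_date: dt.date,
                  lookback_days: int = DEFAULT_LAB_LOOKBACK_DAYS,
                  ) -> dict[str, float]:
    """Most recent value per test inside ``[index - lookback, index)``."""
    window_start = index_date - dt.timedelta(days=lookback_days)
    best: dict[str, LabResult] = {}
    for lab in labs:
        if not (window_start <= lab.date < index_date):
            continue
        cur = best.get(lab.test)
        if cur is None or lab.date > cur.date:
            best[lab.test] = lab
    return {test: lab.value for test, lab in best.items()}


def flag_for_review(patient: Patient,
                    lines: Sequence[TherapyLine],
                    surgery_claims: Sequence[SurgeryClaim],
                    gap_months: int = DEFAULT_REVIEW_GAP_MONTHS) -> bool:
    """Flag for oncologist review: alive at last follow-up, no
    liver-resection billing, and a systemic-therapy-free gap of at least
    ``gap_months`` months (after the last line, or between lines)."""
    if patient.death_date is not None:
        return False
    if any(c.patient_id == patient.patient_id and c.procedure == "liver_metastasectomy"
           for c in surgery_claims):
        return False
    if not lines:
        return False
    ordered = sorted(lines, key=lambda ln: ln.start)
    gaps: list[bool] = []
    for a, b in zip(ordered[:-1], ordered[1:]):
        gaps.append(b.start >= add_months(a.end, gap_months))
    gaps.append(patient.last_seen_date >= add_months(ordered[-1].end, gap_months))
    return any(gaps)


def anti_egfr_exposure(lines: Sequence[TherapyLine],
                       policy_date: dt.date = DEFAULT_POLICY_DATE,
                       ) -> tuple[bool, bool]:
    """(anti-EGFR in any line >= 2, any line >= 2 starting after policy_date).

    The policy date marks when wild-type KRAS status became mandatory for
    anti-EGFR therapy; lines after it identify the assessable subgroup.
    """
    later = [ln for ln in lines if ln.line_number >= 2]
    exposed = any(ln.biologics & ANTI_EGFR_CLASSES for ln in later)
    post_policy = any(ln.start > policy_date for ln in later)
    return exposed, post_policy


def received_both_aggressive(lines: Sequence[TherapyLine]) -> bool:
    """Ever treated with an oxaliplatin-based and an irinotecan-based line."""
    backbones = {ln.backbone for ln in lines}
    return "FP_O" in backbones and "FP_I" in backbones


def last_followup_date(patient: Patient, cutoff: dt.date) -> dt.date:
    """End of observation: min(death, cutoff, last activity)."""
    candidates = [cutoff, patient.last_seen_date]
    if patient.death_date is not None:
        candidates.append(patient.death_date)
    return min(candidates)
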