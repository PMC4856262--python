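"""Primary endpoints: overall survival and duration of first-line treatment.

OS runs from the index date (first bevacizumab administration) to death,
censored at the study cutoff or at last contact if earlier.  DOT is the
length of the first-line bevacizumab-containing treatment period; for
Surgery patients it covers the pre-surgery portion only.  Durations are
reported in months using a fixed 30.44 days/month conversion.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

from ._dates import days_to_months
from .cohort import CohortMember
from .data_model import Patient
from .line_segmentation import TherapyLine, first_line


@dataclass(frozen=True)
class SurvivalOutcome:
    patient_id: str
    os_months: float
    os_event: bool
    dot_months: float
    dot_event: bool

    def __post_init__(self) -> None:
        if self.os_months < 0 or self.dot_months < 0:
            raise ValueError("durations must be nonnegative")


def compute_os(member: CohortMember, patient: Patient,
               cutoff: dt.date) -> tuple[float, bool]:
    """(os_months, event).  Event on death on/before cutoff, else censored at
    min(cutoff, last_seen)."""
    index = member.index_date
    if patient.death_date is not None and patient.death_date <= cutoff:
        if patient.death_date < index:
            raise ValueError(
                f"{member.patient_id}: death precedes index date")
        return days_to_months((patient.death_date - index).days), True
    censor = min(cutoff, patient.last_seen_date)
    return days_to_months(max((censor - index).days, 0)), False


def compute_dot(member: CohortMember, lines: Sequence[TherapyLine],
                cutoff: dt.date,
                observation_end: dt.date | None = None) -> tuple[float, bool]:
    """(dot_months, event) for the first-line bevacizumab-containing regimen.

    The interval runs from the index date to the earliest of the first
    line's end, the surgery date (Surgery group), and the cutoff; the
    outcome is an event unless the cutoff itself truncates the interval.
    Nominal dispensing coverage can outlast the observed record, so the
    interval is also capped at ``observation_end`` (death date, or last
    contact for patients alive at cutoff).
    """
    line1 = first_line(lines)
    if line1 is None or "bevacizumab" not in line1.biologics:
        raise ValueError(f"{member.patient_id}: no first-line bevacizumab")
    end = line1.end
    if member.surgery_date is not None:
        end = min(end, member.surgery_date)
    if observation_end is not None:
        end = min(end, observation_end)
    if end <= cutoff:
        event = True
    else:
        end = cutoff
        event = False
    return days_to_months(max((end - member.index_date).days, 0)), event


def compute_outcomes(member: CohortMember, patient: Patient,
                     lines: Sequence[TherapyLine],
                     cutoff: dt.date) -> SurvivalOutcome:
    os_m, os_e = compute_os(member, patient, cutoff)
    obs_end = (patient.death_date if patient.death_date is not None
               else patient.last_seen_date)
    dot_m, dot_e = compute_dot(member, lines, cutoff, obs_end)
    return SurvivalOutcome(member.patient_id, os_m, os_e, dot_m, dot_e)
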