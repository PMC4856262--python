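"""Therapy-line inference from dated drug-exposure events.

The timeline of systemic treatment is reconstructed in three steps:

1. :func:`build_exposure_intervals` — each dispensing or infusion record
   contributes a nominal coverage window (1 day for an infusion, 30 days for
   an oral dispense by default); per agent class, windows whose uncovered gap
   is at most ``gap_days`` are merged into half-open exposure intervals.
2. :func:`derive_regimen_states` — the treated span is partitioned at every
   interval boundary and each slice is classified by its chemotherapy
   backbone (FP alone, FP plus oxaliplatin = FP-O, FP plus irinotecan = FP-I)
   and its set of active biologics (bevacizumab, cetuximab, panitumumab).
3. :func:`segment_lines` — numbered therapy lines.  A new line starts when a
   biologic is omitted or replaced, or when the backbone class changes,
   except that stopping some chemotherapy agents while the rest of the line's
   composition continues (FP-O -> FP, FP-I -> FP, or chemo stopping entirely
   under a continuing biologic) stays within the current line.  Treatment
   gaps of more than ``short_gap_days`` start a new line flagged as a
   resumption when the composition is unchanged.

All intervals are half-open ``[start, end)`` calendar-day intervals.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .data_model import (
    ANTI_EGFR_CLASSES,
    BIOLOGIC_CLASSES,
    FP_CLASSES,
    ONCOLOGY_AGENT_CLASSES,
    DispenseEvent,
    DrugDictionary,
    InfusionEvent,
)

DEFAULT_GAP_DAYS = 30
DEFAULT_ORAL_COVERAGE_DAYS = 30
DEFAULT_INFUSION_COVERAGE_DAYS = 1

BACKBONES = ("FP", "FP_O", "FP_I", "none")


@dataclass(frozen=True)
class AgentEvent:
    """A dated administration of an oncology agent with nominal coverage."""

    patient_id: str
    date: dt.date
    agent_class: str
    coverage_days: int = 1


@dataclass(frozen=True)
class ExposureInterval:
    patient_id: str
    agent_class: str
    start: dt.date
    end: dt.date  # half-open

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")


@dataclass(frozen=True)
class RegimenState:
    start: dt.date
    end: dt.date
    backbone: str                      # FP | FP_O | FP_I | none
    biologics: frozenset[str]
    warnings: tuple[str, ...] = ()


@dataclass
class TherapyLine:
    line_number: int
    start: dt.date
    end: dt.date
    backbone: str                      # the line's defining backbone
    biologics: frozenset[str]          # union of biologics seen in the line
    states: list[RegimenState] = field(default_factory=list)
    resumption: bool = False
    warnings: list[str] = field(default_factory=list)


def events_from_claims(dispenses: Iterable[DispenseEvent],
                       infusions: Iterable[InfusionEvent],
                       dictionary: DrugDictionary,
                       oral_coverage_days: int = DEFAULT_ORAL_COVERAGE_DAYS,
                       infusion_coverage_days: int = DEFAULT_INFUSION_COVERAGE_DAYS,
                       ) -> list[AgentEvent]:
    """Pool pharmacy dispenses and infusion claims into oncology agent events.

    Oral fluoropyrimidine dispenses cover ``oral_coverage_days``; infusions
    cover ``infusion_coverage_days``.  Non-oncology and unmapped codes are
    skipped (non-oncology exposure is handled by the cohort module).
    """
    events: list[AgentEvent] = []
    for d in dispenses:
        cls = dictionary.agent_class(d.drug_code)
        if cls in ONCOLOGY_AGENT_CLASSES:
            events.append(AgentEvent(d.patient_id, d.date, cls, oral_coverage_days))
    for inf in infusions:
        cls = dictionary.agent_class(inf.agent_code)
        if cls in ONCOLOGY_AGENT_CLASSES:
            events.append(AgentEvent(inf.patient_id, inf.date, cls,
                                     infusion_coverage_days))
    return events


def build_exposure_intervals(events: Iterable[AgentEvent],
                             gap_days: int = DEFAULT_GAP_DAYS,
                             ) -> list[ExposureInterval]:
    """Merge per-agent coverage windows into exposure intervals.

    Each event covers ``[date, date + coverage_days)``.  Within one patient
    and agent class, consecutive windows separated by an uncovered gap of at
    most ``gap_days`` days are bridged into a single interval.
    """
    if gap_days < 0:
        raise ValueError("gap_days must be >= 0")
    by_key: dict[tuple[str, str], list[AgentEvent]] = {}
    for ev in events:
        if ev.coverage_days < 1:
            raise ValueError("coverage_days must be >= 1")
        by_key.setdefault((ev.patient_id, ev.agent_class), []).append(ev)
    intervals: list[ExposureInterval] = []
    for (pid, cls), evs in by_key.items():
        evs = sorted(evs, key=lambda e: e.date)
        start = evs[0].date
        end = evs[0].date + dt.timedelta(days=evs[0].coverage_days)
        for ev in evs[1:]:
            ev_end = ev.date + dt.timedelta(days=ev.coverage_days)
            if (ev.date - end).days <= gap_days:
                end = max(end, ev_end)
            else:
                intervals.append(ExposureInterval(pid, cls, start, end))
                start, end = ev.date, ev_end
        intervals.append(ExposureInterval(pid, cls, start, end))
    intervals.sort(key=lambda iv: (iv.patient_id, iv.start, iv.agent_class))
    return intervals


def _classify_backbone(active: set[str]) -> tuple[str, tuple[str, ...]]:
    """Backbone class for a set of simultaneously active agent classes."""
    has_fp = bool(active & FP_CLASSES)
    has_ox = "oxaliplatin" in active
    has_ir = "irinotecan" in active
    warnings: tuple[str, ...] = ()
    if has_ox and has_ir:
        backbone = "FP_O"
        warnings += ("triplet_chemotherapy",)
    elif has_ox:
        backbone = "FP_O"
    elif has_ir:
        backbone = "FP_I"
    elif has_fp:
        backbone = "FP"
    else:
        backbone = "none"
    if (has_ox or has_ir) and not has_fp:
        warnings += ("non_fp_chemotherapy_without_fp",)
    return backbone, warnings


def derive_regimen_states(intervals: Sequence[ExposureInterval],
                          ) -> list[RegimenState]:
    """Partition one patient's treated span into constant-composition states.

    The timeline is cut at every interval boundary; each treated slice is
    classified by backbone and active biologic set; contiguous slices with
    identical composition are merged.  Untreated gaps are not represented as
    states (states separated by a gap may share a composition).
    """
    if not intervals:
        return []
    pids = {iv.patient_id for iv in intervals}
    if len(pids) > 1:
        raise ValueError("derive_regimen_states expects a single patient")
    bounds = sorted({iv.start for iv in intervals} | {iv.end for iv in intervals})
    states: list[RegimenState] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        active = {iv.agent_class for iv in intervals
                  if iv.start < hi and iv.end > lo}
        if not active:
            continue
        backbone, warns = _classify_backbone(active)
        bio = frozenset(active & BIOLOGIC_CLASSES)
        if backbone == "none" and not bio:
            continue
        prev = states[-1] if states else None
        if (prev is not None and prev.end == lo
                and prev.backbone == backbone and prev.biologics == bio):
            states[-1] = replace(prev, end=hi,
                                 warnings=tuple(dict.fromkeys(prev.warnings + warns)))
        else:
            states.append(RegimenState(lo, hi, backbone, bio, warns))
    return states


def _is_line_change(line: TherapyLine, state: RegimenState) -> bool:
    """Apply the line-change rules to the next contiguous state.

    A change is: a biologic omitted or replaced, or a backbone change other
    than de-escalation within the line's composition.  Biologic additions
    never split; chemo-free (backbone ``none``) states under continuing
    biologics never split; returning to the line's defining backbone after a
    de-escalation or chemo holiday continues the line.
    """
    if line.biologics - state.biologics:
        return True                     # biologic omitted (or replaced)
    sb, lb = state.backbone, line.backbone
    if sb == lb or sb == "none":
        return False
    if lb == "none":
        # line so far had no chemo backbone; chemo starting sets it
        return False
    if sb == "FP" and lb in ("FP_O", "FP_I"):
        return False                    # de-escalation stays in line
    return True                         # FP->FP_O/FP_I escalation, FP_O<->FP_I


def segment_lines(states: Sequence[RegimenState],
                  short_gap_days: int = DEFAULT_GAP_DAYS) -> list[TherapyLine]:
    """Group regimen states into numbered therapy lines.

    Gaps of at most ``short_gap_days`` between states are bridged; longer
    gaps always start a new line, flagged ``resumption`` when the composition
    is unchanged.  Within bridged continuity a new line starts exactly on a
    disqualifying composition change (see :func:`_is_line_change`).
    """
    if short_gap_days < 0:
        raise ValueError("short_gap_days must be >= 0")
    lines: list[TherapyLine] = []
    cur: TherapyLine | None = None
    for st in sorted(states, key=lambda s: s.start):
        if cur is not None:
            gap = (st.start - cur.end).days
            long_gap = gap > short_gap_days
            change = _is_line_change(cur, st)
            if long_gap or change:
                lines.append(cur)
                cur = None
                resumption = long_gap and not change
        if cur is None:
            cur = TherapyLine(
                line_number=len(lines) + 1,
                start=st.start, end=st.end,
                backbone=st.backbone, biologics=st.biologics,
                states=[st],
                resumption=bool(lines) and resumption if lines else False,
                warnings=list(st.warnings),
            )
            # a fresh line defined by a chemo-free biologic state has no
            # backbone yet; the first chemo state will set it
            continue
        # state continues the current line
        cur.end = max(cur.end, st.end)
        cur.biologics = cur.biologics | st.biologics
        if cur.backbone == "none" and st.backbone != "none":
            cur.backbone = st.backbone
        cur.states.append(st)
        for w in st.warnings:
            if w not in cur.warnings:
                cur.warnings.append(w)
    if cur is not None:
        lines.append(cur)
    return lines


def segment_patient(events: Iterable[AgentEvent],
                    gap_days: int = DEFAULT_GAP_DAYS,
                    short_gap_days: int | None = None) -> list[TherapyLine]:
    """Full pipeline for one patient's agent events."""
    if short_gap_days is None:
        short_gap_days = gap_days
    intervals = build_exposure_intervals(events, gap_days)
    states = derive_regimen_states(intervals)
    return segment_lines(states, short_gap_days)


def first_line(lines: Sequence[TherapyLine]) -> TherapyLine | None:
    """Line number 1, or ``None`` for an untreated patient."""
    if not lines:
        return None
    numbers = [ln.line_number for ln in lines]
    if numbers != sorted(numbers) or numbers[0] != 1:
        raise ValueError("lines are not numbered consecutively from 1")
    for a, b in zip(lines[:-1], lines[1:]):
        if b.start < a.end:
            raise ValueError("therapy lines overlap")
    return lines[0]


def max_line_number(lines: Sequence[TherapyLine]) -> int:
    return max((ln.line_number for ln in lines), default=0)


def has_anti_egfr_after_first(lines: Sequence[TherapyLine]) -> bool:
    return any(ln.line_number >= 2 and (ln.biologics & ANTI_EGFR_CLASSES)
               for ln in lines)
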