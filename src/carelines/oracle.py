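"""Brute-force day-resolution reference for exposure merging and line rules.

This module re-implements the therapy-timeline rules literally, one calendar
day at a time, with no interval arithmetic: every event paints its coverage
days onto a per-agent day grid, uncovered runs of at most ``gap_days`` days
are filled in, each day is classified by the agents active on it, and the
line rules are applied walking day by day.  It is deliberately simple and
slow, and serves as an independent cross-check of
:mod:`carelines.line_segmentation` in the test-suite and the validation
script; it is never used by the pipeline itself.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Sequence

import numpy as np

from .data_model import BIOLOGIC_CLASSES, FP_CLASSES
from .line_segmentation import AgentEvent


def _day_grid(events: Sequence[AgentEvent], gap_days: int,
              ) -> tuple[dt.date, dict[str, np.ndarray], int]:
    origin = min(ev.date for ev in events)
    horizon = max((ev.date - origin).days + ev.coverage_days for ev in events)
    pad = gap_days + 1
    grids: dict[str, np.ndarray] = {}
    for ev in events:
        grid = grids.setdefault(ev.agent_class, np.zeros(horizon + pad, dtype=bool))
        off = (ev.date - origin).days
        grid[off:off + ev.coverage_days] = True
    # bridge uncovered runs of <= gap_days between covered days
    for grid in grids.values():
        covered = np.flatnonzero(grid)
        for a, b in zip(covered[:-1], covered[1:]):
            if 1 < b - a <= gap_days + 1:
                grid[a:b] = True
    return origin, grids, horizon + pad


def day_compositions(events: Sequence[AgentEvent], gap_days: int,
                     ) -> list[tuple[dt.date, str, frozenset[str]]]:
    """Per treated day: (day, backbone, biologics), in calendar order."""
    if not events:
        return []
    origin, grids, n = _day_grid(events, gap_days)
    out: list[tuple[dt.date, str, frozenset[str]]] = []
    for i in range(n):
        active = {cls for cls, grid in grids.items() if grid[i]}
        if not active:
            continue
        has_fp = bool(active & FP_CLASSES)
        if "oxaliplatin" in active:
            backbone = "FP_O"
        elif "irinotecan" in active:
            backbone = "FP_I"
        elif has_fp:
            backbone = "FP"
        else:
            backbone = "none"
        bio = frozenset(active & BIOLOGIC_CLASSES)
        if backbone == "none" and not bio:
            continue
        out.append((origin + dt.timedelta(days=i), backbone, bio))
    return out


def segment_lines_daily(events: Iterable[AgentEvent],
                        gap_days: int = 30,
                        short_gap_days: int | None = None,
                        ) -> list[dict]:
    """Day-by-day line segmentation.

    Returns one dict per line: ``{"start", "end", "backbone", "biologics",
    "resumption"}`` with ``end`` exclusive.  The line-change rules are the
    same as the interval implementation: a new line on biologic loss or on a
    backbone change that is not a de-escalation to FP (or to chemo-free under
    a continuing biologic), and on any treatment-free run longer than
    ``short_gap_days`` days.
    """
    events = list(events)
    if short_gap_days is None:
        short_gap_days = gap_days
    days = day_compositions(events, gap_days)
    lines: list[dict] = []
    cur: dict | None = None
    prev_day: dt.date | None = None
    for day, backbone, bio in days:
        if cur is not None:
            gap = (day - prev_day).days - 1   # untreated days in between
            long_gap = gap > short_gap_days
            bio_lost = bool(cur["biologics"] - bio)
            lb = cur["backbone"]
            if backbone == lb or backbone == "none" or lb == "none":
                backbone_change = False
            elif backbone == "FP" and lb in ("FP_O", "FP_I"):
                backbone_change = False
            else:
                backbone_change = True
            if long_gap or bio_lost or backbone_change:
                lines.append(cur)
                cur = {"start": day, "end": day + dt.timedelta(days=1),
                       "backbone": backbone, "biologics": bio,
                       "resumption": long_gap and not (bio_lost or backbone_change)}
            else:
                cur["end"] = day + dt.timedelta(days=1)
                cur["biologics"] = cur["biologics"] | bio
                if cur["backbone"] == "none" and backbone != "none":
                    cur["backbone"] = backbone
        else:
            cur = {"start": day, "end": day + dt.timedelta(days=1),
                   "backbone": backbone, "biologics": bio, "resumption": False}
        prev_day = day
    if cur is not None:
        lines.append(cur)
    return lines
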