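"""Shared fixtures and independent reference helpers for the test-suite."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from carelines._dates import add_months, month_index
from carelines.line_segmentation import AgentEvent
from carelines.pipeline import run_pipeline
from carelines.synthetic_data import SimConfig, simulate_cohort

AGENT_CLASSES = ["FP_oral", "FP_iv", "oxaliplatin", "irinotecan",
                 "bevacizumab", "cetuximab", "panitumumab"]


def random_agent_events(rng: np.random.Generator,
                        max_events: int = 40,
                        max_agents: int = 5,
                        span_days: int = 1096,
                        origin: dt.date = dt.date(2010, 1, 1),
                        ) -> list[AgentEvent]:
    """A random single-patient event history for oracle comparisons."""
    n = int(rng.integers(1, max_events + 1))
    agents = rng.choice(AGENT_CLASSES, size=int(rng.integers(1, max_agents + 1)),
                        replace=False)
    events = []
    for _ in range(n):
        cls = str(rng.choice(agents))
        date = origin + dt.timedelta(days=int(rng.integers(0, span_days)))
        coverage = 30 if cls == "FP_oral" else 1
        events.append(AgentEvent("X", date, cls, coverage))
    return events


def brute_force_regular_use(dispense_dates, index_date, last_followup) -> bool:
    """Literal enumeration of every 12-consecutive-calendar-month window."""
    lo = month_index(add_months(index_date, -12))
    hi = month_index(last_followup)
    months = {month_index(d) for d in dispense_dates}
    for w in range(lo, hi - 10):
        if w + 11 > hi:
            break
        if sum(1 for m in months if w <= m <= w + 11) >= 4:
            return True
    return False


@pytest.fixture(scope="session")
def small_sim():
    """One fixed synthetic cohort shared across tests (300 patients)."""
    return simulate_cohort(SimConfig(n_patients=300, seed=20240901))


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    sim = small_sim
    return run_pipeline(sim.patients, sim.dispenses, sim.infusions,
                        sim.surgeries, sim.labs, sim.dictionary)
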