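"""Survival estimation and covariate screening.

Kaplan-Meier product-limit curves with median survival and 95% confidence
intervals (log-log transformed curve bounds), log-rank group comparison,
Cox proportional-hazards models with Efron handling of tied event times
(claims data are day-granular, so ties are common), one-covariate-at-a-time
screening adjusted for age and sex (optionally stratified by chemotherapy
backbone), and one-way ANOVA with Bonferroni correction for subgroup
characteristic comparisons.

Model fitting is delegated to lifelines and scipy; this module fixes the
conventions (tie handling, CI transform, screening design) and the result
containers used across the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats as sps

NOT_REACHED = math.inf


@dataclass
class KMEstimate:
    event_times: np.ndarray
    survival_probs: np.ndarray
    n_at_risk: np.ndarray
    median_months: float                   # inf when not reached
    median_ci_95: tuple[float, float]
    survival_at: dict[float, float] = field(default_factory=dict)

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median_months)

    def survival_probability(self, horizon: float) -> float:
        idx = np.searchsorted(self.event_times, horizon, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


@dataclass(frozen=True)
class CoxRow:
    covariate: str
    hazard_ratio: float
    ci_95: tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_95[0] <= self.hazard_ratio <= self.ci_95[1]):
            raise ValueError("CI must contain the point estimate")


@dataclass
class CoxResult:
    rows: dict[str, CoxRow]
    adjusted_for: tuple[str, ...]
    n: int
    n_events: int

    def __getitem__(self, covariate: str) -> CoxRow:
        return self.rows[covariate]


class DegenerateInputError(ValueError):
    pass


def km_fit(durations: Sequence[float], events: Sequence[bool],
           horizons: Sequence[float] = (60.0,)) -> KMEstimate:
    """Product-limit survival estimate with median and 95% CI.

    The median is the earliest time with survival <= 0.5 ("not reached",
    represented as ``inf``, when the curve never falls that far); its CI is
    read off the log-log-transformed confidence bounds of the curve.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise DegenerateInputError("km_fit requires at least one observation")
    if np.all(durations == 0) and not np.any(events):
        raise DegenerateInputError("all durations zero with no events")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    probs = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMEstimate(
        event_times=times,
        survival_probs=probs,
        n_at_risk=at_risk,
        median_months=median,
        median_ci_95=(lo, hi),
        survival_at={h: float(kmf.survival_function_at_times(h).iloc[0])
                     for h in horizons},
    )


def logrank(groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]],
            ) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("logrank requires at least two groups")
    durations, events, labels = [], [], []
    for label, (durs, evs) in groups.items():
        durs = list(durs)
        if not durs:
            raise ValueError(f"group {label!r} is empty")
        durations.extend(durs)
        events.extend(evs)
        labels.extend([label] * len(durs))
    if not any(events):
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(np.asarray(durations, dtype=float),
                                    np.asarray(labels),
                                    np.asarray(events, dtype=bool))
    return float(res.test_statistic), float(res.p_value)


def cox_fit(data: pd.DataFrame,
            duration_col: str, event_col: str,
            covariates: Sequence[str],
            strata: Sequence[str] | None = None) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) returning HR, Wald 95% CI
    and p per covariate."""
    for cov in covariates:
        if data[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    cols = [duration_col, event_col, *covariates, *(strata or [])]
    cph = CoxPHFitter()
    try:
        cph.fit(data[cols], duration_col=duration_col, event_col=event_col,
                strata=list(strata) if strata else None)
    except ConvergenceError as exc:
        raise ConvergenceError(
            f"Cox fit failed to converge for covariates {list(covariates)}: {exc}"
        ) from exc
    summary = cph.summary
    rows = {}
    for cov in covariates:
        row = summary.loc[cov]
        rows[cov] = CoxRow(
            covariate=cov,
            hazard_ratio=float(row["exp(coef)"]),
            ci_95=(float(row["exp(coef) lower 95%"]),
                   float(row["exp(coef) upper 95%"])),
            p_value=float(row["p"]),
        )
    return CoxResult(rows=rows, adjusted_for=tuple(covariates),
                     n=len(data), n_events=int(data[event_col].sum()))


def screen_covariates(data: pd.DataFrame,
                      duration_col: str, event_col: str,
                      screened: Sequence[str],
                      adjust: Sequence[str] = ("age", "sex"),
                      backbone_col: str | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """One age/sex-adjusted Cox model per screened covariate, ranked by p.

    When ``backbone_col`` is given, each model is refit stratified by
    chemotherapy backbone and the stratified p-value is reported alongside.
    Covariates that are constant in the data are skipped.
    """
    records = []
    for cov in screened:
        if data[cov].nunique() < 2:
            continue
        res = cox_fit(data, duration_col, event_col, [cov, *adjust])
        row = res[cov]
        rec = {
            "covariate": cov,
            "hazard_ratio": row.hazard_ratio,
            "ci_lower": row.ci_95[0],
            "ci_upper": row.ci_95[1],
            "p_value": row.p_value,
            "significant": row.p_value < alpha,
        }
        if backbone_col is not None:
            strat = cox_fit(data, duration_col, event_col, [cov, *adjust],
                            strata=[backbone_col])
            rec["hazard_ratio_stratified"] = strat[cov].hazard_ratio
            rec["p_value_stratified"] = strat[cov].p_value
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    if not out.empty:
        out = out.sort_values("p_value", ignore_index=True)
    return out


def anova_bonferroni(values_by_subgroup: Mapping[str, Sequence[float]],
                     n_comparisons: int) -> tuple[float, float]:
    """One-way ANOVA F-test p-value, raw and Bonferroni-corrected
    (``min(1, p * n_comparisons)``)."""
    groups = [np.asarray(v, dtype=float) for v in values_by_subgroup.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 subgroups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance in every subgroup")
    _, p = sps.f_oneway(*groups)
    p = float(p)
    return p, min(1.0, p * n_comparisons)
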