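"""Cohort summary tables and the query surface.

Produces the two standard study tables — patient characteristics by stratum
(group x first-line backbone) and treatment patterns / clinical outcomes —
plus a simple filter-expression query over the analysis table.  Percentages
are computed with an explicit numerator and denominator and rounded half-up
(1 decimal by default; integer style available for treatment-pattern rows).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import km_fit

STRATA_BACKBONES = ("FP_O", "FP_I", "FP")


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * n / d rounded half-up to ``decimals`` places; 0 when d == 0."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP)
    return float(val)


def _stratum_frames(df: pd.DataFrame) -> list[tuple[str, str, pd.DataFrame]]:
    """(group, backbone-or-'all', rows) in fixed presentation order."""
    out = []
    for group in ("surgery", "non_surgery"):
        gdf = df[df["group"] == group]
        for backbone in STRATA_BACKBONES:
            sdf = gdf[gdf["first_line_backbone"] == backbone]
            if len(sdf):
                out.append((group, backbone, sdf))
        out.append((group, "all", gdf))
    return out


def summarize_cohort(df: pd.DataFrame,
                     med_categories: Sequence[str] = (),
                     decimals: int = 1) -> pd.DataFrame:
    """Patient-characteristics summary per (group, backbone) stratum.

    ``df`` is the pipeline analysis table.  Percent denominators are
    explicit columns; within-group strata use the group total as parent,
    group totals use the cohort total.
    """
    if df.empty:
        return pd.DataFrame()
    n_total = len(df)
    rows = []
    for group, backbone, sdf in _stratum_frames(df):
        parent = len(df[df["group"] == group]) if backbone != "all" else n_total
        n = len(sdf)
        row = {
            "group": group, "backbone": backbone,
            "n": n, "parent_n": parent,
            "percent_of_parent": percent(n, parent, decimals),
            "n_male": int((sdf["sex"] == 1).sum()),
            "pct_male": percent(int((sdf["sex"] == 1).sum()), n, decimals) if n else 0.0,
            "age_median": float(sdf["age"].median()) if n else np.nan,
            "age_mean": float(sdf["age"].mean()) if n else np.nan,
            "age_sd": float(sdf["age"].std()) if n > 1 else np.nan,
        }
        for cat in med_categories:
            col = f"med_{cat}"
            k = int(sdf[col].sum()) if col in sdf else 0
            row[f"n_{cat}"] = k
            row[f"pct_{cat}"] = percent(k, n, decimals) if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def treatment_outcome_table(df: pd.DataFrame,
                            horizon_months: float = 60.0,
                            integer_percents: bool = True) -> pd.DataFrame:
    """Treatment patterns and clinical outcomes per stratum.

    Median first-line DOT, patients proceeding to a second line (n and
    percent of the stratum), censored count, KM median OS with 95% CI, and
    the survival rate at ``horizon_months`` read off the KM curve.
    """
    if df.empty:
        return pd.DataFrame()
    decimals = 0 if integer_percents else 1
    rows = []
    for group, backbone, sdf in _stratum_frames(df):
        n = len(sdf)
        if n == 0:
            continue
        km = km_fit(sdf["os_months"], sdf["os_event"].astype(bool),
                    horizons=(horizon_months,))
        n_second = int((sdf["max_line_number"] >= 2).sum())
        rows.append({
            "group": group, "backbone": backbone, "n": n,
            "median_dot_months": float(sdf["dot_months"].median()),
            "n_second_line": n_second,
            "pct_second_line": percent(n_second, n, decimals),
            "n_censored": int((sdf["os_event"] == 0).sum()),
            "median_os_months": km.median_months,
            "os_ci_lower": km.median_ci_95[0],
            "os_ci_upper": km.median_ci_95[1],
            f"survival_at_{horizon_months:g}m_pct": percent(
                int(round(km.survival_at[horizon_months] * 10000)), 10000,
                decimals),
        })
    return pd.DataFrame(rows)


def subsequent_line_counts(df: pd.DataFrame,
                           integer_percents: bool = True) -> pd.DataFrame:
    """Per-stratum count and percent of patients reaching a second line."""
    decimals = 0 if integer_percents else 1
    rows = []
    for group, backbone, sdf in _stratum_frames(df):
        n = len(sdf)
        k = int((sdf["max_line_number"] >= 2).sum()) if n else 0
        rows.append({"group": group, "backbone": backbone, "n": n,
                     "n_second_line": k,
                     "pct_second_line": percent(k, n, decimals) if n else 0.0})
    return pd.DataFrame(rows)


def query_cohort(df: pd.DataFrame, expr: str) -> pd.DataFrame:
    """Filter the analysis table with a pandas query expression.

    Examples: ``"group == 'surgery'"``, ``"med_gi_ppi == 1 and os_event == 1"``.
    """
    return df.query(expr)
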