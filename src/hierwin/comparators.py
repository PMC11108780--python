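"""Conventional time-to-first-event analyses for side-by-side comparison.

For each composite or single endpoint the module reports events per arm,
event rates per 100 patient-years with exact Poisson confidence intervals,
and the inverse hazard ratio (1/HR, so that a value above 1 favours the
treated arm, directionally aligned with the win ratio) from a Cox model
stratified by diabetes status (and trial, in pooled data). Person-time runs
to the fixed follow-up window — consistent with the censoring-extension rule
used by the win engine, a participant without an event contributes the full
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .trial import CONTROL, DAYS_PER_YEAR, TREATED

#: Endpoint label -> component event-day columns of the tier table.
ENDPOINT_COMPONENTS: dict[str, tuple[str, ...]] = {
    "composite: death, ESKD, eGFR decline >=40%": (
        "death_day", "eskd_day", "decline40_day",
    ),
    "composite: death, ESKD, eGFR decline >=50%": (
        "death_day", "eskd_day", "decline50_day",
    ),
    "all-cause mortality": ("death_day",),
    "ESKD or eGFR <15": ("eskd_day",),
    "eGFR decline >=57%": ("decline57_day",),
    "eGFR decline >=50%": ("decline50_day",),
    "eGFR decline >=40%": ("decline40_day",),
}


@dataclass
class ConventionalResult:
    endpoint: str
    events_treated: int
    events_control: int
    rate_treated: float
    rate_treated_ci: tuple[float, float]
    rate_control: float
    rate_control_ci: tuple[float, float]
    inv_hr: float | None
    inv_hr_ci: tuple[float, float] | None
    p_value: float | None
    estimable: bool


def first_event_table(
    tier_table: pd.DataFrame, components: tuple[str, ...]
) -> pd.DataFrame:
    """Per participant: time-to-first component event and event indicator,
    with non-events censored at the fixed window."""
    days = tier_table[list(components)].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        first = np.nanmin(days, axis=1)
    window = tier_table["window_days"].to_numpy(float)
    event = ~np.isnan(first)
    duration = np.where(event, first, window)
    return pd.DataFrame(
        {
            "id": tier_table["id"].to_numpy(),
            "arm": tier_table["arm"].to_numpy(),
            "diabetes": tier_table["diabetes"].to_numpy(bool),
            "trial": tier_table["trial"].to_numpy(),
            "duration": np.maximum(duration, 0.5),  # Cox needs positive times
            "event": event,
        }
    )


def _poisson_rate_ci(events: int, person_years: float, level: float = 0.95
                     ) -> tuple[float, float]:
    """Exact (chi-squared) CI for a rate per 100 patient-years."""
    a = 1 - level
    lo = stats.chi2.ppf(a / 2, 2 * events) / 2 if events > 0 else 0.0
    hi = stats.chi2.ppf(1 - a / 2, 2 * events + 2) / 2
    return 100 * lo / person_years, 100 * hi / person_years


def event_rate(surv: pd.DataFrame, arm: str) -> tuple[int, float, tuple[float, float]]:
    sub = surv[surv["arm"] == arm]
    events = int(sub["event"].sum())
    py = float(sub["duration"].sum()) / DAYS_PER_YEAR
    rate = 100.0 * events / py
    return events, rate, _poisson_rate_ci(events, py)


def inverse_hazard_ratio(
    surv: pd.DataFrame, strata_cols: tuple[str, ...] = ("diabetes", "trial")
) -> tuple[float, tuple[float, float], float] | None:
    """Stratified Cox 1/HR with 95% CI and p; None when not estimable."""
    if surv.groupby("arm")["event"].sum().min() == 0 or len(surv["arm"].unique()) < 2:
        return None
    df = surv.copy()
    df["treated"] = (df["arm"] == TREATED).astype(float)
    strata = [c for c in strata_cols if df[c].nunique() > 1]
    for c in strata:
        # boolean stratum labels would be misread as indexers downstream
        df[c] = df[c].astype("category").cat.codes
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df[["duration", "event", "treated"] + strata],
            duration_col="duration",
            event_col="event",
            strata=strata or None,
        )
    hr = float(np.exp(cph.params_["treated"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["treated"]).to_numpy(float)
    p = float(cph.summary.loc["treated", "p"])
    return 1.0 / hr, (1.0 / hi, 1.0 / lo), p


def conventional_endpoints(
    tier_table: pd.DataFrame,
    strata_cols: tuple[str, ...] = ("diabetes", "trial"),
    endpoints: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Rates and 1/HRs for the conventional composite and single endpoints."""
    endpoints = endpoints or ENDPOINT_COMPONENTS
    rows = []
    for label, components in endpoints.items():
        cols = [c for c in components if c in tier_table.columns]
        if not cols:
            continue
        surv = first_event_table(tier_table, tuple(cols))
        ev_t, rate_t, ci_t = event_rate(surv, TREATED)
        ev_c, rate_c, ci_c = event_rate(surv, CONTROL)
        cox = inverse_hazard_ratio(surv, strata_cols)
        rows.append(
            ConventionalResult(
                endpoint=label,
                events_treated=ev_t,
                events_control=ev_c,
                rate_treated=rate_t,
                rate_treated_ci=ci_t,
                rate_control=rate_c,
                rate_control_ci=ci_c,
                inv_hr=None if cox is None else cox[0],
                inv_hr_ci=None if cox is None else cox[1],
                p_value=None if cox is None else cox[2],
                estimable=cox is not None,
            )
        )
    return pd.DataFrame(
        [
            {
                "endpoint": r.endpoint,
                "events_treated": r.events_treated,
                "events_control": r.events_control,
                "rate_treated": r.rate_treated,
                "rate_treated_lo": r.rate_treated_ci[0],
                "rate_treated_hi": r.rate_treated_ci[1],
                "rate_control": r.rate_control,
                "rate_control_lo": r.rate_control_ci[0],
                "rate_control_hi": r.rate_control_ci[1],
                "inv_hr": np.nan if r.inv_hr is None else r.inv_hr,
                "inv_hr_lo": np.nan if r.inv_hr_ci is None else r.inv_hr_ci[0],
                "inv_hr_hi": np.nan if r.inv_hr_ci is None else r.inv_hr_ci[1],
                "p_value": np.nan if r.p_value is None else r.p_value,
                "estimable": r.estimable,
            }
            for r in rows
        ]
    )


def km_curves(
    tier_table: pd.DataFrame, components: tuple[str, ...]
) -> pd.DataFrame:
    """Kaplan-Meier event-free survival per arm for one endpoint."""
    surv = first_event_table(tier_table, components)
    frames = []
    for arm in (CONTROL, TREATED):
        sub = surv[surv["arm"] == arm]
        km = KaplanMeierFitter()
        km.fit(sub["duration"], sub["event"], label=arm)
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["arm"] = arm
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)
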