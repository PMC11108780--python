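"""Derivation of the six-tier hierarchical composite kidney outcome.

Tiers, in descending clinical importance:

1. all-cause mortality;
2. ESKD or an observed eGFR < 15 ml/min/1.73m^2 at a scheduled visit;
3. decline in eGFR >= 57% from the randomisation value;
4. decline >= 50%;
5. decline >= 40%;
6. participant-level eGFR slope (continuous; filled in by the slope model).

Decline events are evaluated at scheduled visits only, first occurrence, not
required to be sustained. All time-to-event tiers are truncated at the
trial's fixed follow-up window; a participant censored before the window is
treated as followed to exactly the window (closed boundary: an event on the
window day counts). Participants without a baseline eGFR are excluded and
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial import ParticipantRecord, TrialDesign

logger = logging.getLogger(__name__)

TIME_TO_EVENT = "time_to_event"
CONTINUOUS = "continuous"


class MissingBaselineError(ValueError):
    """Raised when a decline tier is derived for a participant with no baseline."""


@dataclass(frozen=True)
class TierSpec:
    """One level of the hierarchy."""

    tier_index: int
    kind: str
    label: str
    column: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (TIME_TO_EVENT, CONTINUOUS):
            raise ValueError(f"unknown tier kind {self.kind!r}")
        if self.threshold is not None and not 0 < self.threshold < 1:
            raise ValueError("decline threshold must be a fraction in (0, 1)")


MAIN_TIERS: tuple[TierSpec, ...] = (
    TierSpec(1, TIME_TO_EVENT, "all-cause mortality", "death_day"),
    TierSpec(2, TIME_TO_EVENT, "ESKD or eGFR <15", "eskd_day"),
    TierSpec(3, TIME_TO_EVENT, "eGFR decline >=57%", "decline57_day", 0.57),
    TierSpec(4, TIME_TO_EVENT, "eGFR decline >=50%", "decline50_day", 0.50),
    TierSpec(5, TIME_TO_EVENT, "eGFR decline >=40%", "decline40_day", 0.40),
    TierSpec(6, CONTINUOUS, "eGFR slope", "slope"),
)

#: Named tier models: the main hierarchy and the three sensitivity variants
#: (1: drop the >=40% decline tier; 2: additionally drop the slope tier,
#: making ties possible; 3: drop all-cause mortality).
TIER_MODELS: dict[str, tuple[TierSpec, ...]] = {
    "main": MAIN_TIERS,
    "model1": tuple(t for t in MAIN_TIERS if t.column != "decline40_day"),
    "model2": tuple(
        t for t in MAIN_TIERS if t.column not in ("decline40_day", "slope")
    ),
    "model3": tuple(t for t in MAIN_TIERS if t.column != "death_day"),
}


def tier_model(name: str) -> tuple[TierSpec, ...]:
    try:
        return TIER_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown tier model {name!r}; valid options: {sorted(TIER_MODELS)}"
        ) from None


def validate_tiers(tiers: tuple[TierSpec, ...] | list[TierSpec]) -> None:
    """Check ordering and at-most-one trailing continuous tier."""
    if not tiers:
        raise ValueError("empty tier list")
    cont = [t for t in tiers if t.kind == CONTINUOUS]
    if len(cont) > 1:
        raise ValueError("at most one continuous tier allowed")
    if cont and tiers[-1].kind != CONTINUOUS:
        raise ValueError("the continuous tier must be last")
    idx = [t.tier_index for t in tiers]
    if len(set(idx)) != len(idx) or sorted(idx) != idx:
        raise ValueError("tier indices must be unique and ascending")


def derive_decline_event(record: ParticipantRecord, threshold: float) -> float | None:
    """Day of the first scheduled visit with a fractional decline from
    baseline of at least ``threshold``; ``None`` if never met."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if record.baseline_egfr is None:
        raise MissingBaselineError(record.id)
    base = record.baseline_egfr
    for day, egfr in record.visits:
        if day <= 0:
            continue
        if (base - egfr) / base >= threshold:
            return day
    return None


def derive_eskd_event(record: ParticipantRecord) -> float | None:
    """Earlier of the recorded ESKD day and the first visit with eGFR < 15."""
    candidates = [record.eskd_day] if record.eskd_day is not None else []
    for day, egfr in record.visits:
        if egfr < 15.0:
            candidates.append(day)
            break
    return min(candidates) if candidates else None


def apply_fixed_window(
    event_day: float | None, last_contact_day: float, window: float
) -> tuple[float | None, float]:
    """Truncate an event at the fixed follow-up window.

    Events after the window are discarded; the boundary is closed (an event
    on the window day counts). Every participant's effective follow-up is the
    window itself — censoring earlier than the window is treated as censoring
    at the window, so the returned follow-up ignores ``last_contact_day``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if last_contact_day < 0 or (event_day is not None and event_day < 0):
        raise ValueError("days must be non-negative")
    if event_day is not None and event_day <= window:
        return event_day, float(window)
    return None, float(window)


def build_tier_table(
    cohort: list[ParticipantRecord],
    tiers: tuple[TierSpec, ...] = MAIN_TIERS,
    design: TrialDesign | None = None,
    window: float | None = None,
) -> pd.DataFrame:
    """One row per non-excluded participant with windowed per-tier event days.

    Participants lacking a baseline eGFR are excluded (and counted in the
    ``n_excluded_missing_baseline`` attribute). Columns for decline tiers are
    nested by construction: a >=57% event implies >=50% and >=40% events at
    the same or an earlier visit.
    """
    validate_tiers(tiers)
    if not cohort:
        raise ValueError("empty cohort")
    if window is None:
        if design is None:
            raise ValueError("either design or window is required")
        window = float(design.fixed_window_days)

    rows = []
    excluded = 0
    for rec in cohort:
        if rec.baseline_egfr is None:
            excluded += 1
            continue
        row: dict[str, object] = {
            "id": rec.id,
            "arm": rec.arm,
            "trial": rec.trial,
            "diabetes": rec.diabetes,
            "baseline_egfr": rec.baseline_egfr,
            "window_days": window,
        }
        for tier in tiers:
            if tier.kind != TIME_TO_EVENT:
                continue
            if tier.column == "death_day":
                raw = rec.death_day
            elif tier.column == "eskd_day":
                raw = derive_eskd_event(rec)
            elif tier.threshold is not None:
                raw = derive_decline_event(rec, tier.threshold)
            else:  # pragma: no cover - guarded by TierSpec construction
                raise ValueError(f"tier {tier.label!r} has no derivation rule")
            day, _ = apply_fixed_window(raw, rec.last_contact_day, window)
            row[tier.column] = np.nan if day is None else day
        rows.append(row)

    if excluded:
        logger.info("excluded %d participant(s) without baseline eGFR", excluded)
    columns = ["id", "arm", "trial", "diabetes", "baseline_egfr", "window_days"] + [
        t.column for t in tiers if t.kind == TIME_TO_EVENT
    ]
    table = pd.DataFrame(rows, columns=columns)
    if any(t.kind == CONTINUOUS for t in tiers):
        table["slope"] = np.nan
    table.attrs["n_excluded_missing_baseline"] = excluded
    table.attrs["window_days"] = window
    return table


def build_pooled_tier_table(
    cohorts: dict[str, tuple[list[ParticipantRecord], TrialDesign]],
    tiers: tuple[TierSpec, ...] = MAIN_TIERS,
) -> pd.DataFrame:
    """Concatenate per-trial tier tables, each windowed at its own horizon."""
    parts = []
    excluded = 0
    for _, (cohort, design) in cohorts.items():
        tab = build_tier_table(cohort, tiers, design)
        excluded += tab.attrs["n_excluded_missing_baseline"]
        parts.append(tab)
    pooled = pd.concat(parts, ignore_index=True)
    pooled.attrs["n_excluded_missing_baseline"] = excluded
    return pooled
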