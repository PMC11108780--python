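"""Synthetic two-arm trial cohorts with longitudinal eGFR and survival events.

The generator emulates the statistical structure that the hierarchical
kidney-outcome analysis assumes: a baseline eGFR truncated at the trial
eligibility floor, an acute treatment-induced eGFR dip realised linearly up to
the first post-randomisation visit (the "knot"), a per-participant chronic
linear decline thereafter, additive visit-level measurement noise, and
exponential death/ESKD/dropout processes with arm-specific hazards.

Two built-in designs mirror the visit schedules and fixed follow-up horizons
of a 720-day HFrEF-style trial and a 1,080-day HFpEF-style trial (calendar
months converted at 30 days/month).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30

TREATED = "treated"
CONTROL = "control"

#: eGFR values are clipped at this physiological floor (ml/min/1.73m^2).
EGFR_MIN = 1.0


class ConfigurationError(ValueError):
    """Invalid design or cohort configuration."""


@dataclass(frozen=True)
class TrialDesign:
    """Visit schedule and fixed follow-up horizon of one trial.

    ``visit_days`` must be strictly increasing and start at 0 (randomisation);
    the acute phase ends at the first post-randomisation visit.
    """

    name: str
    visit_days: tuple[int, ...]
    fixed_window_days: int

    def __post_init__(self) -> None:
        days = tuple(self.visit_days)
        if len(days) < 2:
            raise ConfigurationError("need at least randomisation and one follow-up visit")
        if days[0] != 0:
            raise ConfigurationError("first visit must be day 0 (randomisation)")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError("visit_days must be strictly increasing")
        if self.fixed_window_days < days[-1]:
            raise ConfigurationError(
                "fixed_window_days must cover the last scheduled visit "
                f"({self.fixed_window_days} < {days[-1]})"
            )
        object.__setattr__(self, "visit_days", days)

    @property
    def acute_knot_day(self) -> int:
        """Day of the first post-randomisation visit (end of the acute phase)."""
        return self.visit_days[1]


DAPA_HF_LIKE = TrialDesign(
    name="dapa_hf_like",
    # randomisation, 14 days, then 2..24 months
    visit_days=(0, 14, 60, 120, 240, 360, 480, 600, 720),
    fixed_window_days=720,
)

DELIVER_LIKE = TrialDesign(
    name="deliver_like",
    # randomisation, 1 month, then 4..36 months
    visit_days=(0, 30, 120, 360, 720, 1080),
    fixed_window_days=1080,
)

BUILTIN_DESIGNS: dict[str, TrialDesign] = {
    DAPA_HF_LIKE.name: DAPA_HF_LIKE,
    DELIVER_LIKE.name: DELIVER_LIKE,
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one simulated two-arm cohort.

    Rates are events per 100 patient-years; slopes are ml/min/1.73m^2 per
    year; acute dips are the total eGFR change (ml/min/1.73m^2) accrued
    linearly over the acute phase.
    """

    n_per_arm: int = 1000
    baseline_egfr_mean: float = 65.0
    baseline_egfr_sd: float = 19.0
    egfr_floor_inclusion: float = 30.0
    acute_dip_treated: float = -3.5
    acute_dip_control: float = -0.3
    chronic_slope_treated: float = -1.0
    chronic_slope_control: float = -3.1
    slope_sd_between: float = 2.0
    egfr_noise_sd: float = 9.0
    death_rate_control: float = 9.6
    death_hr_treated: float = 1 / 1.20
    eskd_rate_control: float = 0.4
    eskd_hr_treated: float = 1.0
    dropout_rate: float = 3.0
    diabetes_prevalence: float = 0.435
    missing_baseline_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ConfigurationError("n_per_arm must be >= 2")
        for name in ("baseline_egfr_sd", "egfr_noise_sd", "slope_sd_between"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.baseline_egfr_sd <= 0:
            raise ConfigurationError("baseline_egfr_sd must be > 0")
        for name in (
            "death_rate_control",
            "eskd_rate_control",
            "dropout_rate",
            "death_hr_treated",
            "eskd_hr_treated",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.diabetes_prevalence <= 1:
            raise ConfigurationError("diabetes_prevalence must be in [0, 1]")
        if not 0 <= self.missing_baseline_fraction <= 1:
            raise ConfigurationError("missing_baseline_fraction must be in [0, 1]")


#: Defaults loosely calibrated to published event rates and total-slope
#: estimates of the two source trials (placebo mortality ~9.6 and ~7.6 per
#: 100 patient-years, ESKD ~0.7 and ~0.3, inverse death HRs ~1.20 and ~1.06).
DAPA_HF_CONFIG = CohortConfig(
    egfr_floor_inclusion=30.0,
    acute_dip_treated=-3.5,
    acute_dip_control=-0.3,
    chronic_slope_treated=-1.0,
    chronic_slope_control=-3.1,
    death_rate_control=9.6,
    death_hr_treated=1 / 1.20,
    eskd_rate_control=0.4,
    eskd_hr_treated=1 / 1.02,
)

DELIVER_CONFIG = CohortConfig(
    egfr_floor_inclusion=25.0,
    acute_dip_treated=-3.5,
    acute_dip_control=-0.3,
    chronic_slope_treated=0.15,
    chronic_slope_control=-1.5,
    death_rate_control=7.6,
    death_hr_treated=1 / 1.06,
    eskd_rate_control=0.15,
    eskd_hr_treated=1 / 1.51,
)

BUILTIN_CONFIGS: dict[str, CohortConfig] = {
    "dapa_hf_like": DAPA_HF_CONFIG,
    "deliver_like": DELIVER_CONFIG,
}


@dataclass
class ParticipantRecord:
    """One participant's arm, strata, events and visit-level eGFR series."""

    id: str
    arm: str
    trial: str
    diabetes: bool
    baseline_egfr: float | None
    death_day: float | None
    eskd_day: float | None
    last_contact_day: float
    visits: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [d for d, _ in self.visits]
        if days != sorted(days):
            raise ValueError(f"{self.id}: visits must be sorted by day")
        if self.death_day is not None and any(d > self.death_day for d in days):
            raise ValueError(f"{self.id}: visit after death_day")
        if days and self.last_contact_day < max(days):
            raise ValueError(f"{self.id}: last_contact_day before last visit")


def _exponential_days(rng: np.random.Generator, rate_per_100py: float, n: int) -> np.ndarray:
    """Draw event days from a constant hazard given a rate per 100 patient-years."""
    if rate_per_100py <= 0:
        return np.full(n, np.inf)
    lam = rate_per_100py / 100.0 / DAYS_PER_YEAR  # per day
    return rng.exponential(1.0 / lam, size=n)


def generate_cohort(design: TrialDesign, config: CohortConfig) -> list[ParticipantRecord]:
    """Generate a seeded synthetic cohort under ``design`` and ``config``.

    The latent trajectory is baseline plus a linear acute change up to the
    knot, then a per-participant linear chronic trend; the observed series
    adds iid normal noise at every scheduled visit. Visits stop at
    min(death, dropout, administrative end). ESKD occurs at the earlier of
    its own hazard draw and the first visit with observed eGFR < 15.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_arm
    n_tot = 2 * n
    arm_treated = np.repeat([False, True], n)
    knot = design.acute_knot_day
    horizon = float(design.fixed_window_days)
    visit_days = np.asarray(design.visit_days, dtype=float)

    a = (config.egfr_floor_inclusion - config.baseline_egfr_mean) / config.baseline_egfr_sd
    base_true = stats.truncnorm.rvs(
        a, np.inf, loc=config.baseline_egfr_mean, scale=config.baseline_egfr_sd,
        size=n_tot, random_state=rng,
    )
    dip = np.where(arm_treated, config.acute_dip_treated, config.acute_dip_control)
    slope_mean = np.where(
        arm_treated, config.chronic_slope_treated, config.chronic_slope_control
    )
    slope = rng.normal(slope_mean, config.slope_sd_between)  # per year

    death_rate = np.where(
        arm_treated,
        config.death_rate_control * config.death_hr_treated,
        config.death_rate_control,
    )
    eskd_rate = np.where(
        arm_treated,
        config.eskd_rate_control * config.eskd_hr_treated,
        config.eskd_rate_control,
    )
    # inverse-cdf draws with per-subject rates
    u_death, u_eskd = rng.uniform(size=(2, n_tot))
    with np.errstate(divide="ignore"):
        death_day = np.where(
            death_rate > 0,
            -np.log(u_death) / (death_rate / 100.0 / DAYS_PER_YEAR),
            np.inf,
        )
        eskd_hazard_day = np.where(
            eskd_rate > 0,
            -np.log(u_eskd) / (eskd_rate / 100.0 / DAYS_PER_YEAR),
            np.inf,
        )
    dropout_day = _exponential_days(rng, config.dropout_rate, n_tot)

    diabetes = rng.uniform(size=n_tot) < config.diabetes_prevalence
    missing_base = rng.uniform(size=n_tot) < config.missing_baseline_fraction

    # latent trajectory at every scheduled visit, all participants at once
    acute_part = np.minimum(visit_days, knot) / knot  # (m,)
    chronic_part = np.clip(visit_days - knot, 0.0, None) / DAYS_PER_YEAR
    latent = (
        base_true[:, None]
        + dip[:, None] * acute_part[None, :]
        + slope[:, None] * chronic_part[None, :]
    )
    noise = rng.normal(0.0, config.egfr_noise_sd, size=latent.shape)
    # the randomisation eGFR is treated as noise-free: trials adjudicate the
    # baseline value, and it anchors both the decline denominators and the
    # slope model's baseline covariate
    noise[:, 0] = 0.0
    observed = np.maximum(latent + noise, EGFR_MIN)

    records: list[ParticipantRecord] = []
    for i in range(n_tot):
        last_obs = min(death_day[i], dropout_day[i], horizon)
        keep = visit_days <= last_obs
        if missing_base[i]:
            keep[0] = False
        vdays = visit_days[keep]
        vegfr = observed[i, keep]
        sub15 = vdays[vegfr < 15.0]
        eskd = min(eskd_hazard_day[i], sub15[0] if len(sub15) else np.inf)
        died = death_day[i] <= horizon
        last_contact = min(death_day[i], dropout_day[i], horizon)
        records.append(
            ParticipantRecord(
                id=f"{design.name}-{i:05d}",
                arm=TREATED if arm_treated[i] else CONTROL,
                trial=design.name,
                diabetes=bool(diabetes[i]),
                baseline_egfr=None if missing_base[i] else float(observed[i, 0]),
                death_day=float(death_day[i]) if died else None,
                eskd_day=float(eskd) if eskd <= last_contact else None,
                last_contact_day=float(last_contact),
                visits=list(zip(vdays.tolist(), vegfr.tolist())),
            )
        )
    return records


# ---------------------------------------------------------------------------
# tabular views and delimited-text round trip

PARTICIPANT_COLUMNS = [
    "id", "arm", "trial", "diabetes", "baseline_egfr",
    "death_day", "eskd_day", "last_contact_day",
]


def cohort_to_frames(cohort: list[ParticipantRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (participants, visits) DataFrames in the on-disk dialect."""
    part = pd.DataFrame(
        [
            {
                "id": r.id,
                "arm": r.arm,
                "trial": r.trial,
                "diabetes": r.diabetes,
                "baseline_egfr": np.nan if r.baseline_egfr is None else r.baseline_egfr,
                "death_day": np.nan if r.death_day is None else r.death_day,
                "eskd_day": np.nan if r.eskd_day is None else r.eskd_day,
                "last_contact_day": r.last_contact_day,
            }
            for r in cohort
        ],
        columns=PARTICIPANT_COLUMNS,
    )
    visits = pd.DataFrame(
        [(r.id, d, e) for r in cohort for d, e in r.visits],
        columns=["id", "day", "egfr"],
    )
    return part, visits


def frames_to_cohort(participants: pd.DataFrame, visits: pd.DataFrame) -> list[ParticipantRecord]:
    by_id: dict[str, list[tuple[float, float]]] = {}
    for pid, day, egfr in visits[["id", "day", "egfr"]].itertuples(index=False):
        by_id.setdefault(str(pid), []).append((float(day), float(egfr)))
    out = []
    for row in participants.itertuples(index=False):
        out.append(
            ParticipantRecord(
                id=str(row.id),
                arm=str(row.arm),
                trial=str(row.trial),
                diabetes=bool(row.diabetes),
                baseline_egfr=None if pd.isna(row.baseline_egfr) else float(row.baseline_egfr),
                death_day=None if pd.isna(row.death_day) else float(row.death_day),
                eskd_day=None if pd.isna(row.eskd_day) else float(row.eskd_day),
                last_contact_day=float(row.last_contact_day),
                visits=sorted(by_id.get(str(row.id), [])),
            )
        )
    return out


def write_cohort(cohort: list[ParticipantRecord], outdir: str | Path) -> tuple[Path, Path]:
    """Write participants.csv and visits.csv (UTF-8, RFC-4180)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    part, visits = cohort_to_frames(cohort)
    ppath = outdir / "participants.csv"
    vpath = outdir / "visits.csv"
    part.to_csv(ppath, index=False, quoting=csv.QUOTE_MINIMAL, float_format="%.4f")
    visits.to_csv(vpath, index=False, quoting=csv.QUOTE_MINIMAL, float_format="%.4f")
    return ppath, vpath


def read_cohort(outdir: str | Path) -> list[ParticipantRecord]:
    outdir = Path(outdir)
    part = pd.read_csv(outdir / "participants.csv")
    visits = pd.read_csv(outdir / "visits.csv")
    return frames_to_cohort(part, visits)


def null_config(config: CohortConfig) -> CohortConfig:
    """A no-treatment-effect version of ``config`` (both arms like control)."""
    return replace(
        config,
        death_hr_treated=1.0,
        eskd_hr_treated=1.0,
        acute_dip_treated=config.acute_dip_control,
        chronic_slope_treated=config.chronic_slope_control,
    )
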