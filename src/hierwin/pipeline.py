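"""End-to-end run: generate -> derive tiers -> slope fit -> win engine ->
temporal profile -> conventional comparators, with versioned text outputs.

All times are serialised as integer-valued days and all slopes with four
decimals, so repeated runs with the same config and seed produce
byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparators import conventional_endpoints
from .endpoints import MAIN_TIERS, build_pooled_tier_table, tier_model
from .slope import attach_slopes, fit_two_slope, individual_slopes
from .temporal import wins_over_time
from .trial import (
    BUILTIN_CONFIGS,
    BUILTIN_DESIGNS,
    CohortConfig,
    cohort_to_frames,
    generate_cohort,
    write_cohort,
)
from .winstats import sensitivity_models

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.4f"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    designs: tuple[str, ...] = ("dapa_hf_like", "deliver_like")
    tier_model: str = "main"
    strata: tuple[str, ...] = ("diabetes", "trial")
    n_per_arm: int = 500
    grid_step: float = 10.0
    horizon: float | None = 720.0
    seed: int = 0
    outdir: str = "hierwin_run"
    config_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise PipelineError("config", "seed is mandatory in the run config")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        for key in ("designs", "strata"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for name in self.designs:
            if name not in BUILTIN_DESIGNS:
                raise PipelineError(
                    "config",
                    f"unknown design {name!r}; valid: {sorted(BUILTIN_DESIGNS)}",
                )
        tier_model(self.tier_model)  # raises with valid options


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle as a dict and
    writes all artifacts under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    # --- generate ---------------------------------------------------------
    try:
        cohorts = {}
        for i, name in enumerate(config.designs):
            design = BUILTIN_DESIGNS[name]
            base = BUILTIN_CONFIGS.get(name, CohortConfig())
            cfg = replace(
                base,
                n_per_arm=config.n_per_arm,
                seed=config.seed + i,
                **config.config_overrides,
            )
            cohorts[name] = (generate_cohort(design, cfg), design)
            write_cohort(cohorts[name][0], outdir / name)
        log["stages"]["generate"] = {
            name: len(c) for name, (c, _) in cohorts.items()
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("generate", str(exc)) from exc

    # --- derive -----------------------------------------------------------
    try:
        tiers = tier_model(config.tier_model)
        table = build_pooled_tier_table(cohorts, MAIN_TIERS)
        log["stages"]["derive"] = {
            "n_participants": len(table),
            "n_excluded_missing_baseline": table.attrs["n_excluded_missing_baseline"],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("derive", str(exc)) from exc

    # --- slope fit --------------------------------------------------------
    try:
        parts = []
        vis = []
        for cohort, _ in cohorts.values():
            p, v = cohort_to_frames(cohort)
            parts.append(p)
            vis.append(v)
        participants = pd.concat(parts, ignore_index=True)
        visits = pd.concat(vis, ignore_index=True)
        designs = {n: d for n, (_, d) in cohorts.items()}
        fit = fit_two_slope(participants, visits, design=designs)
        slopes = individual_slopes(participants, visits, design=designs)
        table = attach_slopes(table, slopes)
        log["stages"]["slope"] = {
            "converged": fit.converged,
            "n_obs": fit.n_obs,
            "sigma": float(np.sqrt(fit.sigma2)),
        }
        if not fit.converged:
            logger.warning("slope model did not converge: %s", fit.message)
        _write_csv(fit.slope_summary(), outdir / "slope_summary.csv")
        _write_csv(
            slopes.rename("slope").rename_axis("id").reset_index(),
            outdir / "slopes.csv",
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("slope", str(exc)) from exc

    _write_csv(_format_tier_table(table), outdir / "tier_table.csv")

    # --- win engine -------------------------------------------------------
    try:
        results = sensitivity_models(table, tuple(config.strata))
        main = results[config.tier_model]
        bundle = {name: r.to_dict() for name, r in results.items()}
        log["stages"]["winstats"] = {"n_pairs": main.n_pairs}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("winstats", str(exc)) from exc

    # --- temporal ---------------------------------------------------------
    try:
        horizon = config.horizon or min(
            d.fixed_window_days for _, d in cohorts.values()
        )
        traj = wins_over_time(
            table, MAIN_TIERS, horizon=horizon, grid_step=config.grid_step,
            strata_cols=tuple(config.strata),
        )
        _write_csv(traj.table, outdir / "wins_over_time.csv")
        log["stages"]["temporal"] = {"horizon": horizon, "n_times": traj.table["time"].nunique()}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("temporal", str(exc)) from exc

    # --- conventional -----------------------------------------------------
    try:
        conv = conventional_endpoints(table, tuple(config.strata))
        _write_csv(conv, outdir / "conventional.csv")
        log["stages"]["conventional"] = {"n_endpoints": len(conv)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("conventional", str(exc)) from exc

    bundle_out = {
        "win_statistics": bundle,
        "slope_summary": _round_records(fit.slope_summary()),
        "conventional": _round_records(conv),
        "log": log,
    }
    with open(outdir / "result.json", "w") as fh:
        json.dump(bundle_out, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    return bundle_out


def _format_tier_table(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in out.columns:
        if col.endswith("_day") or col == "window_days":
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else str(int(round(v)))
            )
    return out


def _round_records(df: pd.DataFrame) -> list[dict]:
    out = df.copy()
    for col in out.select_dtypes(include=[float]).columns:
        out[col] = out[col].round(4)
    return out.to_dict(orient="records")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
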