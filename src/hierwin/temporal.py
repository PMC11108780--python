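"""Proportions of wins and losses per tier as a function of follow-up time.

At each grid time t (every 10 days by default) all cross-arm pairs are
re-compared using only events that have occurred by t, through the same tier
cascade restricted to the time-to-event tiers (the slope tier is excluded:
a participant-level slope is defined over the whole fixed window, not at an
interim time point). Proportions are of all within-stratum pairs, pooled
over strata by pair counts. At t = horizon the counts equal the main engine
run on the same tiers — the construction is definitionally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .endpoints import TIME_TO_EVENT, TierSpec
from .trial import CONTROL, TREATED
from .winstats import NO_EVENT, _stratum_engine, tier_values


@dataclass
class WinTrajectory:
    """Long-format per-tier win/loss proportions over the time grid."""

    table: pd.DataFrame  # columns: time, tier, label, win_prop, loss_prop
    tie_prop: pd.Series  # index time
    horizon: float
    grid_step: float
    n_pairs: int

    def at(self, time: float) -> pd.DataFrame:
        return self.table[self.table["time"] == time]


def wins_over_time(
    tier_table: pd.DataFrame,
    tiers: tuple[TierSpec, ...],
    horizon: float | None = None,
    grid_step: float = 10.0,
    strata_cols: tuple[str, ...] = ("diabetes", "trial"),
) -> WinTrajectory:
    """Win/loss proportions per tier on a regular time grid.

    Only time-to-event tiers are used; a trailing continuous tier in
    ``tiers`` is dropped. ``horizon`` defaults to the tier table's window
    and must not exceed it.
    """
    tte = tuple(t for t in tiers if t.kind == TIME_TO_EVENT)
    if not tte:
        raise ValueError("need at least one time-to-event tier")
    window = float(tier_table.attrs.get("window_days", tier_table["window_days"].min()))
    if horizon is None:
        horizon = window
    if horizon > tier_table["window_days"].min():
        raise ValueError("horizon exceeds the fixed follow-up window")

    cols = tuple(c for c in strata_cols if tier_table[c].nunique() > 1)
    groups = (
        [g for _, g in tier_table.groupby(list(cols), sort=True)]
        if cols
        else [tier_table]
    )
    mats = []
    total_pairs = 0
    for grp in groups:
        A = tier_values(grp[grp["arm"] == TREATED], tte)
        B = tier_values(grp[grp["arm"] == CONTROL], tte)
        if len(A) and len(B):
            mats.append((A, B))
            total_pairs += len(A) * len(B)
    if total_pairs == 0:
        raise ValueError("no stratum with both arms populated")

    grid = np.arange(0.0, horizon + 0.5 * grid_step, grid_step)
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    K = len(tte)
    rows = []
    ties = []
    for t in grid:
        tier_w = np.zeros(K, dtype=np.int64)
        tier_l = np.zeros(K, dtype=np.int64)
        n_tie = 0
        for A, B in mats:
            At = np.where(A <= t, A, NO_EVENT)
            Bt = np.where(B <= t, B, NO_EVENT)
            w, l, *_ = _stratum_engine(At, Bt)
            tier_w += w
            tier_l += l
            n_tie += A.shape[0] * B.shape[0] - int(w.sum()) - int(l.sum())
        for k, tier in enumerate(tte):
            rows.append(
                {
                    "time": t,
                    "tier": tier.tier_index,
                    "label": tier.label,
                    "win_prop": tier_w[k] / total_pairs,
                    "loss_prop": tier_l[k] / total_pairs,
                }
            )
        ties.append(n_tie / total_pairs)
    table = pd.DataFrame(rows)
    return WinTrajectory(
        table=table,
        tie_prop=pd.Series(ties, index=grid, name="tie_prop"),
        horizon=float(horizon),
        grid_step=float(grid_step),
        n_pairs=total_pairs,
    )


def plot_trajectory(traj: WinTrajectory, path: str) -> None:
    """Simple per-tier line chart of win and loss proportions over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tiers = traj.table["tier"].unique()
    fig, axes = plt.subplots(1, len(tiers), figsize=(3.2 * len(tiers), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, k in zip(axes, tiers):
        sub = traj.table[traj.table["tier"] == k]
        ax.plot(sub["time"], sub["win_prop"], label="wins")
        ax.plot(sub["time"], sub["loss_prop"], label="losses", linestyle="--")
        ax.set_title(sub["label"].iloc[0], fontsize=8)
        ax.set_xlabel("day")
    axes[0].set_ylabel("proportion of pairs")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
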