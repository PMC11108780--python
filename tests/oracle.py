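"""Independent brute-force reference for the pairwise win cascade.

Deliberately written from the comparison rules themselves (a plain Python
double loop over per-participant value lists, no shared code with the
production engine) so it can serve as an oracle for the vectorised
implementation.
"""

from __future__ import annotations

import math

import pandas as pd


def brute_force_counts(
    tier_table: pd.DataFrame,
    tier_columns: list[str],
    continuous_last: bool,
    strata_cols: list[str],
) -> dict:
    """Win/loss/tie pair counts and per-tier settlements by naive double loop.

    ``tier_columns`` are event-day columns (NaN = no event) except, when
    ``continuous_last``, the final column which holds a continuous value
    where larger is better.
    """
    wins = losses = ties = 0
    K = len(tier_columns)
    tier_wins = [0] * K
    tier_losses = [0] * K

    if strata_cols:
        keys = tier_table[strata_cols].apply(tuple, axis=1)
    else:
        keys = pd.Series([()] * len(tier_table), index=tier_table.index)

    def rows_of(frame):
        return [tuple(frame[c].iloc[i] for c in tier_columns)
                for i in range(len(frame))]

    for key in sorted(keys.unique()):
        grp = tier_table[keys == key]
        treated = rows_of(grp[grp["arm"] == "treated"])
        control = rows_of(grp[grp["arm"] == "control"])
        for t_row in treated:
            for c_row in control:
                outcome = None
                for k in range(K):
                    tv, cv = t_row[k], c_row[k]
                    if continuous_last and k == K - 1:
                        # shallower (larger) slope wins; equality -> tie
                        if tv > cv:
                            outcome = ("win", k)
                        elif tv < cv:
                            outcome = ("loss", k)
                        break
                    t_has = not math.isnan(tv)
                    c_has = not math.isnan(cv)
                    if t_has and not c_has:
                        outcome = ("loss", k)  # event-free patient wins
                        break
                    if c_has and not t_has:
                        outcome = ("win", k)
                        break
                    if t_has and c_has:
                        if tv > cv:  # later event wins
                            outcome = ("win", k)
                            break
                        if tv < cv:
                            outcome = ("loss", k)
                            break
                        # same day: not settled, descend
                if outcome is None:
                    ties += 1
                elif outcome[0] == "win":
                    wins += 1
                    tier_wins[outcome[1]] += 1
                else:
                    losses += 1
                    tier_losses[outcome[1]] += 1
    return {
        "wins": wins,
        "losses": losses,
        "ties": ties,
        "tier_wins": tier_wins,
        "tier_losses": tier_losses,
    }
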