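"""Unmatched all-pairs hierarchical comparison and the four win statistics.

Every treated participant is compared with every control participant in the
same stratum, tier by tier in ascending order. For a time-to-event tier the
pair is settled if exactly one of the two has an in-window event (the
event-free participant wins) or if both do and the days differ (the later
event wins); otherwise the next tier is assessed. The final continuous tier
(eGFR slope) settles the pair unless the slopes are exactly equal; without
it, unsettled pairs are ties.

From the pooled win/loss/tie proportions P_W, P_L, P_T the engine reports

    win ratio        P_W / P_L
    net benefit      P_W - P_L
    win odds         (P_W + 0.5 P_T) / (P_L + 0.5 P_T)
    win probability  P_W + 0.5 P_T

with variances from the two-sample U-statistic projection: per subject, the
fraction of opposite-arm subjects (same stratum) it beats/loses to is an
asymptotically sufficient summary, and the empirical (co)variances of these
fractions yield var(P_W), var(P_L) and their covariance. Strata are pooled
by raw pair counts and contribute independent variance terms. Confidence
intervals for the ratio statistics are normal on the log scale (delta
method); the reported two-sided p-value is the log-win-ratio Wald test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .endpoints import TIME_TO_EVENT, TierSpec, validate_tiers
from .trial import CONTROL, TREATED

logger = logging.getLogger(__name__)

#: Sentinel event "day" for no event: later is better, so no event is best.
NO_EVENT = 1e12

#: Row-block size cap for the pair matrices (elements per block).
_BLOCK_ELEMS = 4_000_000


def tier_values(table: pd.DataFrame, tiers: tuple[TierSpec, ...]) -> np.ndarray:
    """Per-participant (n, K) value matrix; larger value = better outcome."""
    cols = []
    for tier in tiers:
        v = table[tier.column].to_numpy(float)
        if tier.kind == TIME_TO_EVENT:
            v = np.where(np.isnan(v), NO_EVENT, v)
        elif np.isnan(v).any():
            raise ValueError(
                f"missing values in continuous tier {tier.label!r}; "
                "fit the slope model and attach participant slopes first"
            )
        cols.append(v)
    return np.column_stack(cols)


def compare_pair(
    a: np.ndarray | list[float], b: np.ndarray | list[float],
    tiers: tuple[TierSpec, ...],
) -> tuple[str, int | None]:
    """Compare one pair of per-tier value vectors.

    Returns ("a_wins" | "b_wins" | "tie", settling tier index or None).
    Vectors must be encoded as by :func:`tier_values` (absent events coded
    as the NO_EVENT sentinel; larger = better).
    """
    validate_tiers(tiers)
    for tier, va, vb in zip(tiers, a, b):
        if np.isnan(va) or np.isnan(vb):
            raise ValueError(f"missing value at tier {tier.label!r}")
        if va > vb:
            return "a_wins", tier.tier_index
        if va < vb:
            return "b_wins", tier.tier_index
    return "tie", None


@dataclass
class StratumCounts:
    """Pair counts and per-subject win/loss fractions for one stratum."""

    stratum: tuple
    n_treated: int
    n_control: int
    tier_wins: np.ndarray  # (K,) pairs settled as treated wins at each tier
    tier_losses: np.ndarray
    frac_win_treated: np.ndarray  # per treated subject, fraction of controls beaten
    frac_loss_treated: np.ndarray
    frac_win_control: np.ndarray  # per control subject, fraction of treated that beat it
    frac_loss_control: np.ndarray

    @property
    def pairs(self) -> int:
        return self.n_treated * self.n_control

    @property
    def wins(self) -> int:
        return int(self.tier_wins.sum())

    @property
    def losses(self) -> int:
        return int(self.tier_losses.sum())

    @property
    def ties(self) -> int:
        return self.pairs - self.wins - self.losses


@dataclass
class WinCounts:
    """Win/loss/tie pair counts per stratum, attributed to settling tiers."""

    tiers: tuple[TierSpec, ...]
    strata: list[StratumCounts]
    strata_cols: tuple[str, ...]

    @property
    def pairs(self) -> int:
        return sum(s.pairs for s in self.strata)

    @property
    def wins(self) -> int:
        return sum(s.wins for s in self.strata)

    @property
    def losses(self) -> int:
        return sum(s.losses for s in self.strata)

    @property
    def ties(self) -> int:
        return sum(s.ties for s in self.strata)

    def tier_breakdown(self) -> pd.DataFrame:
        """Pooled wins/losses (counts and proportions) per settling tier."""
        rows = []
        total = self.pairs
        for k, tier in enumerate(self.tiers):
            w = sum(int(s.tier_wins[k]) for s in self.strata)
            l = sum(int(s.tier_losses[k]) for s in self.strata)
            rows.append(
                {
                    "tier": tier.tier_index,
                    "label": tier.label,
                    "wins": w,
                    "losses": l,
                    "win_prop": w / total,
                    "loss_prop": l / total,
                }
            )
        rows.append(
            {
                "tier": 0,
                "label": "tie",
                "wins": self.ties,
                "losses": self.ties,
                "win_prop": self.ties / total,
                "loss_prop": self.ties / total,
            }
        )
        return pd.DataFrame(rows)


def _stratum_engine(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, ...]:
    """All-pairs tier cascade between value matrices A (treated) and B
    (control), processed in row blocks. Returns per-tier win/loss counts and
    per-subject win/loss counts for both arms."""
    n_t, K = A.shape
    n_c = B.shape[0]
    tier_w = np.zeros(K, dtype=np.int64)
    tier_l = np.zeros(K, dtype=np.int64)
    row_w = np.zeros(n_t, dtype=np.int64)
    row_l = np.zeros(n_t, dtype=np.int64)
    col_w = np.zeros(n_c, dtype=np.int64)
    col_l = np.zeros(n_c, dtype=np.int64)
    block = max(1, _BLOCK_ELEMS // max(n_c, 1))
    for start in range(0, n_t, block):
        stop = min(start + block, n_t)
        unsettled = np.ones((stop - start, n_c), dtype=bool)
        for k in range(K):
            d = A[start:stop, k][:, None] - B[None, :, k]
            win = unsettled & (d > 0)
            loss = unsettled & (d < 0)
            tier_w[k] += win.sum()
            tier_l[k] += loss.sum()
            row_w[start:stop] += win.sum(axis=1)
            row_l[start:stop] += loss.sum(axis=1)
            col_w += win.sum(axis=0)
            col_l += loss.sum(axis=0)
            unsettled &= d == 0
    return tier_w, tier_l, row_w, row_l, col_w, col_l


def count_wins(
    tier_table: pd.DataFrame,
    tiers: tuple[TierSpec, ...],
    strata_cols: tuple[str, ...] = ("diabetes", "trial"),
) -> WinCounts:
    """All-pairs win/loss/tie counts, pairing only within strata.

    Strata with an empty arm contribute no pairs and are dropped with a
    warning. ``strata_cols`` may be empty for an unstratified analysis.
    """
    validate_tiers(tiers)
    strata_cols = tuple(c for c in strata_cols if tier_table[c].nunique() > 1) \
        if strata_cols else ()
    groups = (
        tier_table.groupby(list(strata_cols), sort=True)
        if strata_cols
        else [((), tier_table)]
    )
    out: list[StratumCounts] = []
    for key, grp in groups:
        key = key if isinstance(key, tuple) else (key,)
        treated = grp[grp["arm"] == TREATED]
        control = grp[grp["arm"] == CONTROL]
        if treated.empty or control.empty:
            warnings.warn(
                f"stratum {key} has an empty arm; dropped from the analysis",
                stacklevel=2,
            )
            continue
        A = tier_values(treated, tiers)
        B = tier_values(control, tiers)
        tier_w, tier_l, row_w, row_l, col_w, col_l = _stratum_engine(A, B)
        out.append(
            StratumCounts(
                stratum=key,
                n_treated=len(treated),
                n_control=len(control),
                tier_wins=tier_w,
                tier_losses=tier_l,
                frac_win_treated=row_w / len(control),
                frac_loss_treated=row_l / len(control),
                frac_win_control=col_w / len(treated),
                frac_loss_control=col_l / len(treated),
            )
        )
    if not out:
        raise ValueError("no stratum with both arms populated")
    return WinCounts(tiers=tuple(tiers), strata=out, strata_cols=strata_cols)


@dataclass
class WinResult:
    """Point estimates, variances, CIs and p-value for the win statistics."""

    p_win: float
    p_loss: float
    p_tie: float
    win_ratio: float
    net_benefit: float
    win_odds: float
    win_probability: float
    var_p_win: float
    var_p_loss: float
    cov_win_loss: float
    se_log_win_ratio: float
    se_net_benefit: float
    se_log_win_odds: float
    ci_win_ratio: tuple[float, float]
    ci_net_benefit: tuple[float, float]
    ci_win_odds: tuple[float, float]
    ci_win_probability: tuple[float, float]
    p_value: float
    n_pairs: int
    n_treated: int
    n_control: int
    alpha: float = 0.05
    tier_breakdown: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "p_win", "p_loss", "p_tie", "win_ratio", "net_benefit",
                "win_odds", "win_probability", "var_p_win", "var_p_loss",
                "cov_win_loss", "se_log_win_ratio", "se_net_benefit",
                "se_log_win_odds", "p_value", "n_pairs", "n_treated",
                "n_control", "alpha",
            )
        }
        for k in ("ci_win_ratio", "ci_net_benefit", "ci_win_odds",
                  "ci_win_probability"):
            d[k] = list(getattr(self, k))
        if self.tier_breakdown is not None:
            d["tier_breakdown"] = self.tier_breakdown.to_dict(orient="records")
        return d


def _moments(counts: WinCounts) -> tuple[float, float, float, float, float]:
    """Pooled (P_W, P_L) and their U-statistic variance/covariance.

    Strata are pooled with weights proportional to their pair counts and are
    independent, so variances add with squared weights. Within a stratum the
    first-order projection uses the per-subject win/loss fractions; the
    O(1/(n_T n_C)) term is neglected.
    """
    total_pairs = counts.pairs
    p_w = p_l = var_w = var_l = cov_wl = 0.0
    for s in counts.strata:
        w = s.pairs / total_pairs
        pw_s = s.wins / s.pairs
        pl_s = s.losses / s.pairs
        p_w += w * pw_s
        p_l += w * pl_s

        def vc(x, y, n):
            if n < 2:
                return 0.0
            return float(np.cov(x, y, ddof=1)[0, 1]) / n

        var_w_s = vc(s.frac_win_treated, s.frac_win_treated, s.n_treated) + vc(
            s.frac_win_control, s.frac_win_control, s.n_control
        )
        var_l_s = vc(s.frac_loss_treated, s.frac_loss_treated, s.n_treated) + vc(
            s.frac_loss_control, s.frac_loss_control, s.n_control
        )
        cov_s = vc(s.frac_win_treated, s.frac_loss_treated, s.n_treated) + vc(
            s.frac_win_control, s.frac_loss_control, s.n_control
        )
        var_w += w * w * var_w_s
        var_l += w * w * var_l_s
        cov_wl += w * w * cov_s
    return p_w, p_l, var_w, var_l, cov_wl


def win_statistics(counts: WinCounts, alpha: float = 0.05) -> WinResult:
    """The four win statistics with U-statistic CIs from pair counts.

    If no losses were observed the win ratio is +inf; its CI is then formed
    from continuity-corrected counts (0.5 added to the loss count) with an
    infinite upper bound, and this policy is logged.
    """
    p_w, p_l, var_w, var_l, cov_wl = _moments(counts)
    p_t = max(1.0 - p_w - p_l, 0.0)
    z = stats.norm.ppf(1 - alpha / 2)

    nb = p_w - p_l
    var_nb = max(var_w + var_l - 2 * cov_wl, 0.0)
    se_nb = np.sqrt(var_nb)
    wp = p_w + 0.5 * p_t
    se_wp = se_nb / 2  # wp = (1 + nb)/2

    if p_l > 0:
        wr = p_w / p_l
        var_log_wr = max(
            var_w / p_w**2 + var_l / p_l**2 - 2 * cov_wl / (p_w * p_l), 0.0
        ) if p_w > 0 else np.inf
        se_log_wr = np.sqrt(var_log_wr)
        ci_wr = (wr * np.exp(-z * se_log_wr), wr * np.exp(z * se_log_wr))
        z_wr = np.log(wr) / se_log_wr if se_log_wr > 0 else np.inf
        p_value = float(2 * stats.norm.sf(abs(z_wr)))
    else:
        wr = np.inf
        logger.info("no losing pairs: win ratio +inf, CI from 0.5-corrected losses")
        pl_cc = 0.5 / counts.pairs
        wr_cc = p_w / pl_cc
        se_log_wr = np.sqrt(var_w / p_w**2 + 1.0 / 0.5) if p_w > 0 else np.inf
        ci_wr = (wr_cc * np.exp(-z * se_log_wr), np.inf)
        p_value = float(2 * stats.norm.sf(abs(nb) / se_nb)) if se_nb > 0 else 0.0

    # win odds = (1 + nb) / (1 - nb); d log(wo)/d nb = 2 / (1 - nb^2)
    wo = (p_w + 0.5 * p_t) / (p_l + 0.5 * p_t)
    if abs(nb) < 1:
        se_log_wo = 2 * se_nb / (1 - nb**2)
        ci_wo = (wo * np.exp(-z * se_log_wo), wo * np.exp(z * se_log_wo))
    else:
        se_log_wo = np.inf
        ci_wo = (0.0, np.inf)

    return WinResult(
        p_win=p_w,
        p_loss=p_l,
        p_tie=p_t,
        win_ratio=wr,
        net_benefit=nb,
        win_odds=wo,
        win_probability=wp,
        var_p_win=var_w,
        var_p_loss=var_l,
        cov_win_loss=cov_wl,
        se_log_win_ratio=float(se_log_wr),
        se_net_benefit=float(se_nb),
        se_log_win_odds=float(se_log_wo),
        ci_win_ratio=(float(ci_wr[0]), float(ci_wr[1])),
        ci_net_benefit=(float(nb - z * se_nb), float(nb + z * se_nb)),
        ci_win_odds=(float(ci_wo[0]), float(ci_wo[1])),
        ci_win_probability=(float(wp - z * se_wp), float(wp + z * se_wp)),
        p_value=p_value,
        n_pairs=counts.pairs,
        n_treated=sum(s.n_treated for s in counts.strata),
        n_control=sum(s.n_control for s in counts.strata),
        alpha=alpha,
        tier_breakdown=counts.tier_breakdown(),
    )


def analyze(
    tier_table: pd.DataFrame,
    tiers: tuple[TierSpec, ...],
    strata_cols: tuple[str, ...] = ("diabetes", "trial"),
    alpha: float = 0.05,
) -> WinResult:
    """Convenience wrapper: count pairs then compute the win statistics."""
    return win_statistics(count_wins(tier_table, tiers, strata_cols), alpha=alpha)


def sensitivity_models(
    tier_table: pd.DataFrame,
    strata_cols: tuple[str, ...] = ("diabetes", "trial"),
    alpha: float = 0.05,
) -> dict[str, WinResult]:
    """Main hierarchy plus the three sensitivity variants."""
    from .endpoints import TIER_MODELS

    return {
        name: analyze(tier_table, tiers, strata_cols, alpha=alpha)
        for name, tiers in TIER_MODELS.items()
    }


def subgroup_analysis(
    tier_table: pd.DataFrame,
    subgroups: dict[str, pd.Series],
    tiers: tuple[TierSpec, ...],
    strata_cols: tuple[str, ...] = ("diabetes", "trial"),
    alpha: float = 0.05,
) -> dict[str, WinResult | None]:
    """Run the full engine within each subgroup, retaining stratification.

    ``subgroups`` maps a label to a boolean mask over the tier table. A
    subgroup in which some arm is entirely absent is reported as None (not
    estimable).
    """
    out: dict[str, WinResult | None] = {}
    for label, mask in subgroups.items():
        sub = tier_table[np.asarray(mask, bool)]
        arms = set(sub["arm"].unique())
        if not {TREATED, CONTROL} <= arms:
            logger.warning("subgroup %r has an empty arm; not estimable", label)
            out[label] = None
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[label] = analyze(sub, tiers, strata_cols, alpha=alpha)
    return out


def egfr_category_subgroups(tier_table: pd.DataFrame, cutoff: float = 60.0
                            ) -> dict[str, pd.Series]:
    """Baseline kidney-function subgroups (eGFR < cutoff vs >= cutoff)."""
    lo = tier_table["baseline_egfr"] < cutoff
    return {f"egfr<{cutoff:g}": lo, f"egfr>={cutoff:g}": ~lo}


def diabetes_subgroups(tier_table: pd.DataFrame) -> dict[str, pd.Series]:
    d = tier_table["diabetes"].astype(bool)
    return {"diabetes": d, "no_diabetes": ~d}
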