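"""Win engine: pair cascade, counting, statistics, symmetry, subgroups."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hierwin import (
    BUILTIN_CONFIGS,
    DAPA_HF_LIKE,
    MAIN_TIERS,
    TIER_MODELS,
    compare_pair,
    count_wins,
    generate_cohort,
    win_statistics,
)
from hierwin.endpoints import build_tier_table
from hierwin.slope import attach_slopes, individual_slopes
from hierwin.trial import CONTROL, TREATED, cohort_to_frames
from hierwin.winstats import (
    NO_EVENT,
    StratumCounts,
    WinCounts,
    analyze,
    diabetes_subgroups,
    subgroup_analysis,
)

from oracle import brute_force_counts

TIER_COLS = [t.column for t in MAIN_TIERS]


def swap_arms(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["arm"] = out["arm"].map({TREATED: CONTROL, CONTROL: TREATED})
    return out


def counts_from(w: int, l: int, t: int, n_t: int = 10, n_c: int = 10) -> WinCounts:
    """A WinCounts with prescribed totals in one stratum (fractions spread
    evenly; only the totals matter for the point estimates)."""
    assert w + l + t == n_t * n_c
    s = StratumCounts(
        stratum=(), n_treated=n_t, n_control=n_c,
        tier_wins=np.array([w]), tier_losses=np.array([l]),
        frac_win_treated=np.full(n_t, w / (n_t * n_c) * n_t / n_t),
        frac_loss_treated=np.full(n_t, l / (n_t * n_c)),
        frac_win_control=np.full(n_c, w / (n_t * n_c)),
        frac_loss_control=np.full(n_c, l / (n_t * n_c)),
    )
    tiers = (MAIN_TIERS[0],)
    return WinCounts(tiers=tiers, strata=[s], strata_cols=())


class TestComparePair:
    def test_death_settles_tier_one(self):
        a = [100.0] + [NO_EVENT] * 4 + [-2.0]
        b = [NO_EVENT] * 5 + [-5.0]
        outcome, tier = compare_pair(a, b, MAIN_TIERS)
        assert outcome == "b_wins" and tier == 1

    def test_identical_patterns_tie_at_final_tier(self):
        a = [NO_EVENT, NO_EVENT, NO_EVENT, 300.0, 200.0, -3.0]
        outcome, tier = compare_pair(a, list(a), MAIN_TIERS)
        assert outcome == "tie" and tier is None

    def test_decline_settles_before_slope(self):
        # a has a >=40% decline at day 60 but the better slope; the decline
        # tier settles first, so b wins despite its worse slope
        a = [NO_EVENT, NO_EVENT, NO_EVENT, NO_EVENT, 60.0, -3.0]
        b = [NO_EVENT, NO_EVENT, NO_EVENT, NO_EVENT, NO_EVENT, -5.0]
        outcome, tier = compare_pair(a, b, MAIN_TIERS)
        assert outcome == "b_wins" and tier == 5

    def test_later_event_wins(self):
        a = [500.0] + [NO_EVENT] * 4 + [0.0]
        b = [100.0] + [NO_EVENT] * 4 + [0.0]
        outcome, tier = compare_pair(a, b, MAIN_TIERS)
        assert outcome == "a_wins" and tier == 1

    def test_equal_event_days_descend(self):
        a = [100.0, NO_EVENT, NO_EVENT, NO_EVENT, NO_EVENT, -1.0]
        b = [100.0, NO_EVENT, NO_EVENT, NO_EVENT, NO_EVENT, -2.0]
        outcome, tier = compare_pair(a, b, MAIN_TIERS)
        assert outcome == "a_wins" and tier == 6

    def test_missing_slope_raises(self):
        a = [NO_EVENT] * 5 + [np.nan]
        with pytest.raises(ValueError):
            compare_pair(a, a, MAIN_TIERS)


class TestCountWins:
    def test_pair_product_rule(self):
        rows = []
        for i, arm in enumerate([TREATED] * 2 + [CONTROL] * 3):
            rows.append(
                {"id": f"p{i}", "arm": arm, "trial": "t", "diabetes": False,
                 "baseline_egfr": 60.0, "window_days": 720.0,
                 "death_day": np.nan, "eskd_day": np.nan,
                 "decline57_day": np.nan, "decline50_day": np.nan,
                 "decline40_day": np.nan, "slope": float(i)}
            )
        table = pd.DataFrame(rows)
        wc = count_wins(table, MAIN_TIERS, ())
        assert wc.pairs == 6
        assert wc.wins + wc.losses + wc.ties == 6

    def test_equals_brute_force_with_strata(self, medium_tier_table):
        wc = count_wins(medium_tier_table, MAIN_TIERS, ("diabetes",))
        bf = brute_force_counts(medium_tier_table, TIER_COLS, True, ["diabetes"])
        assert wc.wins == bf["wins"]
        assert wc.losses == bf["losses"]
        assert wc.ties == bf["ties"]
        for k in range(len(MAIN_TIERS)):
            assert sum(int(s.tier_wins[k]) for s in wc.strata) == bf["tier_wins"][k]
            assert sum(int(s.tier_losses[k]) for s in wc.strata) == bf["tier_losses"][k]

    def test_arm_relabel_swaps_wins_losses(self, small_tier_table):
        wc = count_wins(small_tier_table, MAIN_TIERS, ("diabetes",))
        ws = count_wins(swap_arms(small_tier_table), MAIN_TIERS, ("diabetes",))
        assert wc.wins == ws.losses and wc.losses == ws.wins
        assert wc.ties == ws.ties

    def test_empty_arm_stratum_dropped_with_warning(self, small_tier_table):
        table = small_tier_table.copy()
        # make one diabetes stratum single-armed
        mask = table["diabetes"] & (table["arm"] == TREATED)
        table = table[~mask]
        with pytest.warns(UserWarning, match="empty arm"):
            wc = count_wins(table, MAIN_TIERS, ("diabetes",))
        assert len(wc.strata) == 1

    def test_single_stratum_equals_unstratified(self, small_tier_table):
        table = small_tier_table.copy()
        table["diabetes"] = False
        a = count_wins(table, MAIN_TIERS, ("diabetes",))
        b = count_wins(table, MAIN_TIERS, ())
        assert (a.wins, a.losses, a.ties) == (b.wins, b.losses, b.ties)

    def test_counts_invariants(self, medium_tier_table):
        wc = count_wins(medium_tier_table, MAIN_TIERS, ("diabetes",))
        for s in wc.strata:
            assert s.wins + s.losses + s.ties == s.pairs
            assert s.tier_wins.sum() == s.wins
            assert np.all(s.tier_wins >= 0) and np.all(s.tier_losses >= 0)


class TestWinStatistics:
    def test_formula_arithmetic_on_fixed_triple(self):
        res = win_statistics(counts_from(w=30, l=20, t=50))
        assert res.p_win == pytest.approx(0.3)
        assert res.p_loss == pytest.approx(0.2)
        assert res.win_ratio == pytest.approx(1.5)
        assert res.net_benefit == pytest.approx(0.1)
        assert res.win_odds == pytest.approx(0.55 / 0.45)
        assert res.win_probability == pytest.approx(0.55)

    @given(
        w=st.integers(min_value=0, max_value=100),
        l=st.integers(min_value=1, max_value=100),
        t=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_formula_identities_hold(self, w, l, t):
        """The four statistics satisfy their defining formulas for any
        (P_W, P_L, P_T) composition, and P_T = 0 implies WR = WO."""
        total = w + l + t
        n = max(2, int(np.ceil(np.sqrt(total))) + 1)
        pad = n * n - total
        res = win_statistics(counts_from(w, l, t + pad, n_t=n, n_c=n))
        pw, pl, pt = res.p_win, res.p_loss, res.p_tie
        assert pw + pl + pt == pytest.approx(1.0)
        assert res.win_ratio == pytest.approx(pw / pl)
        assert res.net_benefit == pytest.approx(pw - pl)
        assert res.win_odds == pytest.approx((pw + 0.5 * pt) / (pl + 0.5 * pt))
        assert res.win_probability == pytest.approx(pw + 0.5 * pt)
        if pt == 0:
            assert res.win_ratio == pytest.approx(res.win_odds)

    def test_cloned_arms_give_exact_null(self):
        """Every treated subject cloned from a control: WR = 1, NB = 0."""
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            death = rng.choice([np.nan, rng.uniform(0, 720)], p=[0.8, 0.2])
            slope = rng.normal(-2, 1)
            for arm in (TREATED, CONTROL):
                rows.append(
                    {"id": f"{arm}{i}", "arm": arm, "trial": "t",
                     "diabetes": bool(i % 2), "baseline_egfr": 60.0,
                     "window_days": 720.0, "death_day": death,
                     "eskd_day": np.nan, "decline57_day": np.nan,
                     "decline50_day": np.nan, "decline40_day": np.nan,
                     "slope": slope}
                )
        res = analyze(pd.DataFrame(rows), MAIN_TIERS, ("diabetes",))
        assert res.win_ratio == pytest.approx(1.0)
        assert res.net_benefit == pytest.approx(0.0, abs=1e-15)
        assert res.win_odds == pytest.approx(1.0)
        assert res.win_probability == pytest.approx(0.5)

    def test_arm_swap_antisymmetry_exact(self, small_tier_table):
        r = analyze(small_tier_table, MAIN_TIERS, ("diabetes",))
        s = analyze(swap_arms(small_tier_table), MAIN_TIERS, ("diabetes",))
        assert s.win_ratio == pytest.approx(1 / r.win_ratio, rel=1e-12)
        assert s.net_benefit == pytest.approx(-r.net_benefit, rel=1e-12)
        assert s.win_odds == pytest.approx(1 / r.win_odds, rel=1e-12)
        assert s.win_probability == pytest.approx(1 - r.win_probability, rel=1e-12)
        assert s.p_value == pytest.approx(r.p_value, rel=1e-9)

    def test_no_losses_policy(self):
        res = win_statistics(counts_from(w=99, l=0, t=1))
        assert res.win_ratio == np.inf
        assert res.ci_win_ratio[1] == np.inf
        assert np.isfinite(res.ci_win_ratio[0])


class TestSensitivityAndSubgroups:
    def test_model2_has_ties_main_does_not(self, medium_tier_table):
        main = analyze(medium_tier_table, TIER_MODELS["main"], ("diabetes",))
        m2 = analyze(medium_tier_table, TIER_MODELS["model2"], ("diabetes",))
        assert main.p_tie == pytest.approx(0.0, abs=1e-12)
        assert m2.p_tie > 0

    def test_model3_equals_main_when_no_deaths(self, small_tier_table):
        table = small_tier_table.copy()
        table["death_day"] = np.nan
        main = analyze(table, TIER_MODELS["main"], ("diabetes",))
        m3 = analyze(table, TIER_MODELS["model3"], ("diabetes",))
        assert (main.p_win, main.p_loss) == (m3.p_win, m3.p_loss)
        assert main.win_ratio == pytest.approx(m3.win_ratio)

    def test_everyone_subgroup_equals_overall(self, small_tier_table):
        overall = analyze(small_tier_table, MAIN_TIERS, ("diabetes",))
        res = subgroup_analysis(
            small_tier_table,
            {"everyone": pd.Series(True, index=small_tier_table.index)},
            MAIN_TIERS, ("diabetes",),
        )["everyone"]
        assert res.win_ratio == pytest.approx(overall.win_ratio)
        assert res.n_pairs == overall.n_pairs

    def test_complementary_subgroups_lose_cross_pairs(self, small_tier_table):
        overall = analyze(small_tier_table, MAIN_TIERS, ())
        subs = subgroup_analysis(
            small_tier_table, diabetes_subgroups(small_tier_table),
            MAIN_TIERS, (),
        )
        total = sum(r.n_pairs for r in subs.values() if r is not None)
        assert total < overall.n_pairs

    def test_degenerate_subgroup_not_estimable(self, small_tier_table):
        mask = small_tier_table["arm"] == TREATED
        res = subgroup_analysis(
            small_tier_table, {"treated_only": mask}, MAIN_TIERS, ("diabetes",)
        )
        assert res["treated_only"] is None


def test_adding_the_slope_tier_never_increases_ties(medium_tier_table):
    with_slope = analyze(medium_tier_table, TIER_MODELS["main"], ("diabetes",))
    without = analyze(medium_tier_table, TIER_MODELS["model2"], ("diabetes",))
    assert with_slope.p_tie <= without.p_tie


def test_monotone_treatment_benefit():
    """Stronger simulated benefit gives a larger win ratio (seeded runs)."""
    wrs = []
    for hr, slope_t in [(1.0, -3.1), (0.8, -2.0), (0.6, -1.0)]:
        cfg = replace(
            BUILTIN_CONFIGS["dapa_hf_like"],
            n_per_arm=300, seed=99, death_hr_treated=hr,
            chronic_slope_treated=slope_t,
        )
        cohort = generate_cohort(DAPA_HF_LIKE, cfg)
        table = build_tier_table(cohort, MAIN_TIERS, DAPA_HF_LIKE)
        participants, visits = cohort_to_frames(cohort)
        table = attach_slopes(
            table, individual_slopes(participants, visits, design=DAPA_HF_LIKE)
        )
        wrs.append(analyze(table, MAIN_TIERS, ("diabetes",)).win_ratio)
    assert wrs[0] < wrs[1] < wrs[2]
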