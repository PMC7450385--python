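"""Data reduction: binning, the four indicators, chasing proxy, covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lottotraj.indicators import (N_BINS, bin_index, build_indicator_panel,
                                  compute_covariates, describe_sample,
                                  detect_chasing, inverse_log_wager_transform,
                                  log_wager_transform)
from tests.conftest import make_stream

CREATED = pd.Timestamp("2016-01-01", tz="UTC")


def _ts(day: float) -> pd.Timestamp:
    return CREATED + pd.Timedelta(days=day)


class TestBinIndex:
    @pytest.mark.parametrize("day,expected", [
        (0, 0), (14.99, 0), (15, 1), (29.999, 1), (165, 11), (179, 11),
        (179.99, 11), (180, -1), (500, -1),
    ])
    def test_half_open_bins(self, day, expected):
        assert bin_index(CREATED, [_ts(day)])[0] == expected

    def test_before_creation_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            bin_index(CREATED, [_ts(-0.01)])

    def test_twelve_bins_cover_window(self):
        days = np.arange(0, 180, 0.5)
        bins = bin_index(CREATED, [_ts(d) for d in days])
        assert set(bins) == set(range(N_BINS))


def brute_force_chasing(dep_t: np.ndarray, bet_t: np.ndarray) -> np.ndarray:
    """Exhaustive all-pairs restatement of the proxy, O(n^2).

    For each deposit i (time-sorted): rule (a) counts every earlier deposit
    within the inclusive 12 h window; rule (b) checks every bet for a gap in
    [0 h, 1 h)."""
    d = dep_t.astype("datetime64[s]").astype(np.int64)
    b = bet_t.astype("datetime64[s]").astype(np.int64)
    flags = np.zeros(len(d), dtype=bool)
    for i, t in enumerate(d):
        gaps = t - d[:i]
        rule_a = int(((gaps >= 0) & (gaps <= 12 * 3600)).sum()) >= 2
        bgaps = t - b
        rule_b = bool(((bgaps >= 0) & (bgaps < 3600)).any()) if len(b) else False
        flags[i] = rule_a or rule_b
    return flags


def _chasing_stream(dep_hours, bet_hours):
    rows = [("P1", _ts(1) + pd.Timedelta(hours=h), "deposit", 10.0, None, None)
            for h in dep_hours]
    rows += [("P1", _ts(1) + pd.Timedelta(hours=h), "bet", 2.0, "G00",
              "deferred") for h in bet_hours]
    return make_stream(rows)


class TestChasingDetector:
    def test_burst_flags_third_deposit_only(self):
        # deposits at 00:00, 05:00, 11:30, no bets -> only the 11:30 one
        s = _chasing_stream([0, 5, 11.5], [])
        flags = detect_chasing(s.events)
        dep = s.events.sort_values("timestamp")
        assert flags[dep.index].tolist() == [False, False, True]

    def test_deposit_shortly_after_bet_flags(self):
        s = _chasing_stream([1.5], [1.0])  # 30 min after the bet
        assert detect_chasing(s.events).sum() == 1

    def test_sparse_deposits_no_flags(self):
        s = _chasing_stream([0, 13], [])
        assert detect_chasing(s.events).sum() == 0

    def test_exactly_one_hour_does_not_flag(self):
        s = _chasing_stream([2.0], [1.0])
        assert detect_chasing(s.events).sum() == 0

    def test_exactly_twelve_hours_counts_in_window(self):
        # inclusive 12 h window: deposits at 0, 6, 12 -> third one flagged
        s = _chasing_stream([0, 6, 12], [])
        assert detect_chasing(s.events).sum() == 1

    def test_count_all_burst_convention(self):
        s = _chasing_stream([0, 5, 11.5], [])
        assert detect_chasing(s.events, count_all_burst=True).sum() == 3

    def test_unsorted_input_handled(self):
        s = _chasing_stream([11.5, 0, 5], [])
        assert detect_chasing(s.events).sum() == 1

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        n_dep, n_bet = rng.integers(0, 60), rng.integers(0, 60)
        dep = np.sort(rng.uniform(0, 96, n_dep))   # hours over 4 days
        bet = np.sort(rng.uniform(0, 96, n_bet))
        s = _chasing_stream(dep, bet)
        flags = detect_chasing(s.events)
        got = flags[s.events.sort_values("timestamp", kind="stable")
                    .pipe(lambda d: d[d["event_type"] == "deposit"]).index]
        dep_t = (CREATED.tz_localize(None) + pd.to_timedelta(dep + 24, "h")
                 ).to_numpy().astype("datetime64[s]")
        bet_t = (CREATED.tz_localize(None) + pd.to_timedelta(bet + 24, "h")
                 ).to_numpy().astype("datetime64[s]")
        assert got.tolist() == brute_force_chasing(dep_t, bet_t).tolist()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 96 * 60), max_size=25),
           st.lists(st.integers(0, 96 * 60), max_size=25))
    def test_property_matches_brute_force(self, dep_min, bet_min):
        dep = np.sort(np.array(dep_min, dtype=float)) / 60.0
        bet = np.sort(np.array(bet_min, dtype=float)) / 60.0
        if len(dep) == 0:
            return
        s = _chasing_stream(dep, bet)
        flags = detect_chasing(s.events)
        got = flags[s.events.sort_values("timestamp", kind="stable")
                    .pipe(lambda d: d[d["event_type"] == "deposit"]).index]
        to_t = lambda h: (CREATED.tz_localize(None)
                          + pd.to_timedelta(h + 24, "h")
                          ).to_numpy().astype("datetime64[s]")
        assert got.tolist() == brute_force_chasing(to_t(dep), to_t(bet)).tolist()


class TestPanel:
    def test_exactly_12_bins_per_player(self, cohort, panel):
        counts = panel.groupby("player_id")["bin"].agg(["count", "nunique"])
        assert (counts["count"] == N_BINS).all()
        assert (counts["nunique"] == N_BINS).all()
        assert set(panel["bin"]) == set(range(N_BINS))

    def test_partition_conservation(self, cohort, panel):
        """Every in-window bet lands in exactly one bin: bin sums reconcile
        with per-player stream totals."""
        ev = cohort.events.merge(
            cohort.players[["player_id", "account_created"]], on="player_id")
        days = (ev["timestamp"]
                - ev["account_created"].dt.tz_localize("UTC")) / pd.Timedelta(days=1)
        bets = ev[(ev["event_type"] == "bet") & (days < 180)]
        totals = bets.groupby("player_id")["amount"].sum()
        panel_totals = panel.groupby("player_id")["wagered"].sum()
        pd.testing.assert_series_equal(
            panel_totals[totals.index].rename("amount"), totals,
            check_exact=False, rtol=1e-12)

    def test_indicator_ranges(self, panel):
        assert (panel["gambling_days"].between(0, 15)).all()
        assert (panel[["wagered", "chasing", "involvement"]] >= 0).all().all()
        for col in ("gambling_days", "chasing", "involvement"):
            assert np.issubdtype(panel[col].dtype, np.integer)

    def test_simple_stream_values(self):
        rows = [
            ("P1", _ts(1.2), "bet", 2.00, "A", "deferred"),
            ("P1", _ts(1.3), "bet", 3.50, "A", "deferred"),
            ("P1", _ts(9.0), "bet", 1.00, "B", "instant"),
            ("P1", _ts(20.0), "bet", 5.00, "B", "instant"),
        ]
        panel = build_indicator_panel(make_stream(rows))
        b0 = panel[(panel["player_id"] == "P1") & (panel["bin"] == 0)].iloc[0]
        assert b0["wagered"] == pytest.approx(6.50)
        assert b0["gambling_days"] == 2   # days 1 and 9
        assert b0["involvement"] == 2     # games A and B
        b1 = panel[(panel["player_id"] == "P1") & (panel["bin"] == 1)].iloc[0]
        assert b1["wagered"] == pytest.approx(5.00)
        assert panel.loc[panel["bin"] > 1, "wagered"].eq(0).all()


class TestCovariates:
    def test_net_loss_formula(self):
        rows = [
            ("P1", _ts(1), "bet", 100.0, "A", "deferred"),
            ("P1", _ts(2), "win", 40.0, None, None),
            ("P1", _ts(3), "promo_credit", 10.0, None, None),
        ]
        cov = compute_covariates(make_stream(rows))
        assert cov.loc[0, "net_loss"] == pytest.approx(50.0)

    def test_negative_net_loss_accepted(self):
        rows = [
            ("P1", _ts(1), "bet", 10.0, "A", "deferred"),
            ("P1", _ts(2), "win", 200.0, None, None),
        ]
        cov = compute_covariates(make_stream(rows))
        assert cov.loc[0, "net_loss"] == pytest.approx(-190.0)

    def test_largest_single_day_deposit(self):
        rows = [
            ("P1", _ts(1.1), "deposit", 20.0, None, None),
            ("P1", _ts(1.8), "deposit", 30.0, None, None),
            ("P1", _ts(5.0), "deposit", 40.0, None, None),
        ]
        cov = compute_covariates(make_stream(rows))
        assert cov.loc[0, "largest_single_day_deposit"] == pytest.approx(50.0)
        assert cov.loc[0, "cumulative_deposits"] == pytest.approx(90.0)

    def test_pct_instant_by_count_and_zero_bets(self):
        rows = [
            ("P1", _ts(1), "bet", 5.0, "A", "instant"),
            ("P1", _ts(2), "bet", 500.0, "B", "deferred"),
            ("P1", _ts(3), "bet", 5.0, "A", "instant"),
            ("P2", _ts(1), "deposit", 10.0, None, None),
        ]
        cov = compute_covariates(make_stream(rows)).set_index("player_id")
        assert cov.loc["P1", "pct_instant"] == pytest.approx(100 * 2 / 3)
        assert cov.loc["P2", "pct_instant"] == 0.0

    def test_invariants_on_cohort(self, covariates):
        assert covariates["pct_instant"].between(0, 100).all()
        assert (covariates["largest_single_day_deposit"]
                <= covariates["cumulative_deposits"] + 1e-9).all()


class TestLogWagerTransform:
    def test_zero_maps_to_zero(self):
        assert log_wager_transform(0) == 0.0

    def test_inverse_roundtrip(self):
        x = np.array([0.0, 1.7, 19.0, 147.0])
        assert inverse_log_wager_transform(log_wager_transform(x)) == pytest.approx(x)

    def test_transform_anchors_match_axis_labels(self):
        """Whole-euro axis anchors 2/6/19/54/147 sit at 1..5 on the
        transformed scale, within the slack their euro rounding implies."""
        for k, euros in enumerate([2, 6, 19, 54, 147], start=1):
            assert round(inverse_log_wager_transform(k)) == euros
            assert abs(log_wager_transform(euros) - k) <= 0.5 / (euros + 0.5) + 1e-12


class TestDescribeSample:
    def test_hand_computed_decomposition(self):
        # 2 players x 2 months; monthly wagered A: 1, 3 and B: 5, 7
        rows = []
        for pid, (m1, m2) in {"A": (1.0, 3.0), "B": (5.0, 7.0)}.items():
            rows.append((pid, _ts(2), "bet", m1, "G", "deferred"))
            rows.append((pid, _ts(32), "bet", m2, "G", "deferred"))
        panel = build_indicator_panel(make_stream(rows))
        desc = describe_sample(panel).indicators.loc["wagered"]
        # months 3..6 are all-zero observed months; restrict to a 2-month
        # panel by computing on bins 0..3 only
        panel2 = panel[panel["bin"] < 4]
        desc = describe_sample(panel2).indicators.loc["wagered"]
        assert desc["mean"] == pytest.approx(4.0)
        assert desc["sd"] == pytest.approx(np.sqrt(20 / 3))
        assert desc["sd_between"] == pytest.approx(np.sqrt(8.0))
        assert desc["sd_within"] == pytest.approx(np.sqrt(4 / 3))
        assert desc["min"] == 1.0 and desc["max"] == 7.0

    def test_constant_players_zero_within_sd(self):
        rows = []
        for m in range(6):
            rows.append(("A", _ts(30 * m + 2), "bet", 4.0, "G", "deferred"))
            rows.append(("B", _ts(30 * m + 2), "bet", 9.0, "G", "deferred"))
        panel = build_indicator_panel(make_stream(rows))
        desc = describe_sample(panel).indicators.loc["wagered"]
        assert desc["sd_within"] == pytest.approx(0.0)
        assert desc["sd_between"] == pytest.approx(np.std([4.0, 9.0], ddof=1))

    def test_identical_players_zero_between_sd(self):
        rows = []
        for pid in ("A", "B", "C"):
            for m, amt in enumerate([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]):
                rows.append((pid, _ts(30 * m + 2), "bet", amt, "G", "deferred"))
        panel = build_indicator_panel(make_stream(rows))
        desc = describe_sample(panel).indicators.loc["wagered"]
        assert desc["sd_between"] == pytest.approx(0.0)
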