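"""Reduce raw transaction streams to 15-day-binned behavioral indicators.

Four per-player indicator series on a 12-point grid covering the first six
months after account creation (half-open 15-day bins, bin 0 starting on the
account-creation day):

* ``wagered``         — total stakes (EUR) in the bin;
* ``gambling_days``   — distinct calendar days with at least one bet;
* ``chasing``         — deposits flagged by the within-session chasing proxy;
* ``involvement``     — distinct games bet on (breadth of involvement).

The chasing proxy flags a deposit when it is the third-or-later deposit
within a rolling 12-hour window, or when it falls less than one hour after a
bet — recurrent or immediately-post-bet deposits indicate unplanned
continuation of play to recover losses.

Bins with no activity are observed zeros, not missing data: inactivity is
behavior, and near-zero trajectory tails are part of the signal.

Six-month covariates (age, gender, cumulative and largest single-day
deposits, % instant-lottery bets, net loss = wagers - winnings - promotional
credits, self-exclusion, highest risk tag) are computed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lottotraj.synthetic import EventStream

__all__ = [
    "N_BINS",
    "BIN_DAYS",
    "INDICATORS",
    "bin_index",
    "detect_chasing",
    "build_indicator_panel",
    "compute_covariates",
    "log_wager_transform",
    "inverse_log_wager_transform",
    "describe_sample",
]

BIN_DAYS = 15
N_BINS = 12
INDICATORS = ("wagered", "gambling_days", "chasing", "involvement")

_H12 = np.timedelta64(12 * 3600, "s")
_H1 = np.timedelta64(3600, "s")


def bin_index(account_created, timestamps) -> np.ndarray:
    """15-day bin index of each timestamp; -1 marks out-of-window events.

    Bin t covers days [15t, 15(t+1)) since account creation, day 0 being the
    creation day itself; events at day >= 180 are out of window.  Raises if
    any timestamp precedes account creation.
    """
    ts = pd.to_datetime(pd.Series(np.atleast_1d(timestamps)), utc=True)
    created = pd.Timestamp(account_created)
    if created.tzinfo is None:
        created = created.tz_localize("UTC")
    days = (ts - created) / pd.Timedelta(days=1)
    if (days < 0).any():
        raise ValueError("timestamp precedes account creation")
    t = np.floor(days.to_numpy() / BIN_DAYS).astype(int)
    t[t >= N_BINS] = -1
    return t


def _flag_chasing_one(dep_t: np.ndarray, bet_t: np.ndarray,
                      count_all_burst: bool = False) -> np.ndarray:
    """Flags for one player's sorted deposit times against sorted bet times."""
    flags = np.zeros(len(dep_t), dtype=bool)
    if len(dep_t):
        # rule (a): >=2 other deposits in the inclusive window [t-12h, t]
        lo = np.searchsorted(dep_t, dep_t - _H12, side="left")
        in_window = np.arange(len(dep_t)) - lo  # preceding deposits in window
        flags |= in_window >= 2
        if count_all_burst:
            # alternative convention: every member of a >=3 burst counts
            hi = np.searchsorted(dep_t, dep_t + _H12, side="right")
            flags |= (hi - lo) >= 3
    if len(bet_t) and len(dep_t):
        # rule (b): strictly less than 1 h after the nearest preceding bet
        # (a deposit at the bet's own timestamp counts; exactly 1 h does not)
        prev = np.searchsorted(bet_t, dep_t, side="right") - 1
        has_prev = prev >= 0
        delta = dep_t[has_prev] - bet_t[prev[has_prev]]
        f = np.zeros(len(dep_t), dtype=bool)
        f[has_prev] = delta < _H1
        flags |= f
    return flags


def detect_chasing(events: pd.DataFrame, count_all_burst: bool = False) -> pd.Series:
    """Boolean flag per event row: deposit satisfying the chasing proxy.

    A deposit is flagged iff (a) at least two other deposits by the same
    player fall in the 12 hours up to and including it (i.e. it is the
    third-or-later of a burst), or (b) it occurs strictly less than one hour
    after a bet by that player.  With ``count_all_burst=True`` every deposit
    belonging to a >=3-in-12h burst is flagged, not only the third-and-later
    ones.  Input need not be sorted; flags are returned on the input index.
    """
    flags = pd.Series(False, index=events.index)
    for _, grp in events.groupby("player_id", sort=False):
        grp = grp.sort_values("timestamp", kind="stable")
        ts = grp["timestamp"]
        if ts.dt.tz is not None:
            ts = ts.dt.tz_localize(None)
        t = ts.to_numpy().astype("datetime64[s]")
        is_dep = (grp["event_type"] == "deposit").to_numpy()
        is_bet = (grp["event_type"] == "bet").to_numpy()
        if not is_dep.any():
            continue
        f = _flag_chasing_one(t[is_dep], t[is_bet], count_all_burst)
        flags.loc[grp.index[is_dep]] = f
    return flags


def build_indicator_panel(stream: EventStream,
                          count_all_burst: bool = False) -> pd.DataFrame:
    """Tidy panel: one row per (player_id, bin), columns = four indicators.

    Every player contributes exactly 12 rows; empty bins are zeros.  Events
    on or after day 180 are excluded.
    """
    ev = stream.events.merge(
        stream.players[["player_id", "account_created"]], on="player_id"
    )
    created = pd.to_datetime(ev["account_created"])
    if created.dt.tz is None:
        created = created.dt.tz_localize("UTC")
    days = (ev["timestamp"] - created) / pd.Timedelta(days=1)
    if (days < 0).any():
        raise ValueError("event precedes account creation")
    ev = ev.assign(
        _day=np.floor(days).astype(int),
        _bin=np.floor(days / BIN_DAYS).astype(int),
        _chase=detect_chasing(stream.events, count_all_burst).to_numpy(),
    )
    ev = ev[ev["_bin"] < N_BINS]

    bets = ev[ev["event_type"] == "bet"]
    g = bets.groupby(["player_id", "_bin"])
    wagered = g["amount"].sum()
    gambling_days = g["_day"].nunique()
    involvement = g["game_id"].nunique()
    chasing = ev[ev["_chase"]].groupby(["player_id", "_bin"]).size()

    idx = pd.MultiIndex.from_product(
        [stream.players["player_id"], range(N_BINS)], names=["player_id", "bin"]
    )
    panel = pd.DataFrame(index=idx)
    panel["wagered"] = wagered.reindex(idx, fill_value=0.0)
    panel["gambling_days"] = gambling_days.reindex(idx, fill_value=0).astype(int)
    panel["chasing"] = chasing.reindex(idx, fill_value=0).astype(int)
    panel["involvement"] = involvement.reindex(idx, fill_value=0).astype(int)
    return panel.reset_index()


def compute_covariates(stream: EventStream,
                       risk_tags: pd.Series | None = None,
                       count_all_burst: bool = False) -> pd.DataFrame:
    """One row per player: six-month covariates.

    net_loss = total wagers - total winnings - promotional credits (negative
    values mean the player netted a win); pct_instant is by bet count;
    risk_tag is the supplied per-player tag (or the synthetic heuristic's).
    """
    from lottotraj.synthetic import assign_synthetic_risk_tags

    ev = stream.events.merge(
        stream.players[["player_id", "account_created"]], on="player_id"
    )
    created = pd.to_datetime(ev["account_created"])
    if created.dt.tz is None:
        created = created.dt.tz_localize("UTC")
    days = (ev["timestamp"] - created) / pd.Timedelta(days=1)
    ev = ev[days < N_BINS * BIN_DAYS].assign(_date=lambda d: d["timestamp"].dt.date)

    def by_type(t: str) -> pd.api.typing.DataFrameGroupBy:
        return ev[ev["event_type"] == t].groupby("player_id")

    pid = stream.players["player_id"]
    out = stream.players[["player_id", "age", "gender"]].set_index("player_id").copy()

    wagers = by_type("bet")["amount"].sum().reindex(pid, fill_value=0.0)
    wins = by_type("win")["amount"].sum().reindex(pid, fill_value=0.0)
    promo = by_type("promo_credit")["amount"].sum().reindex(pid, fill_value=0.0)
    out["net_loss"] = wagers - wins - promo

    dep = ev[ev["event_type"] == "deposit"]
    out["cumulative_deposits"] = (
        dep.groupby("player_id")["amount"].sum().reindex(pid, fill_value=0.0))
    out["largest_single_day_deposit"] = (
        dep.groupby(["player_id", "_date"])["amount"].sum()
        .groupby("player_id").max().reindex(pid, fill_value=0.0))

    bets = ev[ev["event_type"] == "bet"]
    n_bets = bets.groupby("player_id").size().reindex(pid, fill_value=0)
    n_inst = (bets[bets["game_type"] == "instant"].groupby("player_id").size()
              .reindex(pid, fill_value=0))
    out["pct_instant"] = np.where(n_bets > 0, 100.0 * n_inst / n_bets.replace(0, 1), 0.0)

    n_excl = (ev[ev["event_type"] == "self_exclusion"].groupby("player_id").size()
              .reindex(pid, fill_value=0))
    out["self_exclusion"] = np.where(n_excl > 0, "yes", "no")

    if risk_tags is None:
        risk_tags = assign_synthetic_risk_tags(stream)
    out["risk_tag"] = risk_tags.reindex(pid)
    return out.reset_index()


def log_wager_transform(x) -> np.ndarray | float:
    """ln(x + 1) transform applied to the wagered indicator before modeling.

    Compresses the heavy right tail of stakes while keeping zero at zero;
    on this scale 1 ~ EUR 2, 2 ~ EUR 6, 3 ~ EUR 19, 4 ~ EUR 54, 5 ~ EUR 147.
    """
    return np.log1p(x)


def inverse_log_wager_transform(y) -> np.ndarray | float:
    """Inverse of :func:`log_wager_transform`: EUR value for a transformed y."""
    return np.expm1(y)


@dataclass
class SampleDescription:
    """Descriptive table over monthly-aggregated indicators + covariates."""

    indicators: pd.DataFrame  # mean, sd, sd_between, sd_within, min, max
    covariates: pd.DataFrame


def describe_sample(panel: pd.DataFrame,
                    covariates: pd.DataFrame | None = None) -> SampleDescription:
    """Cohort description with a between/within variance decomposition.

    Indicators are first aggregated to monthly values (consecutive 15-day
    bins summed in pairs).  For each indicator: overall mean and SD across
    all player-months, between-subject SD (SD of the player means), and
    within-subject SD (SD of player-mean-centered values), plus min/max.
    """
    p = panel.copy()
    p["month"] = p["bin"] // 2
    monthly = (p.groupby(["player_id", "month"])[list(INDICATORS)]
               .sum().reset_index())

    rows = {}
    for var in INDICATORS:
        v = monthly[var].astype(float)
        pm = monthly.groupby("player_id")[var].transform("mean").astype(float)
        rows[var] = {
            "mean": v.mean(),
            "sd": v.std(ddof=1),
            "sd_between": monthly.groupby("player_id")[var].mean().std(ddof=1),
            "sd_within": (v - pm).std(ddof=1),
            "min": v.min(),
            "max": v.max(),
        }
    ind = pd.DataFrame(rows).T

    cov_rows = {}
    if covariates is not None:
        for var in ("age", "cumulative_deposits", "largest_single_day_deposit",
                    "net_loss", "pct_instant"):
            v = covariates[var].astype(float)
            cov_rows[var] = {"mean": v.mean(), "sd": v.std(ddof=1),
                             "min": v.min(), "max": v.max()}
        for var, val in (("gender", "female"), ("self_exclusion", "yes")):
            cov_rows[f"{var}={val}"] = {
                "mean": 100.0 * (covariates[var] == val).mean(),
                "sd": np.nan, "min": np.nan, "max": np.nan}
        for tag in ("green", "orange", "red"):
            cov_rows[f"risk_tag={tag}"] = {
                "mean": 100.0 * (covariates["risk_tag"] == tag).mean(),
                "sd": np.nan, "min": np.nan, "max": np.nan}
    return SampleDescription(indicators=ind, covariates=pd.DataFrame(cov_rows).T)
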