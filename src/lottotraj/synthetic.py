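"""Seeded synthetic cohorts of online-lottery transaction streams.

Real operator data of this kind (per-event logs of bets, deposits, wins and
self-exclusions for newly registered lottery accounts) is proprietary, so the
package ships a generator that emulates a cohort of new accounts observed for
six months from account creation.  Events are generated at the timestamp
level — not pre-binned — because the chasing proxy downstream is defined on
raw deposit/bet timing.

The default configuration encodes five latent behavioral classes whose
mixture weights, trajectory shapes (stable / declining / parabolic activity
peaking near day 120) and risk markers (chasing bursts, self-exclusion
restricted to the highest-risk class at ~10%) mirror the published structure
of early online-lottery cohorts.  All event-level rates are calibration
choices, documented in ``docs/methods.md``; they are not estimates from any
real dataset.

Mechanism, per player and day: a gambling session occurs with a class- and
time-varying Bernoulli rate; sessions hold 1+Poisson bets with log-normal
stakes on games drawn from a class-specific pool split between deferred and
instant lotteries.  Deposits are balance-driven: a top-up is made at session
start whenever the planned stakes exceed the current balance.  Session start
times are confined to 09:00-21:00 and a session spans at most ~2 h, which
guarantees that balance-driven deposits can never satisfy the chasing proxy
(never <1 h after a bet, never 3 within 12 h).  Chasing-prone classes
additionally emit explicit chasing episodes: a deposit minutes after a bet,
optionally extended into a burst of three deposits inside a 12-hour window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClassParams",
    "CohortConfig",
    "EventStream",
    "RiskTagRule",
    "generate_cohort",
    "assign_synthetic_risk_tags",
    "default_cohort_config",
    "write_events",
    "read_events",
]

OBSERVATION_DAYS = 180
EVENT_TYPES = ("bet", "deposit", "win", "promo_credit", "self_exclusion")

#: earliest account-creation date of the emulated recruitment window
_RECRUITMENT_START = np.datetime64("2015-09-01")
#: width of the recruitment window in days (Sep 2015 - Feb 2016)
_RECRUITMENT_DAYS = 182


@dataclass
class ClassParams:
    """Event-generation parameters for one latent behavioral class.

    ``session_rate_knots`` gives the daily session probability at days 0, 90
    and 180; the rate curve is the quadratic through those three points,
    clipped to [0, 0.95].  Equal knots give a stable class, decreasing knots
    a declining one, and a high middle knot a parabolic class peaking
    mid-window.
    """

    name: str
    weight: float
    session_rate_knots: tuple[float, float, float]
    bets_per_session: float  # mean of the Poisson part; bets = 1 + Poisson
    wager_log_mu: float      # log-scale location of the lognormal stake
    wager_log_sigma: float   # log-scale dispersion of the lognormal stake
    deposit_rate: float      # extra voluntary session-start deposits per day
    chasing_propensity: float  # P(chasing episode | session)
    n_deferred_games: int
    n_instant_games: int
    instant_share: float     # P(bet placed on an instant lottery)
    self_exclusion_hazard: float  # daily hazard of voluntary self-exclusion
    payout_ratio: float      # expected win per euro wagered
    female_share: float
    age_mean: float = 40.0
    age_sd: float = 12.6

    def session_rate(self, day: np.ndarray) -> np.ndarray:
        r0, r90, r180 = self.session_rate_knots
        # Lagrange quadratic through (0, r0), (90, r90), (180, r180)
        d = np.asarray(day, dtype=float)
        rate = (
            r0 * (d - 90.0) * (d - 180.0) / (90.0 * 180.0)
            - r90 * d * (d - 180.0) / (90.0 * 90.0)
            + r180 * d * (d - 90.0) / (180.0 * 90.0)
        )
        return np.clip(rate, 0.0, 0.95)


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort; deterministic given ``seed``."""

    n_players: int
    classes: list[ClassParams]
    observation_days: int = OBSERVATION_DAYS
    promo_credit_rate: float = 0.01   # small promotional credits per day
    deposit_unit: float = 10.0        # top-ups rounded up to this granularity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_players < 1:
            raise ValueError(f"n_players must be >= 1, got {self.n_players}")
        if self.observation_days < 15:
            raise ValueError(
                f"observation_days must be >= 15, got {self.observation_days}"
            )
        if not self.classes:
            raise ValueError("classes must be a nonempty list")
        w = np.array([c.weight for c in self.classes], dtype=float)
        if np.any(w < 0):
            raise ValueError("class weight must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"class_weights must sum to 1 within 1e-12, got sum {w.sum()!r}"
            )
        for c in self.classes:
            for fname in (
                "deposit_rate",
                "chasing_propensity",
                "self_exclusion_hazard",
                "payout_ratio",
                "wager_log_sigma",
                "bets_per_session",
            ):
                if getattr(c, fname) < 0:
                    raise ValueError(
                        f"class {c.name!r}: {fname} must be nonnegative, "
                        f"got {getattr(c, fname)}"
                    )
            if any(r < 0 for r in c.session_rate_knots):
                raise ValueError(
                    f"class {c.name!r}: session_rate_knots must be nonnegative"
                )
            if c.n_deferred_games + c.n_instant_games < 1:
                raise ValueError(f"class {c.name!r}: game pool must be nonempty")

    @property
    def class_weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.classes], dtype=float)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["classes"] = [dataclasses.asdict(c) for c in self.classes]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        doc = yaml.safe_load(Path(path).read_text())
        classes = [
            ClassParams(**{**c, "session_rate_knots": tuple(c["session_rate_knots"])})
            for c in doc.pop("classes")
        ]
        return cls(classes=classes, **doc)


@dataclass
class EventStream:
    """Raw cohort data: one row per event, plus a player table.

    ``events`` columns: player_id, timestamp (UTC), event_type, amount (EUR),
    game_id, game_type ({deferred, instant}; bets only).
    ``players`` columns: player_id, account_created (date), age, gender,
    true_class (synthetic only; absent/NaN for real data).
    """

    events: pd.DataFrame
    players: pd.DataFrame

    def validate(self) -> None:
        ev, pl = self.events, self.players
        merged = ev.merge(pl[["player_id", "account_created"]], on="player_id")
        if (merged["timestamp"].dt.tz_localize(None).to_numpy()
                < merged["account_created"].to_numpy()).any():
            raise ValueError("event precedes the player's account creation")
        money = ev["event_type"].isin(["bet", "deposit"])
        if (ev.loc[money, "amount"] <= 0).any():
            raise ValueError("bet and deposit amounts must be > 0")
        has_game = ev["game_id"].notna()
        if not (has_game == (ev["event_type"] == "bet")).all():
            raise ValueError("game_id must be present iff event_type == 'bet'")


@dataclass
class RiskTagRule:
    """Declared heuristic mapping behavior to a {green, orange, red} tag.

    This is a transparent, monotone stand-in for the operator's proprietary
    responsible-gambling classifier (which weighs five weeks of behavior and
    is NOT re-implemented here): the tag escalates with cumulative deposits
    and with the number of chasing episodes, and never de-escalates when
    either grows.
    """

    orange_deposits: float = 150.0
    red_deposits: float = 600.0
    orange_chasing: int = 1
    red_chasing: int = 5


def default_cohort_config(n_players: int = 1200, seed: int = 0) -> CohortConfig:
    """Five-class cohort with the study's class-weight and shape structure.

    Weights 56.8 / 14.8 / 13.9 / 9.7 / 4.8 %; classes range from casual
    low-stake play through steady and declining engagement to a broadly
    involved class and a small high-risk class with chasing bursts, parabolic
    activity peaking near day 112, and a self-exclusion hazard calibrated so
    that ~10.8% self-exclude within the six-month window.
    """
    classes = [
        ClassParams(
            name="casual", weight=0.568,
            session_rate_knots=(0.08, 0.07, 0.06),
            bets_per_session=0.3, wager_log_mu=0.7, wager_log_sigma=0.6,
            deposit_rate=0.0, chasing_propensity=0.0,
            n_deferred_games=2, n_instant_games=1, instant_share=0.21,
            self_exclusion_hazard=0.0, payout_ratio=0.60,
            female_share=0.352,
        ),
        ClassParams(
            name="steady", weight=0.148,
            session_rate_knots=(0.16, 0.18, 0.17),
            bets_per_session=1.0, wager_log_mu=2.0, wager_log_sigma=0.5,
            deposit_rate=0.01, chasing_propensity=0.02,
            n_deferred_games=2, n_instant_games=1, instant_share=0.12,
            self_exclusion_hazard=0.0, payout_ratio=0.92,
            female_share=0.265, age_mean=43.4,
        ),
        ClassParams(
            name="declining", weight=0.139,
            session_rate_knots=(0.40, 0.12, 0.04),
            bets_per_session=1.0, wager_log_mu=1.8, wager_log_sigma=0.6,
            deposit_rate=0.0, chasing_propensity=0.02,
            n_deferred_games=3, n_instant_games=2, instant_share=0.39,
            self_exclusion_hazard=0.0, payout_ratio=0.65,
            female_share=0.379, age_mean=38.2,
        ),
        ClassParams(
            name="broad", weight=0.097,
            session_rate_knots=(0.22, 0.28, 0.24),
            bets_per_session=2.0, wager_log_mu=2.2, wager_log_sigma=0.6,
            deposit_rate=0.01, chasing_propensity=0.05,
            n_deferred_games=4, n_instant_games=5, instant_share=0.65,
            self_exclusion_hazard=0.0, payout_ratio=0.60,
            female_share=0.451,
        ),
        ClassParams(
            name="high_risk", weight=0.048,
            session_rate_knots=(0.30, 0.53, 0.45),
            bets_per_session=4.0, wager_log_mu=3.0, wager_log_sigma=0.8,
            deposit_rate=0.02, chasing_propensity=0.45,
            n_deferred_games=7, n_instant_games=10, instant_share=0.78,
            # P(self-exclusion within 180 d) = 1 - exp(-180 h) = 0.108
            self_exclusion_hazard=6.35e-4, payout_ratio=0.60,
            female_share=0.48, age_mean=41.7,
        ),
    ]
    return CohortConfig(n_players=n_players, classes=classes, seed=seed)


def _player_events(
    cfg: CohortConfig, params: ClassParams, rng: np.random.Generator,
    created: np.datetime64,
) -> list[tuple]:
    """Generate the event rows for one player (timestamps as datetime64[s])."""
    day0 = created.astype("datetime64[s]")
    days = np.arange(cfg.observation_days)
    active = rng.random(cfg.observation_days) < params.session_rate(days)

    # voluntary self-exclusion truncates everything after its day
    excl_day = None
    if params.self_exclusion_hazard > 0:
        hit = rng.random(cfg.observation_days) < params.self_exclusion_hazard
        if hit.any():
            excl_day = int(np.argmax(hit))
            active[excl_day:] = False

    n_def, n_ins = params.n_deferred_games, params.n_instant_games
    rows: list[tuple] = []
    balance = 0.0

    for d in np.flatnonzero(active):
        # session confined to 09:00-21:00 so that consecutive-day funding
        # deposits are always >= 10 h away from any earlier bet
        start = day0 + np.timedelta64(int(d) * 86400 + int(rng.integers(9 * 3600, 21 * 3600)), "s")
        n_bets = 1 + rng.poisson(params.bets_per_session)
        stakes = np.exp(rng.normal(params.wager_log_mu, params.wager_log_sigma, n_bets))
        stakes = np.round(np.maximum(stakes, 0.5), 2)

        need = stakes.sum() - balance
        if need > 0:
            topup = float(np.ceil(need / cfg.deposit_unit) * cfg.deposit_unit)
            rows.append((start, "deposit", topup, None, None))
            balance += topup
        elif rng.random() < params.deposit_rate * 15:
            # occasional voluntary top-up, also at session start
            rows.append((start, "deposit", cfg.deposit_unit, None, None))
            balance += cfg.deposit_unit

        offs = np.cumsum(rng.integers(60, 600, n_bets))  # bets 1-10 min apart
        t_bet = start + offs.astype("timedelta64[s]")
        for j in range(n_bets):
            instant = rng.random() < params.instant_share
            pool, gtype, g0 = (n_ins, "instant", n_def) if instant else (n_def, "deferred", 0)
            if pool == 0:  # class pool lacks this type; fall back to the other
                pool, gtype, g0 = (n_def, "deferred", 0) if instant else (n_ins, "instant", n_def)
            gid = f"G{g0 + int(rng.integers(pool)):02d}"
            amt = float(stakes[j])
            rows.append((t_bet[j], "bet", amt, gid, gtype))
            balance -= amt
            if rng.random() < params.payout_ratio / 3.0:
                win = np.round(amt * 3.0 * np.exp(rng.normal(0, 0.5)), 2)
                rows.append((t_bet[j] + np.timedelta64(30, "s"), "win", float(win), None, None))
                balance += win

        if rng.random() < params.chasing_propensity:
            # explicit chasing episode: deposit minutes after the last bet,
            # optionally extended into a >=3-deposit burst within 12 h
            last = t_bet[-1]
            amt = float(cfg.deposit_unit)
            rows.append((last + np.timedelta64(int(rng.integers(300, 3000)), "s"),
                         "deposit", amt, None, None))
            balance += amt
            if rng.random() < 0.6:
                for off_h in (3.0 + rng.random() * 2, 7.0 + rng.random() * 3):
                    rows.append((last + np.timedelta64(int(off_h * 3600), "s"),
                                 "deposit", amt, None, None))
                    balance += amt

    # sprinkle small promotional e-credits (operator marketing), any hour
    n_promo = rng.poisson(cfg.promo_credit_rate * cfg.observation_days)
    last_day = cfg.observation_days if excl_day is None else excl_day
    if n_promo and last_day > 0:
        for d in rng.integers(0, last_day, n_promo):
            t = day0 + np.timedelta64(int(d) * 86400 + int(rng.integers(0, 86400)), "s")
            rows.append((t, "promo_credit", float(rng.integers(2, 6)), None, None))

    if excl_day is not None:
        t = day0 + np.timedelta64(int(excl_day) * 86400 + int(rng.integers(0, 86400)), "s")
        rows.append((t, "self_exclusion", 0.0, None, None))

    return rows


def generate_cohort(config: CohortConfig) -> EventStream:
    """Generate a synthetic cohort; byte-identical for identical config+seed.

    Each player draws a latent class from ``config.class_weights``; events are
    then generated by the class's declared mechanism.  Per-player RNG streams
    are derived from ``(seed, player_index)`` so the stream for a given player
    does not depend on cohort size.
    """
    head = np.random.default_rng(config.seed)
    labels = head.choice(len(config.classes), size=config.n_players,
                         p=config.class_weights)
    created = (_RECRUITMENT_START
               + head.integers(0, _RECRUITMENT_DAYS, config.n_players)
               .astype("timedelta64[D]"))

    all_rows: list[tuple] = []
    players: list[tuple] = []
    for i in range(config.n_players):
        params = config.classes[labels[i]]
        rng = np.random.default_rng([config.seed, i])
        age = int(np.clip(rng.normal(params.age_mean, params.age_sd), 18, 85))
        gender = "female" if rng.random() < params.female_share else "male"
        pid = f"P{i:05d}"
        players.append((pid, created[i], age, gender, params.name))
        for row in _player_events(config, params, rng, created[i]):
            all_rows.append((pid, *row))

    events = pd.DataFrame(
        all_rows, columns=["player_id", "timestamp", "event_type", "amount",
                           "game_id", "game_type"],
    )
    events["timestamp"] = pd.to_datetime(events["timestamp"], utc=True)
    events = events.sort_values(["player_id", "timestamp"],
                                kind="stable").reset_index(drop=True)
    players_df = pd.DataFrame(
        players, columns=["player_id", "account_created", "age", "gender",
                          "true_class"],
    )
    players_df["account_created"] = pd.to_datetime(players_df["account_created"])
    return EventStream(events=events, players=players_df)


def assign_synthetic_risk_tags(
    stream: EventStream, rule: RiskTagRule | None = None
) -> pd.Series:
    """Per-player {green, orange, red} tag from a declared monotone heuristic.

    NOT the operator's proprietary classifier — a documented stand-in that
    escalates with cumulative deposits and chasing episodes (see
    :class:`RiskTagRule`).  Monotone: raising deposits or chasing never
    lowers the tag.
    """
    from lottotraj.indicators import detect_chasing

    if stream.events.empty:
        raise ValueError("cannot tag an empty event stream")
    rule = rule or RiskTagRule()
    ev = stream.events
    deposits = (ev[ev["event_type"] == "deposit"]
                .groupby("player_id")["amount"].sum())
    chasing = detect_chasing(ev).groupby(ev["player_id"]).sum()

    tags = pd.Series("green", index=stream.players["player_id"], name="risk_tag")
    dep = deposits.reindex(tags.index).fillna(0.0)
    cha = chasing.reindex(tags.index).fillna(0).astype(int)
    tags[(dep >= rule.orange_deposits) | (cha >= rule.orange_chasing)] = "orange"
    tags[(dep >= rule.red_deposits) | (cha >= rule.red_chasing)] = "red"
    return tags


def write_events(stream: EventStream, path: str | Path) -> None:
    """Write the event table (CSV or Parquet by extension) + a players table."""
    path = Path(path)
    ev = stream.events.copy()
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    pl = stream.players.copy()
    pl["account_created"] = pl["account_created"].dt.strftime("%Y-%m-%d")
    if path.suffix == ".parquet":
        stream.events.to_parquet(path, index=False)
        stream.players.to_parquet(path.with_name(path.stem + "_players.parquet"),
                                  index=False)
    else:
        ev.to_csv(path, index=False)
        pl.to_csv(path.with_name(path.stem + "_players" + path.suffix), index=False)


def read_events(path: str | Path) -> EventStream:
    path = Path(path)
    if path.suffix == ".parquet":
        events = pd.read_parquet(path)
        players = pd.read_parquet(path.with_name(path.stem + "_players.parquet"))
    else:
        events = pd.read_csv(path, float_precision="round_trip")
        players = pd.read_csv(path.with_name(path.stem + "_players" + path.suffix),
                              float_precision="round_trip")
    events["timestamp"] = pd.to_datetime(events["timestamp"], utc=True)
    players["account_created"] = pd.to_datetime(players["account_created"])
    if "game_id" in events:
        events["game_id"] = events["game_id"].where(events["game_id"].notna(), None)
    return EventStream(events=events, players=players)
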