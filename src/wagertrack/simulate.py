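"""Generative simulator for online-casino wager/win transaction streams.

The generator produces a player population and a timestamped wager log with
the statistical structure the downstream analysis assumes:

* bets are lognormal, moment-matched to each game's (avg_bet, sd_bet);
* wins follow a hit/miss Bernoulli with probability 1/hit_frequency; a hit
  pays ``bet * M`` where the multiplier M has mean ``rtp * hit_frequency``,
  so the per-wager expected win is exactly ``rtp * bet`` for any bet
  distribution;
* within-session inter-wager gaps are lognormal truncated at the session
  threshold (900 s), with the location parameter solved so the truncated
  population mean equals the game's event-frequency target;
* players arrive at sessions via per-player homogeneous Poisson processes
  over the horizon; each session plays exactly one game drawn from the
  player's preference weights, with a geometric number of wagers.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .specs import (
    ConfigurationError,
    GameSpec,
    default_game_specs,
    default_group_weights,
)

__all__ = [
    "DemographicsConfig",
    "EffectSpec",
    "SimConfig",
    "make_game_portfolio",
    "plant_effect",
    "sample_bet",
    "sample_win",
    "sample_session_wagers",
    "simulate_population",
]

EVENT_COLUMNS = ["player_id", "game_id", "group", "timestamp", "bet", "win"]


# ---------------------------------------------------------------------------
# lognormal moment matching

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD; sigma=0 is the
    degenerate point mass at *mean*."""
    if not math.isfinite(mean) or mean <= 0:
        raise ConfigurationError(f"lognormal mean must be positive, got {mean}")
    if sd < 0 or not math.isfinite(sd):
        raise ConfigurationError(f"lognormal sd must be >= 0, got {sd}")
    if sd == 0:
        return math.log(mean), 0.0
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def _draw_lognormal(rng: np.random.Generator, mu: float, sigma: float, n: int) -> np.ndarray:
    if sigma == 0.0:
        return np.full(n, math.exp(mu))
    return rng.lognormal(mu, sigma, n)


@lru_cache(maxsize=256)
def _gap_params(mean: float, sd: float, cap: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose ``<= cap`` truncation has mean *mean*.

    sigma comes from untruncated moment matching; mu is then root-solved so
    that the truncated mean hits the target exactly (naive truncation would
    bias the mean low — by about 6% for a fast, heavy-tailed game).
    """
    if mean >= cap:
        raise ConfigurationError(
            f"event_freq_mean {mean} must be below the session threshold {cap}"
        )
    mu0, sigma = _lognormal_params(mean, sd)
    if sigma == 0.0:
        return mu0, sigma
    log_cap = math.log(cap)

    def truncated_mean(mu: float) -> float:
        a = (log_cap - mu) / sigma
        return math.exp(mu + 0.5 * sigma**2) * norm.cdf(a - sigma) / norm.cdf(a)

    lo, hi = mu0 - 1.0, mu0 + 1.0
    while truncated_mean(lo) > mean:
        lo -= 2.0
    while truncated_mean(hi) < mean:
        hi += 2.0
    mu = brentq(lambda m: truncated_mean(m) - mean, lo, hi, xtol=1e-12)
    return mu, sigma


def _sample_gaps(spec: GameSpec, n: int, rng: np.random.Generator,
                 cap: float = 900.0) -> np.ndarray:
    """n inter-wager gaps in seconds, all <= cap, mean matched to the spec."""
    mu, sigma = _gap_params(spec.event_freq_mean, spec.event_freq_sd, cap)
    out = _draw_lognormal(rng, mu, sigma, n)
    bad = out > cap
    while bad.any():
        out[bad] = _draw_lognormal(rng, mu, sigma, int(bad.sum()))
        bad = out > cap
    return out


def _win_multiplier_params(spec: GameSpec) -> tuple[float, float]:
    """Lognormal (mu, sigma) of the conditional win multiplier M.

    E[M] = rtp * hit_frequency fixes the per-wager RTP; the dispersion is
    solved so that SD(bet * M) matches the spec's sd_win where feasible.
    When the bet distribution alone already carries more variance than the
    target (high-stake table games), the multiplier degenerates to its mean.
    """
    m = spec.rtp * spec.hit_frequency
    eb2 = spec.avg_bet**2 + spec.sd_bet**2
    em2 = (spec.sd_win**2 + (spec.avg_bet * m) ** 2) / eb2
    s2 = em2 - m**2
    sd = math.sqrt(s2) if s2 > 0 else 0.0
    return _lognormal_params(m, sd)


def _sample_bets(spec: GameSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = _lognormal_params(spec.avg_bet, spec.sd_bet)
    return _draw_lognormal(rng, mu, sigma, n)


def _sample_wins(spec: GameSpec, bets: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(bets)
    hits = rng.random(n) < 1.0 / spec.hit_frequency
    mu, sigma = _win_multiplier_params(spec)
    mult = _draw_lognormal(rng, mu, sigma, n)
    return np.where(hits, bets * mult, 0.0)


# ---------------------------------------------------------------------------
# public single-draw operations

def sample_bet(spec: GameSpec, rng: np.random.Generator) -> float:
    """Draw one strictly positive stake from the game's bet distribution."""
    return float(_sample_bets(spec, 1, rng)[0])


def sample_win(spec: GameSpec, bet: float, rng: np.random.Generator) -> float:
    """Draw the win paid on one wager of size *bet* (0 on a miss)."""
    if bet <= 0:
        raise ValueError(f"bet must be > 0, got {bet}")
    return float(_sample_wins(spec, np.asarray([bet], dtype=float), rng)[0])


def sample_session_wagers(
    spec: GameSpec,
    n_wagers: int,
    start,
    rng: np.random.Generator,
    player_id: str = "p1",
    gap_seconds: float = 900.0,
) -> pd.DataFrame:
    """One session of *n_wagers* wagers on one game, starting at *start*.

    Timestamps are strictly increasing and every consecutive gap is at most
    *gap_seconds*, so the session survives gap-based sessionization intact.
    Returns a wager-event frame (player_id, game_id, group, timestamp, bet,
    win).
    """
    if n_wagers < 1:
        raise ValueError(f"n_wagers must be >= 1, got {n_wagers}")
    start = pd.Timestamp(start)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    gaps = _sample_gaps(spec, n_wagers - 1, rng, cap=gap_seconds)
    # microsecond resolution: exact CSV round trips, still "seconds or finer"
    offsets = np.round(np.concatenate([[0.0], np.cumsum(gaps)]) * 1e6).astype(
        "int64"
    )
    bets = _sample_bets(spec, n_wagers, rng)
    wins = _sample_wins(spec, bets, rng)
    return pd.DataFrame(
        {
            "player_id": player_id,
            "game_id": spec.game_id,
            "group": spec.group,
            "timestamp": start + pd.to_timedelta(offsets, unit="us"),
            "bet": bets,
            "win": wins,
        }
    )


# ---------------------------------------------------------------------------
# game portfolio

# Scaled-down default portfolio: blackjack, live blackjack and roulette are
# standalone games; slots supply the large majority of titles and volume.
DEFAULT_GAMES_PER_GROUP: dict[str, int] = {
    "blackjack": 1,
    "live_blackjack": 1,
    "roulette": 1,
    "live_roulette": 3,
    "slots": 24,
    "video_poker": 4,
}


def make_game_portfolio(
    group_specs: Mapping[str, GameSpec] | None = None,
    games_per_group: Mapping[str, int] | int | None = None,
    jitter: float = 0.10,
    rng: np.random.Generator | int | None = None,
) -> list[GameSpec]:
    """Expand group-level specs into a portfolio of individual games.

    Each game's parameters are multiplicative lognormal perturbations (CV
    *jitter*) of its group's values; the house edge ``1 - rtp`` and the
    excess hit frequency ``hit_frequency - 1`` are jittered on their own
    scales so rtp stays in (0, 1] and hit frequency stays >= 1.  Distinct
    games per group are what gives the game-level design matrix full rank.
    """
    if group_specs is None:
        group_specs = default_game_specs()
    if games_per_group is None:
        games_per_group = DEFAULT_GAMES_PER_GROUP
    if isinstance(games_per_group, int):
        games_per_group = {g: games_per_group for g in group_specs}
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def bump(value: float) -> float:
        if jitter == 0:
            return value
        return float(value * rng.lognormal(-0.5 * math.log1p(jitter**2),
                                           math.sqrt(math.log1p(jitter**2))))

    portfolio = []
    for group, base in group_specs.items():
        n = int(games_per_group.get(group, 0))
        for i in range(1, n + 1):
            portfolio.append(
                GameSpec(
                    game_id=f"{group}_{i:03d}",
                    group=group,
                    rtp=min(1.0 - bump(1.0 - base.rtp), 1.0),
                    hit_frequency=1.0 + bump(base.hit_frequency - 1.0),
                    avg_bet=bump(base.avg_bet),
                    sd_bet=bump(base.sd_bet),
                    sd_win=bump(base.sd_win),
                    event_freq_mean=bump(base.event_freq_mean),
                    event_freq_sd=bump(base.event_freq_sd),
                )
            )
    if not portfolio:
        raise ConfigurationError("empty game portfolio")
    return portfolio


# ---------------------------------------------------------------------------
# population-level configuration

@dataclass(frozen=True)
class DemographicsConfig:
    """Player demographics: age ~ Normal(mean, sd) clipped to age_range,
    gender female with probability p_female."""

    age_mean: float = 43.0
    age_sd: float = 13.11
    age_range: tuple[float, float] = (18.0, 99.0)
    p_female: float = 0.174


@dataclass(frozen=True)
class EffectSpec:
    """A dependence planted into the session-level wager counts.

    kind="step": sessions on games whose *feature* lies strictly below
    *threshold* get mean wager count *low_mean*, the rest *high_mean*.
    kind="linear": the mean wager count is ``intercept + sum(coefficients[f] *
    feature f of the game)``, floored at 1.
    kind="null": no dependence (per-player means are used).
    """

    kind: str = "null"
    outcome: str = "n_bets"
    feature: str = "event_freq_mean"
    threshold: float = 11.79
    low_mean: float = 241.0
    high_mean: float = 39.0
    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome != "n_bets":
            raise ConfigurationError(
                f"plantable outcomes: 'n_bets'; got {self.outcome!r}"
            )
        if self.kind not in ("step", "linear", "null"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        valid = {f.name for f in dataclasses.fields(GameSpec)} - {"game_id", "group"}
        if self.kind == "step" and self.feature not in valid:
            raise ConfigurationError(f"unknown game feature {self.feature!r}")
        if self.kind == "linear":
            unknown = set(self.coefficients) - valid
            if unknown:
                raise ConfigurationError(f"unknown game features {sorted(unknown)}")

    def session_mean(self, spec: GameSpec) -> float:
        if self.kind == "step":
            value = getattr(spec, self.feature)
            return self.low_mean if value < self.threshold else self.high_mean
        if self.kind == "linear":
            mean = self.intercept + sum(
                c * getattr(spec, f) for f, c in self.coefficients.items()
            )
            return max(mean, 1.0)
        raise ConfigurationError("null effect has no session mean")


@dataclass(frozen=True)
class SimConfig:
    """Population-simulation configuration.

    Defaults describe a 140-day observation window in which an average
    player opens about 17.5 sessions (0.873/week) of about 145 wagers each
    — the scale of a mid-size European online-casino operator.  Session
    rates vary across players (gamma with shape ``session_rate_shape``), as
    do per-player mean session lengths (lognormal with CV
    ``wagers_per_session_cv``).
    """

    start: str = "2020-11-27"
    horizon_days: float = 140.0
    session_rate_per_week: float = 0.873
    session_rate_shape: float = 1.0
    wagers_per_session_mean: float = 145.0
    wagers_per_session_cv: float = 0.5
    gap_seconds: float = 900.0
    preference_concentration: float = 5.0
    group_weights: Mapping[str, float] | None = None
    games_per_group: Mapping[str, int] | int | None = None
    game_jitter: float = 0.10
    demographics: DemographicsConfig = field(default_factory=DemographicsConfig)
    effect: EffectSpec | None = None

    def __post_init__(self) -> None:
        if self.horizon_days <= 0 or self.session_rate_per_week <= 0:
            raise ConfigurationError("horizon and session rate must be > 0")
        if self.wagers_per_session_mean < 1:
            raise ConfigurationError("wagers_per_session_mean must be >= 1")
        if self.gap_seconds <= 0:
            raise ConfigurationError("gap_seconds must be > 0")


def plant_effect(config: SimConfig, effect: EffectSpec) -> SimConfig:
    """Return a copy of *config* whose generated data embody *effect*.

    Used to verify parameter recovery: a regression tree should find a
    planted step threshold, and OLS should recover planted linear
    coefficients, from the simulated stream alone.
    """
    if not isinstance(effect, EffectSpec):
        raise ConfigurationError("effect must be an EffectSpec")
    return dataclasses.replace(config, effect=effect if effect.kind != "null" else None)


# ---------------------------------------------------------------------------
# population simulation

def _sample_players(
    n_players: int, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    demo = config.demographics
    lo, hi = demo.age_range
    ages = np.clip(rng.normal(demo.age_mean, demo.age_sd, n_players), lo, hi)
    female = rng.random(n_players) < demo.p_female
    rate = rng.gamma(
        config.session_rate_shape,
        config.session_rate_per_week / config.session_rate_shape,
        n_players,
    )
    wps_mu, wps_sigma = _lognormal_params(
        config.wagers_per_session_mean,
        config.wagers_per_session_cv * config.wagers_per_session_mean,
    )
    wps = np.maximum(_draw_lognormal(rng, wps_mu, wps_sigma, n_players), 1.0)
    width = len(str(max(n_players, 1)))
    return pd.DataFrame(
        {
            "player_id": [f"p{i:0{width}d}" for i in range(1, n_players + 1)],
            "age": ages,
            "gender": np.where(female, "female", "male"),
            "sessions_per_week": rate,
            "wagers_per_session_mean": wps,
        }
    )


def _grouped_cumsum(values: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at every group boundary (first value kept)."""
    starts = np.r_[0, np.cumsum(sizes)[:-1]]
    cs = np.cumsum(values)
    base = np.repeat(cs[starts] - values[starts], sizes)
    return cs - base


def simulate_population(
    n_players: int,
    specs: Sequence[GameSpec] | Mapping[str, GameSpec] | None = None,
    config: SimConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a player population and its full wager log.

    Returns ``(events, players)``: the event frame has one row per wager
    (player_id, game_id, group, timestamp, bet, win), sorted by player and
    time; the player frame carries player_id, age, gender.  Identical
    ``(n_players, specs, config, seed)`` reproduce identical frames.
    """
    if n_players < 1:
        raise ValueError(f"n_players must be >= 1, got {n_players}")
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = make_game_portfolio(
            games_per_group=config.games_per_group,
            jitter=config.game_jitter,
            rng=rng,
        )
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    spec_by_id = {s.game_id: s for s in specs}

    players = _sample_players(n_players, config, rng)

    # preference weights over games: configured group weights split evenly
    # across the group's games, then per-player Dirichlet jitter around them
    if config.group_weights is not None:
        base_group = dict(config.group_weights)
    else:
        base_group = default_group_weights()
    group_sizes = pd.Series([s.group for s in specs]).value_counts()
    base = np.array(
        [base_group.get(s.group, 0.0) / group_sizes[s.group] for s in specs],
        dtype=float,
    )
    if base.sum() <= 0:  # configured weights miss every spec: fall back to uniform
        base = np.ones(len(specs))
    base = base / base.sum()
    alpha = np.maximum(config.preference_concentration * base, 1e-3)
    pref = rng.dirichlet(alpha, size=n_players)

    weeks = config.horizon_days / 7.0
    n_sessions = rng.poisson(players["sessions_per_week"].to_numpy() * weeks)
    total_sessions = int(n_sessions.sum())
    if total_sessions == 0:
        empty = pd.DataFrame(
            {
                "player_id": pd.Series(dtype=str),
                "game_id": pd.Series(dtype=str),
                "group": pd.Series(dtype=str),
                "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
                "bet": pd.Series(dtype=float),
                "win": pd.Series(dtype=float),
            }
        )
        return empty, players[["player_id", "age", "gender"]].copy()

    player_idx = np.repeat(np.arange(n_players), n_sessions)
    # one game per session, drawn from the owning player's preferences
    u = rng.random(total_sessions)
    cum = np.cumsum(pref, axis=1)
    game_idx = (u[:, None] > cum[player_idx]).sum(axis=1)
    start_s = rng.uniform(0.0, config.horizon_days * 86400.0, total_sessions)

    if config.effect is not None:
        means_by_spec = np.array([config.effect.session_mean(s) for s in specs])
        session_mean = means_by_spec[game_idx]
    else:
        session_mean = players["wagers_per_session_mean"].to_numpy()[player_idx]
    n_wagers = rng.geometric(1.0 / np.maximum(session_mean, 1.0))

    # generate wagers game-by-game so each game's distributions apply, then
    # reassemble in session order
    total_wagers = int(n_wagers.sum())
    bets = np.empty(total_wagers)
    wins = np.empty(total_wagers)
    incr = np.zeros(total_wagers)  # seconds since previous wager in session
    wager_game = np.repeat(game_idx, n_wagers)
    first_of_session = np.zeros(total_wagers, dtype=bool)
    first_of_session[np.r_[0, np.cumsum(n_wagers)[:-1]]] = True
    for gi, spec in enumerate(specs):
        mask = wager_game == gi
        m = int(mask.sum())
        if m == 0:
            continue
        bets[mask] = _sample_bets(spec, m, rng)
        wins[mask] = _sample_wins(spec, bets[mask], rng)
        gap_mask = mask & ~first_of_session
        incr[gap_mask] = _sample_gaps(spec, int(gap_mask.sum()), rng,
                                      cap=config.gap_seconds)

    offsets = _grouped_cumsum(incr, n_wagers)
    times = np.repeat(start_s, n_wagers) + offsets
    times_us = np.round(times * 1e6).astype("int64")  # microsecond resolution
    origin = pd.Timestamp(config.start, tz="UTC")
    events = pd.DataFrame(
        {
            "player_id": players["player_id"].to_numpy()[np.repeat(player_idx, n_wagers)],
            "game_id": np.array([s.game_id for s in specs])[wager_game],
            "group": np.array([s.group for s in specs])[wager_game],
            "timestamp": origin + pd.to_timedelta(times_us, unit="us"),
            "bet": bets,
            "win": wins,
        }
    )
    events = events.sort_values(
        ["player_id", "timestamp"], kind="mergesort", ignore_index=True
    )
    assert set(events["game_id"]) <= set(spec_by_id)
    return events, players[["player_id", "age", "gender"]].copy()
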