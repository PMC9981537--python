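"""Domain types and calibrated defaults for the simulated casino portfolio.

The portfolio mirrors a typical European online-casino operator: six game
groups (blackjack, live blackjack, live roulette, roulette, slots, video
poker), each described by its structural characteristics — return to player
(RTP), hit frequency (wagers per win), bet-size distribution, win dispersion,
and event frequency (seconds between consecutive wagers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "GAME_GROUPS",
    "GameSpec",
    "PlayerSpec",
    "default_game_specs",
    "default_group_weights",
    "single_zero_roulette_rtp",
    "single_zero_roulette_house_advantage",
]

GAME_GROUPS: tuple[str, ...] = (
    "blackjack",
    "live_blackjack",
    "live_roulette",
    "roulette",
    "slots",
    "video_poker",
)


class ConfigurationError(ValueError):
    """A spec or simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GameSpec:
    """Generative parameters of one game (or game group).

    Parameters
    ----------
    rtp
        Return to player: expected fraction of the amount wagered paid back
        as winnings, in (0, 1].
    hit_frequency
        Aggregate wagers per win, >= 1.  A hit frequency of 3.43 means on
        average one wager in 3.43 produces a strictly positive win.
    avg_bet, sd_bet
        Mean and standard deviation of the per-wager stake (currency units).
    sd_win
        Standard deviation of the win amount across *winning* wagers.
    event_freq_mean, event_freq_sd
        Mean and standard deviation, in seconds, of the time between two
        consecutive wagers within a session.

    The implied per-wager mean win is ``rtp * avg_bet``; the win generator
    honours this identity exactly.
    """

    game_id: str
    group: str
    rtp: float
    hit_frequency: float
    avg_bet: float
    sd_bet: float
    sd_win: float
    event_freq_mean: float
    event_freq_sd: float

    def __post_init__(self) -> None:
        if self.group not in GAME_GROUPS:
            raise ConfigurationError(f"unknown game group {self.group!r}")
        if not 0.0 < self.rtp <= 1.0:
            raise ConfigurationError(f"rtp must be in (0, 1], got {self.rtp}")
        if self.hit_frequency < 1.0:
            raise ConfigurationError(
                f"hit_frequency must be >= 1, got {self.hit_frequency}"
            )
        if self.avg_bet <= 0 or self.event_freq_mean <= 0:
            raise ConfigurationError("avg_bet and event_freq_mean must be > 0")
        if min(self.sd_bet, self.sd_win, self.event_freq_sd) < 0:
            raise ConfigurationError("dispersion parameters must be >= 0")

    @property
    def avg_win(self) -> float:
        """Implied mean win per wager (zeros included): ``rtp * avg_bet``."""
        return self.rtp * self.avg_bet


@dataclass(frozen=True)
class PlayerSpec:
    """One simulated player: demographics and behavioural rates."""

    player_id: str
    age: float
    gender: str
    sessions_per_week: float
    wagers_per_session_mean: float
    preferred_games: Mapping[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] = (18.0, 99.0)

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo <= self.age <= hi:
            raise ConfigurationError(f"age {self.age} outside [{lo}, {hi}]")
        if self.gender not in ("female", "male"):
            raise ConfigurationError(f"gender must be female/male, got {self.gender!r}")
        if self.sessions_per_week <= 0 or self.wagers_per_session_mean <= 0:
            raise ConfigurationError("behavioural rates must be > 0")
        if self.preferred_games:
            total = float(sum(self.preferred_games.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError("preference weights must sum to 1")


# Per-group structural characteristics of the default portfolio, and the
# relative betting volume used for default game-preference weights.
_DEFAULTS: dict[str, dict[str, float]] = {
    "blackjack": dict(
        rtp=0.98, hit_frequency=2.03, avg_bet=14.89, sd_bet=45.98,
        sd_win=68.25, event_freq_mean=15.41, event_freq_sd=70.38,
        n_bets=3_188_493,
    ),
    "live_blackjack": dict(
        rtp=0.97, hit_frequency=2.01, avg_bet=49.83, sd_bet=266.37,
        sd_win=406.26, event_freq_mean=76.55, event_freq_sd=99.22,
        n_bets=3_868_911,
    ),
    "live_roulette": dict(
        rtp=0.97, hit_frequency=2.04, avg_bet=27.83, sd_bet=184.11,
        sd_win=256.73, event_freq_mean=54.22, event_freq_sd=89.73,
        n_bets=19_054_053,
    ),
    "roulette": dict(
        rtp=0.97, hit_frequency=2.21, avg_bet=10.95, sd_bet=46.88,
        sd_win=72.94, event_freq_mean=20.27, event_freq_sd=83.91,
        n_bets=6_058_289,
    ),
    "slots": dict(
        rtp=0.96, hit_frequency=3.43, avg_bet=1.15, sd_bet=6.20,
        sd_win=34.86, event_freq_mean=6.14, event_freq_sd=40.87,
        n_bets=1_071_817_666,
    ),
    "video_poker": dict(
        rtp=0.98, hit_frequency=3.61, avg_bet=5.10, sd_bet=13.74,
        sd_win=38.43, event_freq_mean=10.00, event_freq_sd=50.92,
        n_bets=4_459_817,
    ),
}


def default_game_specs() -> dict[str, GameSpec]:
    """Return the six default game specs keyed by group name.

    One representative game per group, calibrated to the portfolio-level
    structural characteristics above.
    """
    specs = {}
    for group, row in _DEFAULTS.items():
        params = {k: v for k, v in row.items() if k != "n_bets"}
        specs[group] = GameSpec(game_id=f"g_{group}", group=group, **params)
    return specs


def default_group_weights() -> dict[str, float]:
    """Game-preference weights proportional to the default betting volume.

    Slots dominate (≈96.7% of all bets), as is typical for online casinos.
    """
    total = sum(row["n_bets"] for row in _DEFAULTS.values())
    return {group: row["n_bets"] / total for group, row in _DEFAULTS.items()}


def single_zero_roulette_rtp() -> float:
    """RTP of classic single-zero roulette.

    A straight-up bet on one of 37 pockets pays 36x the stake, so the
    expected return is 36/37 ≈ 0.973 regardless of the number chosen.
    """
    return 36.0 / 37.0


def single_zero_roulette_house_advantage() -> float:
    """House advantage of single-zero roulette: 1 − RTP = 1/37 ≈ 2.7%."""
    return 1.0 - single_zero_roulette_rtp()
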