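"""Shared fixtures: seeded RNGs, toy logs, and simulation experiment designs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wagertrack import GameSpec, default_game_specs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def specs():
    return default_game_specs()


def make_events(times_by_player, game="g1", bet=1.0, win=0.0, group="slots"):
    """Event frame from {player: [seconds]} with constant bet/win."""
    rows = []
    origin = pd.Timestamp("2021-01-01", tz="UTC")
    for player, seconds in times_by_player.items():
        for s in seconds:
            rows.append(
                {
                    "player_id": player,
                    "game_id": game,
                    "group": group,
                    "timestamp": origin + pd.Timedelta(seconds=float(s)),
                    "bet": bet,
                    "win": win,
                }
            )
    columns = ["player_id", "game_id", "group", "timestamp", "bet", "win"]
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
    return pd.DataFrame(rows, columns=columns)


def step_portfolio(rng, n_games=24, base_group="slots"):
    """Games whose event frequency spans a gap around 11.79 s while the
    monetary characteristics vary independently.

    Half the games sit below the gap (event_freq_mean in [3, 10]), half
    above ([14, 40]); all other parameters are independent jitters of the
    slots profile, so only event frequency can explain a dependence planted
    at the 11.79 s threshold.
    """
    base = default_game_specs()[base_group]
    specs = []
    for i in range(n_games):
        if i % 2 == 0:
            efm = rng.uniform(3.0, 10.0)
        else:
            efm = rng.uniform(14.0, 40.0)
        j = lambda v: float(v * rng.uniform(0.7, 1.3))
        specs.append(
            GameSpec(
                game_id=f"game_{i:03d}",
                group=base_group,
                rtp=min(1.0 - j(1.0 - base.rtp), 1.0),
                hit_frequency=1.0 + j(base.hit_frequency - 1.0),
                avg_bet=j(base.avg_bet),
                sd_bet=j(base.sd_bet),
                sd_win=j(base.sd_win),
                event_freq_mean=efm,
                event_freq_sd=j(base.event_freq_sd),
            )
        )
    return specs
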