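"""Per-session behavioural metrics, including theoretical loss.

Theoretical loss is the expected monetary loss of a session given only how
much was staked: ``amount_bet * (1 - game RTP)``, where the RTP is the
game-level characteristic, not the session's realized return.  It measures
gambling intensity independently of win/loss luck.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "SessionMetricsExtractor",
    "compute_session_metrics",
    "session_summary",
]

METRIC_COLUMNS = [
    "session_length", "n_bets", "amount_bet", "amount_lost", "n_wins",
    "amount_won", "avg_bet", "avg_win", "max_bet", "max_win", "rtp",
    "hit_frequency", "theoretical_loss", "sd_bet", "sd_win",
]


def compute_session_metrics(
    events: pd.DataFrame,
    game_characteristics: pd.DataFrame,
    players: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row of behavioural metrics per retained single-game session.

    *events* must be sessionized and restricted to single-game sessions.
    Sessions whose game has no characteristics row (it failed the volume
    filter, or is unknown) are dropped, with the count logged and recorded
    in ``result.attrs["n_dropped_no_game"]``.  Sessions with zero wins carry
    a missing hit frequency.

    ``amount_lost = amount_won - amount_bet`` (negative means the player
    lost).  ``avg_win`` is per wager (zeros included); the session-level bet
    and win SDs are population SDs across all wagers of the session.  If a
    player table is given, age / gender / a female indicator are joined on.
    """
    n_games = events.groupby("session_id")["game_id"].nunique()
    if (n_games > 1).any():
        raise ValueError(
            "events contain multi-game sessions; apply "
            "filter_single_game_sessions first"
        )
    g = events.groupby("session_id", sort=True)
    m = pd.DataFrame(
        {
            "player_id": g["player_id"].first(),
            "game_id": g["game_id"].first(),
            "n_bets": g.size(),
            "amount_bet": g["bet"].sum(),
            "amount_won": g["win"].sum(),
            "n_wins": g["win"].agg(lambda s: int((s > 0).sum())),
            "avg_bet": g["bet"].mean(),
            "max_bet": g["bet"].max(),
            "max_win": g["win"].max(),
            "sd_bet": g["bet"].agg(lambda s: float(np.std(s.to_numpy(), ddof=0))),
            "sd_win": g["win"].agg(lambda s: float(np.std(s.to_numpy(), ddof=0))),
            "start": g["timestamp"].min(),
            "end": g["timestamp"].max(),
        }
    )
    m["session_length"] = (m["end"] - m["start"]).dt.total_seconds() / 60.0
    m["amount_lost"] = m["amount_won"] - m["amount_bet"]
    m["avg_win"] = m["amount_won"] / m["n_bets"]
    m["rtp"] = m["amount_won"] / m["amount_bet"]
    m["hit_frequency"] = np.where(m["n_wins"] > 0, m["n_bets"] / m["n_wins"], np.nan)

    game_rtp = game_characteristics.set_index("game_id")["rtp"]
    m["game_rtp"] = m["game_id"].map(game_rtp)
    known = m["game_rtp"].notna()
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info(
            "dropped %d sessions on games without a characteristics row", n_dropped
        )
    m = m[known].copy()
    m["theoretical_loss"] = m["amount_bet"] * (1.0 - m["game_rtp"])

    m = m.reset_index()
    if players is not None:
        m = m.merge(players[["player_id", "age", "gender"]], on="player_id", how="left")
        m["female"] = (m["gender"] == "female").astype(float)
    out = m[
        ["session_id", "player_id", "game_id"]
        + METRIC_COLUMNS
        + (["age", "gender", "female"] if players is not None else [])
    ]
    out.attrs["n_dropped_no_game"] = n_dropped
    return out


def session_summary(metrics: pd.DataFrame) -> pd.Series:
    """Means of the headline session metrics across all retained sessions.

    Hit frequency averages only over sessions where it is defined (at least
    one win); the count of excluded zero-win sessions is reported alongside.
    """
    if len(metrics) == 0:
        raise ValueError("cannot summarise an empty metrics table")
    return pd.Series(
        {
            "n_sessions": float(len(metrics)),
            "session_length": metrics["session_length"].mean(),
            "amount_lost": metrics["amount_lost"].mean(),
            "amount_bet": metrics["amount_bet"].mean(),
            "theoretical_loss": metrics["theoretical_loss"].mean(),
            "n_bets": metrics["n_bets"].mean(),
            "hit_frequency": metrics["hit_frequency"].mean(),
            "n_zero_win_sessions": float(metrics["hit_frequency"].isna().sum()),
        }
    )


class SessionMetricsExtractor(BaseEstimator, TransformerMixin):
    """Transformer computing session metrics from a sessionized, single-game
    event frame.

    Parameters
    ----------
    game_characteristics : DataFrame
        Per-game characteristics table supplying each game's RTP for the
        theoretical-loss computation.
    players : DataFrame, optional
        Player table (player_id, age, gender) to join for modelling.
    """

    def __init__(self, game_characteristics: pd.DataFrame,
                 players: pd.DataFrame | None = None):
        self.game_characteristics = game_characteristics
        self.players = players

    def fit(self, X: pd.DataFrame, y=None) -> "SessionMetricsExtractor":
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return compute_session_metrics(
            X, self.game_characteristics, players=self.players
        )
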