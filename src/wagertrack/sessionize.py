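"""Gap-based sessionization of wager logs.

A session is a maximal run of one player's wagers in which no two
consecutive wagers are separated by more than the inactivity threshold
(default 15 minutes).  A gap of exactly the threshold stays within the
session; only a strictly larger gap starts a new one.  Sessions never span
players.
"""

from __future__ import annotations

import logging

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "SessionAssigner",
    "assign_sessions",
    "filter_single_game_sessions",
    "session_table",
]

DEFAULT_GAP_SECONDS = 900.0


class DataError(ValueError):
    """Input records violate the transaction-log contract."""


def assign_sessions(
    events: pd.DataFrame, gap_seconds: float = DEFAULT_GAP_SECONDS
) -> pd.DataFrame:
    """Label every wager with an integer ``session_id``.

    Events are stably sorted by (player_id, timestamp); rows with equal
    timestamps keep their input order.  A new session starts exactly when
    the gap to the player's previous wager exceeds *gap_seconds*.

    Returns the sorted frame with a ``session_id`` column; the original row
    index is preserved.  Missing or unparseable timestamps raise
    :class:`DataError` naming the offending row indices.
    """
    if len(events) == 0:
        out = events.copy()
        out["session_id"] = pd.Series(dtype="int64")
        return out
    ts = pd.to_datetime(events["timestamp"], utc=True, errors="coerce")
    bad = ts.isna()
    if bad.any():
        rows = list(events.index[bad][:20])
        raise DataError(f"missing/unparseable timestamps at rows {rows}")
    out = events.copy()
    out["timestamp"] = ts
    out = out.sort_values(["player_id", "timestamp"], kind="mergesort")
    gap = out["timestamp"].diff().dt.total_seconds()
    new_session = (out["player_id"] != out["player_id"].shift()) | (gap > gap_seconds)
    out["session_id"] = new_session.cumsum().astype("int64") - 1
    return out


def session_table(events: pd.DataFrame) -> pd.DataFrame:
    """Per-session summary of a sessionized event frame.

    Columns: session_id, player_id, n_events, n_games, game_id (the game
    when the session is single-game, else the first), start, end,
    duration_minutes.
    """
    g = events.groupby("session_id", sort=True)
    tab = pd.DataFrame(
        {
            "player_id": g["player_id"].first(),
            "n_events": g.size(),
            "n_games": g["game_id"].nunique(),
            "game_id": g["game_id"].first(),
            "start": g["timestamp"].min(),
            "end": g["timestamp"].max(),
        }
    )
    tab["duration_minutes"] = (tab["end"] - tab["start"]).dt.total_seconds() / 60.0
    return tab.reset_index()


def filter_single_game_sessions(
    events: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a sessionized log into single-game sessions and a discard log.

    Sessions in which more than one game was played cannot attribute their
    outcomes to one game's structural characteristics, so they are dropped.
    Returns ``(kept_events, discards)`` where *discards* has one row per
    discarded session (session_id, n_games).
    """
    n_games = events.groupby("session_id")["game_id"].nunique()
    multi = n_games[n_games > 1]
    discards = multi.rename("n_games").reset_index()
    kept = events[~events["session_id"].isin(set(multi.index))].copy()
    if len(discards):
        logger.info(
            "discarded %d multi-game sessions (%d events)",
            len(discards), len(events) - len(kept),
        )
    return kept, discards


class SessionAssigner(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`assign_sessions`.

    Parameters
    ----------
    gap_seconds : float, default 900
        Inactivity threshold; a strictly larger gap starts a new session.
    """

    def __init__(self, gap_seconds: float = DEFAULT_GAP_SECONDS):
        self.gap_seconds = gap_seconds

    def fit(self, X: pd.DataFrame, y=None) -> "SessionAssigner":
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return assign_sessions(X, gap_seconds=self.gap_seconds)
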