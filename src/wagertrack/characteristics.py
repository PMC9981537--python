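"""Per-game structural characteristics estimated from a sessionized log.

For every game with enough betting volume, nine characteristics are
computed across all its transactions: average and SD of the bet, average
win per wager, SD of the win across winning wagers, hit frequency
(wagers per win), RTP (total win / total bet), continuity (mean duration in
minutes of the game's single-game sessions), and the mean and SD of the
event frequency (seconds between consecutive within-session wagers on the
game).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .sessionize import filter_single_game_sessions, session_table

logger = logging.getLogger(__name__)

__all__ = [
    "GameCharacteristicsExtractor",
    "compute_game_characteristics",
    "characteristics_report",
]

DEFAULT_MIN_WAGERS = 100_000

CHARACTERISTIC_COLUMNS = [
    "avg_bet", "avg_win", "sd_win", "sd_bet", "hit_frequency", "rtp",
    "continuity", "event_freq_mean", "event_freq_sd",
]


def _pop_sd(x: pd.Series) -> float:
    return float(np.std(x.to_numpy(), ddof=0)) if len(x) else np.nan


def compute_game_characteristics(
    events: pd.DataFrame, min_wagers: int = DEFAULT_MIN_WAGERS
) -> pd.DataFrame:
    """One row of structural characteristics per game passing the volume filter.

    *events* must be sessionized (carry ``session_id``); event frequency and
    continuity need the session structure.  All transactions enter the
    monetary and hit-frequency statistics; continuity uses only the game's
    single-game sessions; event frequency uses only within-session gaps
    between consecutive wagers on the same game, so cross-session idle time
    never inflates it.  SDs are population SDs (denominator n).

    Games with fewer than *min_wagers* transactions are dropped; a game with
    zero wins gets a missing hit frequency with a warning.
    """
    if "session_id" not in events.columns:
        raise ValueError("events must be sessionized (missing session_id column)")
    if len(events) == 0:
        logger.warning("empty event table: no game characteristics")
        return pd.DataFrame(columns=["game_id"] + CHARACTERISTIC_COLUMNS)

    ev = events.sort_values(["session_id", "timestamp"], kind="mergesort")
    g = ev.groupby("game_id", sort=True)
    wins = ev[ev["win"] > 0]
    tab = pd.DataFrame(
        {
            "group": g["group"].first() if "group" in ev.columns else None,
            "n_wagers": g.size(),
            "total_bet": g["bet"].sum(),
            "total_win": g["win"].sum(),
            "n_wins": wins.groupby("game_id").size().reindex(g.size().index, fill_value=0),
            "avg_bet": g["bet"].mean(),
            "sd_bet": g["bet"].agg(_pop_sd),
            "sd_win": wins.groupby("game_id")["win"].agg(_pop_sd),
        }
    )
    tab["avg_win"] = tab["total_win"] / tab["n_wagers"]
    tab["rtp"] = tab["total_win"] / tab["total_bet"]
    tab["hit_frequency"] = np.where(
        tab["n_wins"] > 0, tab["n_wagers"] / tab["n_wins"], np.nan
    )
    if (tab["n_wins"] == 0).any():
        logger.warning(
            "games with zero wins have undefined hit frequency: %s",
            list(tab.index[tab["n_wins"] == 0]),
        )

    # event frequency: within-session consecutive gaps on the same game
    same_session = ev["session_id"] == ev["session_id"].shift()
    same_game = ev["game_id"] == ev["game_id"].shift()
    gaps = ev["timestamp"].diff().dt.total_seconds()[same_session & same_game]
    gap_game = ev["game_id"][same_session & same_game]
    gap_stats = gaps.groupby(gap_game).agg(["mean", _pop_sd])
    tab["event_freq_mean"] = gap_stats["mean"]
    tab["event_freq_sd"] = gap_stats["_pop_sd"]

    # continuity: mean duration (minutes) of the game's single-game sessions
    kept, _ = filter_single_game_sessions(ev)
    if len(kept):
        st = session_table(kept)
        tab["continuity"] = st.groupby("game_id")["duration_minutes"].mean()
    else:
        tab["continuity"] = np.nan

    tab = tab[tab["n_wagers"] >= min_wagers]
    if len(tab) == 0:
        logger.warning("no game reaches the %d-wager volume threshold", min_wagers)
    order = ["group", "n_wagers", "total_bet", "total_win", "n_wins"]
    return tab.reset_index()[["game_id"] + order + CHARACTERISTIC_COLUMNS]


def characteristics_report(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-game characteristics to game-group level.

    Monetary and timing statistics are wager-weighted means of the per-game
    values; hit frequency and RTP are recomputed from the pooled counts and
    totals, so they remain exact ratios at group level.
    """
    if len(table) == 0:
        raise ValueError("cannot report on an empty characteristics table")
    rows = []
    for group, sub in table.groupby("group", sort=True):
        w = sub["n_wagers"].to_numpy(dtype=float)
        w = w / w.sum()
        row = {"group": group, "n_games": len(sub), "n_bets": int(sub["n_wagers"].sum())}
        for col in ["avg_bet", "avg_win", "sd_win", "sd_bet", "continuity",
                    "event_freq_mean", "event_freq_sd"]:
            row[col] = float(np.average(sub[col].to_numpy(dtype=float), weights=w))
        n_wins = sub["n_wins"].sum()
        row["hit_frequency"] = float(sub["n_wagers"].sum() / n_wins) if n_wins else np.nan
        row["rtp"] = float(sub["total_win"].sum() / sub["total_bet"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


class GameCharacteristicsExtractor(BaseEstimator, TransformerMixin):
    """Estimator computing per-game structural characteristics.

    ``fit`` stores the characteristics of the training log in
    ``characteristics_`` (and the group-level aggregate in ``report_``);
    ``transform`` computes the table for any sessionized log.

    Parameters
    ----------
    min_wagers : int, default 100_000
        Minimum transaction count for a game to be characterised.
    """

    def __init__(self, min_wagers: int = DEFAULT_MIN_WAGERS):
        self.min_wagers = min_wagers

    def fit(self, X: pd.DataFrame, y=None) -> "GameCharacteristicsExtractor":
        self.characteristics_ = compute_game_characteristics(
            X, min_wagers=self.min_wagers
        )
        self.report_ = (
            characteristics_report(self.characteristics_)
            if len(self.characteristics_)
            else None
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return compute_game_characteristics(X, min_wagers=self.min_wagers)
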