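"""Modelling layer: OLS with full coefficient reporting and nested-model
F-tests, and a CART regression tree with held-out R², root-split report,
and impurity-based feature importances.

Two outcomes are supported — the number of bets in a session and the
session's theoretical loss — regressed on the nine game-level structural
characteristics, optionally extended by seven session metrics plus age and
a female indicator (18 predictors in total).  Predictors enter on their raw
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "GAME_PREDICTORS",
    "SESSION_PREDICTORS",
    "DEMOGRAPHIC_PREDICTORS",
    "ModelMatrix",
    "RegressionReport",
    "TreeReport",
    "OLSRegression",
    "RegressionTreeModel",
    "build_model_matrix",
    "fit_ols",
    "nested_f_test",
    "fit_regression_tree",
    "feature_importance_ranking",
]

GAME_PREDICTORS = [
    "game_avg_bet", "game_avg_win", "game_sd_win", "game_sd_bet",
    "game_hit_frequency", "game_rtp", "game_continuity",
    "game_event_freq_mean", "game_event_freq_sd",
]
SESSION_PREDICTORS = [
    "session_hit_frequency", "session_max_bet", "session_max_win",
    "session_avg_bet", "session_avg_win", "session_sd_bet", "session_sd_win",
]
DEMOGRAPHIC_PREDICTORS = ["age", "female"]

OUTCOMES = ("n_bets", "theoretical_loss")

_GAME_COLS = {
    "game_avg_bet": "avg_bet", "game_avg_win": "avg_win",
    "game_sd_win": "sd_win", "game_sd_bet": "sd_bet",
    "game_hit_frequency": "hit_frequency", "game_rtp": "rtp",
    "game_continuity": "continuity",
    "game_event_freq_mean": "event_freq_mean",
    "game_event_freq_sd": "event_freq_sd",
}
_SESSION_COLS = {
    "session_hit_frequency": "hit_frequency", "session_max_bet": "max_bet",
    "session_max_win": "max_win", "session_avg_bet": "avg_bet",
    "session_avg_win": "avg_win", "session_sd_bet": "sd_bet",
    "session_sd_win": "sd_win",
}


@dataclass
class ModelMatrix:
    """A complete-case design: outcome vector *y*, predictor frame *X*."""

    outcome: str
    X: pd.DataFrame
    y: pd.Series
    n_dropped: int = 0


def build_model_matrix(
    metrics: pd.DataFrame,
    characteristics: pd.DataFrame,
    outcome: str = "n_bets",
    predictors: str = "characteristics",
) -> ModelMatrix:
    """Assemble the session-level design matrix.

    ``predictors="characteristics"`` uses the nine game-level structural
    characteristics; ``"full"`` adds the seven session metrics, age and the
    female indicator.  Game characteristics are joined on ``game_id``.
    Rows with any missing predictor — chiefly zero-win sessions, whose
    session hit frequency is undefined — are dropped with a logged count.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    if predictors not in ("characteristics", "full"):
        raise ValueError("predictors must be 'characteristics' or 'full'")

    game = characteristics.set_index("game_id")
    df = pd.DataFrame(index=metrics.index)
    for name, col in _GAME_COLS.items():
        df[name] = metrics["game_id"].map(game[col])
    if predictors == "full":
        for name, col in _SESSION_COLS.items():
            df[name] = metrics[col]
        if "age" not in metrics.columns or "female" not in metrics.columns:
            raise ValueError("full predictor set needs age/female joined in metrics")
        df["age"] = metrics["age"]
        df["female"] = metrics["female"]
    y = metrics[outcome].astype(float)
    ok = df.notna().all(axis=1) & y.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d incomplete rows from the model matrix", n_dropped)
    return ModelMatrix(outcome=outcome, X=df[ok].copy(), y=y[ok].copy(),
                       n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# OLS

@dataclass
class RegressionReport:
    """Full OLS output in coefficient-table form.

    ``terms`` has one row per term (intercept first): coef, se, t, p,
    ci_low, ci_high.  ``rss`` and ``df_model`` support nested-model F-tests.
    """

    terms: pd.DataFrame
    r_squared: float
    n: int
    rss: float
    df_model: int
    predictor_names: tuple[str, ...]

    def to_text(self) -> str:
        """Human-readable coefficient table; p-values below 0.001 render as
        '<0.001' (stored values keep full precision)."""
        t = self.terms.copy()
        t["p"] = [f"<0.001" if p < 0.001 else f"{p:.3f}" for p in t["p"]]
        body = t.to_string(float_format=lambda v: f"{v:.4g}")
        return (
            f"{body}\n\nn = {self.n}   R^2 = {self.r_squared:.4f}   "
            f"RSS = {self.rss:.6g}   df_model = {self.df_model}"
        )


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = [names[i] for i in sorted(piv[rank:])]
        raise CollinearityError(f"collinear terms in design matrix: {bad}")


class OLSRegression(RegressorMixin, BaseEstimator):
    """Ordinary least squares with an intercept and classical inference.

    Homoscedastic standard errors, two-sided t p-values, and confidence
    intervals at level ``1 - alpha``.  After ``fit``, ``report_`` holds the
    coefficient table and fit statistics, ``coef_``/``intercept_`` the
    point estimates.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y) -> "OLSRegression":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        names = ["intercept"] + [str(c) for c in X.columns]
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(f"need n > {p + 1} rows, got {n}")
        design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
        _check_full_rank(design, names)
        res = sm.OLS(y, design).fit()
        ci = res.conf_int(alpha=self.alpha)
        self.results_ = res
        self.report_ = RegressionReport(
            terms=pd.DataFrame(
                {
                    "coef": res.params,
                    "se": res.bse,
                    "t": res.tvalues,
                    "p": res.pvalues,
                    "ci_low": ci[:, 0],
                    "ci_high": ci[:, 1],
                },
                index=names,
            ),
            r_squared=float(res.rsquared),
            n=n,
            rss=float(res.ssr),
            df_model=p,
            predictor_names=tuple(names[1:]),
        )
        self.intercept_ = float(res.params[0])
        self.coef_ = res.params[1:].copy()
        self.n_features_in_ = p
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X).to_numpy(dtype=float)
        return self.intercept_ + X @ self.coef_


def fit_ols(matrix: ModelMatrix | None = None, X: pd.DataFrame | None = None,
            y=None) -> RegressionReport:
    """Fit OLS on a :class:`ModelMatrix` (or explicit X, y) and return the
    report."""
    if matrix is not None:
        X, y = matrix.X, matrix.y
    return OLSRegression().fit(X, y).report_


def nested_f_test(small: RegressionReport, full: RegressionReport
                  ) -> tuple[float, float]:
    """F-test comparing a smaller OLS model against one that strictly
    contains its predictors, fitted on the same rows.

    F = ((RSS_small − RSS_full)/Δdf) / (RSS_full/(n − df_full − 1)), with the
    p-value from F(Δdf, n − df_full − 1).
    """
    if small.n != full.n:
        raise ValueError(f"models fit on different n ({small.n} vs {full.n})")
    s, f = set(small.predictor_names), set(full.predictor_names)
    if not s < f:
        raise ValueError("small model's predictors must be a strict subset "
                         "of the full model's")
    delta_df = full.df_model - small.df_model
    df_resid = full.n - full.df_model - 1
    F = ((small.rss - full.rss) / delta_df) / (full.rss / df_resid)
    p = float(stats.f.sf(F, delta_df, df_resid))
    return float(F), p


# ---------------------------------------------------------------------------
# regression tree

@dataclass
class TreeReport:
    """Held-out evaluation and structure summary of a fitted CART tree."""

    test_r_squared: float
    importances: pd.Series
    root_split: tuple[str, float] | None
    child_means: dict[str, float] | None
    seed: int
    hyperparameters: dict = field(default_factory=dict)


class RegressionTreeModel(RegressorMixin, BaseEstimator):
    """CART regression tree with an internal train/test split.

    Variance-reduction splitting on a uniformly random ``train_fraction``
    of the rows; ``report_`` carries the R² on the held-out rows, the
    normalized impurity-based feature importances, the root split and the
    mean outcome in each root branch.

    Parameters
    ----------
    train_fraction : float, default 0.8
        Share of rows used for growing the tree.
    max_depth : int, default 4
        Maximum tree depth; shallow trees keep the root split interpretable.
    min_samples_leaf_frac : float, default 0.01
        Minimum leaf size as a fraction of the training rows.
    random_state : int, default 0
        Controls the split assignment (the tree itself is deterministic
        given the training rows).
    """

    def __init__(self, train_fraction: float = 0.8, max_depth: int = 4,
                 min_samples_leaf_frac: float = 0.01, random_state: int = 0):
        self.train_fraction = train_fraction
        self.max_depth = max_depth
        self.min_samples_leaf_frac = min_samples_leaf_frac
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "RegressionTreeModel":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        n = len(X)
        if n < 100:
            raise ValueError(f"need at least 100 rows to split train/test, got {n}")
        if np.var(y) == 0:
            raise ValueError("outcome has zero variance")
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=self.train_fraction, random_state=self.random_state
        )
        min_leaf = max(1, int(round(self.min_samples_leaf_frac * len(X_tr))))
        tree = DecisionTreeRegressor(
            max_depth=self.max_depth, min_samples_leaf=min_leaf,
            random_state=self.random_state,
        ).fit(X_tr, y_tr)
        names = [str(c) for c in X.columns]
        t = tree.tree_
        if t.node_count > 1:
            feat = names[t.feature[0]]
            root_split = (feat, float(t.threshold[0]))
            child_means = {
                "low": float(t.value[t.children_left[0]].ravel()[0]),
                "high": float(t.value[t.children_right[0]].ravel()[0]),
            }
        else:
            root_split, child_means = None, None
        self.tree_ = tree
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.report_ = TreeReport(
            test_r_squared=float(tree.score(X_te, y_te)),
            importances=pd.Series(tree.feature_importances_, index=names),
            root_split=root_split,
            child_means=child_means,
            seed=self.random_state,
            hyperparameters={
                "train_fraction": self.train_fraction,
                "max_depth": self.max_depth,
                "min_samples_leaf": min_leaf,
            },
        )
        return self

    def predict(self, X) -> np.ndarray:
        return self.tree_.predict(pd.DataFrame(X))


def fit_regression_tree(
    matrix: ModelMatrix | None = None,
    X: pd.DataFrame | None = None,
    y=None,
    train_fraction: float = 0.8,
    seed: int = 0,
    max_depth: int = 4,
    min_samples_leaf_frac: float = 0.01,
) -> TreeReport:
    """Fit the CART tree on a :class:`ModelMatrix` (or explicit X, y) and
    return its report."""
    if matrix is not None:
        X, y = matrix.X, matrix.y
    model = RegressionTreeModel(
        train_fraction=train_fraction, max_depth=max_depth,
        min_samples_leaf_frac=min_samples_leaf_frac, random_state=seed,
    )
    return model.fit(X, y).report_


def feature_importance_ranking(report: TreeReport) -> list[tuple[str, float]]:
    """Features by descending importance weight; ties break alphabetically."""
    items = sorted(report.importances.items(), key=lambda kv: (-kv[1], kv[0]))
    ties = len(report.importances) - len(set(report.importances.round(12)))
    if ties:
        logger.info("importance ties broken alphabetically")
    return [(name, float(w)) for name, w in items]
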