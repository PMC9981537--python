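"""End-to-end orchestration: simulate → sessionize → characterize →
session metrics → model, with a reconciled run manifest.

The pipeline is driven by a single (YAML-loadable) configuration and is
bit-for-bit reproducible from (config, seed).  Every exclusion — multi-game
sessions, low-volume games, incomplete model rows — is counted in the
manifest, because those exclusions are analytically meaningful.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import io as wio
from .characteristics import characteristics_report, compute_game_characteristics
from .metrics import compute_session_metrics, session_summary
from .models import (
    build_model_matrix,
    feature_importance_ranking,
    fit_ols,
    fit_regression_tree,
)
from .sessionize import assign_sessions, filter_single_game_sessions
from .simulate import DemographicsConfig, EffectSpec, SimConfig, simulate_population
from .specs import ConfigurationError, GameSpec, default_game_specs

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_players: int = 200
    min_wagers: int = 100_000
    gap_seconds: float = 900.0
    simulation: SimConfig = field(default_factory=SimConfig)
    model: dict = field(default_factory=lambda: {
        "outcome": "n_bets", "predictors": "characteristics", "type": "ols",
        "train_fraction": 0.8, "max_depth": 4, "min_samples_leaf_frac": 0.01,
    })

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _build_sim_config(raw: Mapping[str, Any]) -> SimConfig:
    raw = dict(raw)
    demo = raw.pop("demographics", None)
    effect = raw.pop("effect", None)
    kwargs: dict[str, Any] = dict(raw)
    if demo is not None:
        if "age_range" in demo:
            demo["age_range"] = tuple(demo["age_range"])
        kwargs["demographics"] = DemographicsConfig(**demo)
    if effect is not None:
        kwargs["effect"] = EffectSpec(**effect)
    try:
        return SimConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad simulation config: {exc}") from exc


def load_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a dict, YAML string, or path."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        raw = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = dict(source)
    raw = dict(raw or {})
    sim_raw = raw.pop("simulation", {}) or {}
    model = raw.pop("model", None)
    cfg = PipelineConfig(**raw)
    cfg.simulation = _build_sim_config(sim_raw)
    if model:
        cfg.model.update(model)
    return cfg


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    counts: dict
    outputs: dict
    summary: dict
    created: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config, outdir, specs: list[GameSpec] | None = None) -> RunManifest:
    """Execute all stages and write every artifact under *outdir*.

    Stage counts are reconciled as they accumulate: events in equals the sum
    of per-session sizes before filtering, and model rows equal retained
    sessions minus logged exclusions.  Raises with the stage name on any
    stage failure.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: dict[str, str] = {}

    def _write(df, name):
        path = outdir / name
        wio.write_table(df, path)
        outputs[name.split(".")[0]] = str(path)

    stage = "simulate"
    try:
        events, players = simulate_population(
            cfg.n_players, specs=specs, config=cfg.simulation, seed=cfg.seed
        )
        counts["players"] = len(players)
        counts["events"] = len(events)
        _write(events, "transactions.csv")
        _write(players, "players.csv")

        stage = "sessionize"
        sessionized = assign_sessions(events, gap_seconds=cfg.gap_seconds)
        counts["sessions"] = int(sessionized["session_id"].nunique())
        kept, discards = filter_single_game_sessions(sessionized)
        counts["multi_game_sessions_discarded"] = len(discards)
        counts["events_retained"] = len(kept)
        _write(sessionized, "sessions.csv")
        _write(discards, "discarded_sessions.csv")
        assert counts["sessions"] == (
            kept["session_id"].nunique() + len(discards)
        ), "session partition does not reconcile"

        stage = "game_characteristics"
        chars = compute_game_characteristics(sessionized, min_wagers=cfg.min_wagers)
        counts["games_retained"] = len(chars)
        _write(chars, "game_characteristics.csv")
        if len(chars):
            _write(characteristics_report(chars), "group_report.csv")

        stage = "session_metrics"
        metrics = compute_session_metrics(kept, chars, players=players)
        counts["metric_sessions"] = len(metrics)
        counts["sessions_dropped_no_game"] = metrics.attrs["n_dropped_no_game"]
        assert counts["metric_sessions"] + counts["sessions_dropped_no_game"] == (
            kept["session_id"].nunique()
        ), "session metric counts do not reconcile"
        _write(metrics, "session_metrics.csv")
        summary = session_summary(metrics).to_dict() if len(metrics) else {}

        stage = "model"
        model_cfg = dict(cfg.model)
        matrix = build_model_matrix(
            metrics, chars,
            outcome=model_cfg.get("outcome", "n_bets"),
            predictors=model_cfg.get("predictors", "characteristics"),
        )
        counts["model_rows"] = len(matrix.X)
        counts["model_rows_dropped"] = matrix.n_dropped
        assert counts["model_rows"] + counts["model_rows_dropped"] == counts[
            "metric_sessions"
        ], "model matrix counts do not reconcile"
        kind = model_cfg.get("type", "ols")
        if kind == "ols":
            report = fit_ols(matrix)
            (outdir / "ols_report.txt").write_text(report.to_text() + "\n")
            _write(report.terms.reset_index(names="term"), "ols_coefficients.csv")
            summary["model_r_squared"] = report.r_squared
        elif kind == "tree":
            report = fit_regression_tree(
                matrix,
                train_fraction=model_cfg.get("train_fraction", 0.8),
                seed=cfg.seed,
                max_depth=model_cfg.get("max_depth", 4),
                min_samples_leaf_frac=model_cfg.get("min_samples_leaf_frac", 0.01),
            )
            ranking = feature_importance_ranking(report)
            lines = [
                f"test R^2 = {report.test_r_squared:.4f}",
                f"root split: {report.root_split}",
                f"root branch means: {report.child_means}",
                "feature importances:",
            ] + [f"  {name}: {w:.4f}" for name, w in ranking]
            (outdir / "tree_report.txt").write_text("\n".join(lines) + "\n")
            summary["model_test_r_squared"] = report.test_r_squared
        else:
            raise ConfigurationError(f"unknown model type {kind!r}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seed=cfg.seed,
        counts=counts,
        outputs=outputs,
        summary={k: float(v) for k, v in summary.items()},
        created=datetime.now(timezone.utc).isoformat(),
    )
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    logger.info("pipeline complete: %s", counts)
    return manifest
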