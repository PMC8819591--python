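"""End-to-end orchestration: extract → rank → select → minimize → evaluate → interpret.

One integer seed governs every stochastic stage (fold shuffles, forest
bootstraps); per-stage seeds are derived deterministically from it so a
run is reproducible from (inputs, seed) alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import CVReport, cross_validate, cv_accuracy_evaluator
from .features import FeatureMatrix, extract_feature_matrix, parse_feature_name
from .io_seq import ProteinRecord
from .mrmd import MRMDRanking, SelectionResult, mrmd_rank, select_subset
from .motif import motif_feature_contribution
from .raac import ReductionScheme, default_scheme
from .reduce_dim import EliminationResult, backward_eliminate
from .rule2d import ThresholdRule, fit_rule, scatter_table
from .synthetic import DEFAULT_MOTIF

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters of a full pipeline run."""

    scheme: Optional[ReductionScheme] = None
    gaps: Sequence[int] = (0, 1, 2)
    maxlag: int = 2
    metric: str = "euclidean"
    weights: tuple[float, float] = (1.0, 1.0)
    k_max: int = 30
    select_tolerance: float = 0.005
    min_features: int = 2
    eliminate_tolerance: float = float("inf")
    model: str = "tree"
    folds: int = 10
    min_leaf: int = 2
    seed: int = 7

    def __post_init__(self) -> None:
        if self.scheme is None:
            self.scheme = default_scheme()


@dataclass
class PipelineResult:
    """All artifacts of one end-to-end run."""

    matrix: FeatureMatrix
    ranking: MRMDRanking
    selection: SelectionResult
    elimination: EliminationResult
    report: CVReport
    scatter: pd.DataFrame
    rule: Optional[ThresholdRule]
    config: PipelineConfig

    @property
    def final_features(self) -> list[str]:
        return self.elimination.features


def _stage_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(
    records: Sequence[ProteinRecord],
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run the full identification pipeline on labeled records.

    Stages: reduced-alphabet + ACC feature extraction, MRMD ranking,
    prefix subset selection under cross-validated accuracy, greedy
    backward elimination to a minimal feature set, final k-fold
    evaluation, and the two-feature count-scatter interpretation.

    When ``out_dir`` is given, writes features.tsv, ranking.tsv,
    selection.tsv, trajectory.tsv, cv_report.tsv and scatter.tsv there.
    """
    cfg = config if config is not None else PipelineConfig()
    seed_select, seed_eliminate, seed_final = _stage_seeds(cfg.seed, 3)

    logger.info("extracting features (seed=%d)", cfg.seed)
    matrix = extract_feature_matrix(
        records, scheme=cfg.scheme, gaps=cfg.gaps, maxlag=cfg.maxlag
    )
    if matrix.labels is None:
        raise ValueError("pipeline requires labeled records")

    logger.info("ranking %d features with MRMD", matrix.n_features)
    ranking = mrmd_rank(matrix, weights=cfg.weights, metric=cfg.metric)

    k_max = min(cfg.k_max, matrix.n_features)
    evaluator = cv_accuracy_evaluator(
        model=cfg.model, k=cfg.folds, seed=seed_select, min_leaf=cfg.min_leaf
    )
    logger.info("selecting a ranking prefix (k_max=%d)", k_max)
    selection = select_subset(
        matrix, ranking, evaluator, k_max=k_max, tolerance=cfg.select_tolerance
    )

    logger.info("eliminating down to %d features", cfg.min_features)
    scores = dict(zip(ranking.table["feature"], ranking.table["score"]))
    evaluator_elim = cv_accuracy_evaluator(
        model=cfg.model, k=cfg.folds, seed=seed_eliminate, min_leaf=cfg.min_leaf
    )
    # if selection picked fewer than min_features, pad from the ranking so
    # elimination always starts at or above the requested floor
    start = selection.features
    if len(start) < cfg.min_features:
        start = ranking.ordered_features[: cfg.min_features]
    elimination = backward_eliminate(
        matrix.subset(start),
        evaluator_elim,
        min_features=cfg.min_features,
        tolerance=cfg.eliminate_tolerance,
        scores=scores,
    )

    logger.info("final evaluation on %s", elimination.features)
    report = cross_validate(
        matrix.subset(elimination.features),
        model=cfg.model,
        k=cfg.folds,
        seed=seed_final,
        min_leaf=cfg.min_leaf,
    )

    scatter, rule = _interpret(records, cfg, elimination.features)

    result = PipelineResult(
        matrix=matrix,
        ranking=ranking,
        selection=selection,
        elimination=elimination,
        report=report,
        scatter=scatter,
        rule=rule,
        config=cfg,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _interpret(
    records: Sequence[ProteinRecord],
    cfg: PipelineConfig,
    features: Sequence[str],
) -> tuple[pd.DataFrame, Optional[ThresholdRule]]:
    """Count-scatter + threshold rule when the final pair is two dipeptides."""
    dipeptides = []
    for f in features:
        try:
            dipeptides.append(parse_feature_name(f))
        except ValueError:
            pass
    if len(dipeptides) != 2:
        return pd.DataFrame(columns=["id", "x", "y", "label"]), None
    fx, fy = dipeptides
    table = scatter_table(records, cfg.scheme, fx, fy)
    rule, _ = fit_rule(table, feature_x=fx.name, feature_y=fy.name)
    return table, rule


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.matrix.to_tsv(out_dir / "features.tsv")
    result.ranking.to_tsv(out_dir / "ranking.tsv")
    result.selection.trajectory.to_csv(out_dir / "selection.tsv", sep="\t", index=False)
    result.elimination.trajectory.to_csv(out_dir / "trajectory.tsv", sep="\t", index=False)
    rep = result.report
    rows = [
        {"fold": i + 1, "TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN}
        for i, c in enumerate(rep.folds)
    ]
    rows.append({"fold": "pooled", "TP": rep.pooled.TP, "TN": rep.pooled.TN,
                 "FP": rep.pooled.FP, "FN": rep.pooled.FN})
    pd.DataFrame(rows).to_csv(out_dir / "cv_report.tsv", sep="\t", index=False)
    result.scatter.to_csv(out_dir / "scatter.tsv", sep="\t", index=False)
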