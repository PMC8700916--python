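"""Filter-wrapper cross-validation, ablation experiments and reporting.

The wrapper stage picks the retained-feature count N from a grid
(20, 30, ..., 500 by default) by cross-validated AUC: within each training
split the features are re-discretized and re-ranked by mRMR, the first N
features feed the MKL classifier, and held-out samples are scored.  Nested
cross-validation runs that wrapper inside every outer-training set so the
reported AUC never sees the data used to pick N.  The experiment suite
repeats the evaluation per single block and per leave-one-block-out subset
with identical fold assignments, so multi- vs single-omics comparisons are
paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset import FeatureRef, MultiOmicsDataset
from .mkl import OmicsMKL
from .mrmr import RankedFeatureList

logger = logging.getLogger(__name__)

DEFAULT_N_GRID = tuple(range(20, 501, 10))


@dataclass
class CVConfig:
    outer_folds: int = 10
    inner_folds: int = 10
    n_grid: tuple[int, ...] = DEFAULT_N_GRID
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        grid = tuple(self.n_grid)
        if not grid or any(b <= a for a, b in zip(grid, grid[1:])) or grid[0] < 1:
            raise ValueError("n_grid must be strictly increasing with min >= 1")
        self.n_grid = grid


@dataclass
class FoldResult:
    chosen_n: int
    auc: float
    test_indices: np.ndarray
    scores: np.ndarray


@dataclass
class EvaluationReport:
    """Per-fold and aggregate performance for one experiment.

    ``aggregate_auc`` is the mean of per-fold AUCs; ``pooled_auc`` pools all
    held-out scores into one ranking first.  ``roc_points`` are (FPR, TPR)
    pairs of the pooled ROC curve.
    """

    experiment: str
    folds: list[FoldResult]
    aggregate_auc: float
    pooled_auc: float
    roc_points: np.ndarray
    config: CVConfig | None = None

    @property
    def fold_aucs(self) -> list[float]:
        return [f.auc for f in self.folds]

    @property
    def chosen_n(self) -> list[int]:
        return [f.chosen_n for f in self.folds]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC (Mann-Whitney: P(score+ > score-) + half the tie probability)
    and the ROC points as an (n, 2) array of (FPR, TPR)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to compute an AUC")
    auc = float(roc_auc_score(y == 1, scores))
    fpr, tpr, _ = roc_curve(y == 1, scores)
    return auc, np.column_stack([fpr, tpr])


def make_folds(
    labels: np.ndarray, n_folds: int, stratified: bool, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (train, test) index pairs; stratified folds keep the
    class ratio within one sample of the global ratio."""
    y = np.asarray(labels)
    cls = StratifiedKFold if stratified else KFold
    kf = cls(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    X_dummy = np.zeros((len(y), 1))
    folds = [(tr, te) for tr, te in kf.split(X_dummy, y)]
    if not stratified:
        for _, te in folds:
            if len(np.unique(y[te])) < 2:
                raise ValueError(
                    "a fold lost a class; enable stratified folds"
                )
    return folds


def _truncate_grid(grid: Sequence[int], total_features: int) -> list[int]:
    kept = [n for n in grid if n <= total_features]
    if len(kept) < len(grid):
        logger.warning(
            "N grid truncated at %d (dataset has %d features)",
            kept[-1] if kept else 0, total_features,
        )
    if not kept:
        kept = [total_features]
    return kept


def wrapper_select_n(
    train: MultiOmicsDataset,
    cfg: CVConfig,
    **model_kwargs,
) -> tuple[int, list[tuple[int, float]]]:
    """Pick the retained-feature count N by inner cross-validated AUC.

    Each inner split re-runs discretization and mRMR on its own training
    part (no leakage), evaluates every N in the grid on one shared ranking,
    and the mean AUC across inner folds is maximised; ties go to the
    smallest N.
    """
    total = sum(b.n_features for b in train.blocks)
    grid = _truncate_grid(cfg.n_grid, total)
    cap = max(grid)
    folds = make_folds(train.labels, cfg.inner_folds, cfg.stratified, cfg.seed)
    aucs = np.zeros((len(folds), len(grid)))
    for i, (tr, va) in enumerate(folds):
        tr_ds, va_ds = train.take(tr), train.take(va)
        ranked = OmicsMKL(tr_ds, cap=cap, **model_kwargs).rank_features()
        for j, n in enumerate(grid):
            res = OmicsMKL(tr_ds, n, cap=cap, ranked=ranked, **model_kwargs).fit()
            scores = res.decision_function(va_ds)
            aucs[i, j], _ = roc_auc(scores, va_ds.labels)
    mean_auc = aucs.mean(axis=0)
    best = int(np.argmax(mean_auc))  # argmax takes the first (smallest N) on ties
    return grid[best], list(zip(grid, mean_auc.tolist()))


def nested_cv_evaluate(
    ds: MultiOmicsDataset,
    cfg: CVConfig,
    block_subset: Sequence[str] | None = None,
    experiment: str | None = None,
    outer_folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
    **model_kwargs,
) -> EvaluationReport:
    """Nested cross-validation: the wrapper picks N inside each outer
    training set, the refit model is scored on the held-out fold.

    ``outer_folds`` may be supplied to share fold assignments across
    experiments (paired comparisons); otherwise they derive from
    ``cfg.seed``.
    """
    if block_subset is not None:
        ds = ds.select_blocks(block_subset)
    if outer_folds is None:
        outer_folds = make_folds(ds.labels, cfg.outer_folds, cfg.stratified, cfg.seed)
    fold_results: list[FoldResult] = []
    for k, (tr, te) in enumerate(outer_folds):
        tr_ds, te_ds = ds.take(tr), ds.take(te)
        inner_cfg = replace(cfg, seed=(cfg.seed * 1000003 + k + 1) % (2**31))
        best_n, _curve = wrapper_select_n(tr_ds, inner_cfg, **model_kwargs)
        cap = max(_truncate_grid(cfg.n_grid, sum(b.n_features for b in tr_ds.blocks)))
        res = OmicsMKL(tr_ds, best_n, cap=cap, **model_kwargs).fit()
        scores = res.decision_function(te_ds)
        auc, _ = roc_auc(scores, te_ds.labels)
        fold_results.append(FoldResult(best_n, auc, np.asarray(te), scores))
    all_scores = np.concatenate([f.scores for f in fold_results])
    all_labels = np.concatenate([ds.labels[f.test_indices] for f in fold_results])
    pooled, points = roc_auc(all_scores, all_labels)
    return EvaluationReport(
        experiment=experiment or ("all-blocks" if block_subset is None else "subset"),
        folds=fold_results,
        aggregate_auc=float(np.mean([f.auc for f in fold_results])),
        pooled_auc=pooled,
        roc_points=points,
        config=cfg,
    )


def run_experiment_suite(
    ds: MultiOmicsDataset, cfg: CVConfig, **model_kwargs
) -> list[EvaluationReport]:
    """All-blocks run, one run per single block, one per dropped block —
    1 + B + B reports for B blocks, all with identical outer folds."""
    if len(ds.blocks) < 2:
        raise ValueError("experiment suite needs at least 2 blocks")
    folds = make_folds(ds.labels, cfg.outer_folds, cfg.stratified, cfg.seed)
    reports = [
        nested_cv_evaluate(
            ds, cfg, experiment="all-blocks", outer_folds=folds, **model_kwargs
        )
    ]
    for name in ds.block_names:
        reports.append(
            nested_cv_evaluate(
                ds, cfg, block_subset=[name], experiment=f"single:{name}",
                outer_folds=folds, **model_kwargs,
            )
        )
    for name in ds.block_names:
        keep = [n for n in ds.block_names if n != name]
        reports.append(
            nested_cv_evaluate(
                ds, cfg, block_subset=keep, experiment=f"drop:{name}",
                outer_folds=folds, **model_kwargs,
            )
        )
    return reports


def final_feature_set(
    ds: MultiOmicsDataset, cfg: CVConfig, **model_kwargs
) -> tuple[RankedFeatureList, int, list[tuple[int, float]]]:
    """Single feature set for interpretation: non-nested CV picks N*, then
    one mRMR run on the whole dataset is truncated to its first N* entries."""
    best_n, curve = wrapper_select_n(ds, cfg, **model_kwargs)
    total = sum(b.n_features for b in ds.blocks)
    cap = max(_truncate_grid(cfg.n_grid, total))
    ranked = OmicsMKL(ds, cap=cap, **model_kwargs).rank_features()
    return ranked.head(best_n), best_n, curve


def _round_half_up(x: float, places: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


def composition_summary(
    selected: RankedFeatureList | Mapping[str, int],
    block_names: Sequence[str],
    annotated: Sequence[FeatureRef] | None = None,
) -> dict:
    """Per-block counts and percentages (half-up, 2 decimals) of a selected
    feature list; optionally the share of an annotated subset.

    ``selected`` may be a ranked list or a precomputed block -> count map.
    """
    if isinstance(selected, RankedFeatureList):
        counts = {name: 0 for name in block_names}
        for e in selected:
            counts[e.ref.block_name] = counts.get(e.ref.block_name, 0) + 1
        total = len(selected)
    else:
        counts = {name: int(selected.get(name, 0)) for name in block_names}
        total = sum(counts.values())
    if total == 0:
        percentages = {name: 0.0 for name in block_names}
    else:
        percentages = {
            name: _round_half_up(100.0 * c / total) for name, c in counts.items()
        }
    out = {"counts": counts, "percentages": percentages, "total": total}
    if annotated is not None:
        n_annot = len(annotated)
        out["annotated_count"] = n_annot
        out["annotated_percentage"] = (
            _round_half_up(100.0 * n_annot / total) if total else 0.0
        )
    return out
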