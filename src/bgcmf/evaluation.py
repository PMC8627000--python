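"""ROC/AUC computation, repeated five-fold cross-validation, grid search.

Cross-validation partitions the known (1) entries of the association matrix
into folds, zeroes each test fold in the training matrix, and re-runs the
whole pipeline on the training matrix — GIP kernels and WKNKN included, so
no information about the held-out positives leaks through the interaction
profiles. Test positives are then ranked against every pair that is 0 in
the ORIGINAL matrix; training positives are excluded from scoring.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .data_io import AssociationMatrix, SimilarityMatrix
from .errors import ParameterError
from .pipeline import PipelineConfig, bgcmf_predict

__all__ = ["CvResult", "roc_auc", "five_fold_cv", "grid_search"]


@dataclass(frozen=True)
class CvResult:
    """Fold-level AUCs of a repeated cross-validation run."""

    fold_aucs: tuple[float, ...]
    mean_auc: float
    std_auc: float
    n_repeats: int
    seed: int

    @classmethod
    def from_fold_aucs(cls, fold_aucs, n_repeats: int, seed: int) -> "CvResult":
        arr = np.asarray(fold_aucs, dtype=float)
        return cls(tuple(arr), float(arr.mean()), float(arr.std()), n_repeats, seed)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney statistic.

    Ties count 1/2: the result equals P(score_pos > score_neg) +
    0.5 * P(score_pos = score_neg) over random positive/negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def five_fold_cv(
    Y: AssociationMatrix,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    config: PipelineConfig = PipelineConfig(),
    n_repeats: int = 10,
    seed: int = 0,
    n_folds: int = 5,
    predict_fn=None,
) -> CvResult:
    """Repeated k-fold cross-validation over the known associations.

    ``predict_fn(train_Y, Sm, Sd, config) -> PredictionMatrix`` defaults to
    the full pipeline; it can be swapped out to audit the harness itself.
    """
    if predict_fn is None:
        predict_fn = bgcmf_predict
    positives = np.argwhere(Y.values == 1)
    if len(positives) < n_folds:
        raise ParameterError(f"need at least {n_folds} known associations, got {len(positives)}")
    neg_mask = Y.values == 0
    rng = np.random.default_rng(seed)
    fold_aucs: list[float] = []
    for _ in range(n_repeats):
        order = rng.permutation(len(positives))
        for fold_idx in np.array_split(order, n_folds):
            if fold_idx.size == 0:
                warnings.warn("fold with zero test positives skipped")
                continue
            test_pos = positives[fold_idx]
            train = Y.values.copy()
            train[test_pos[:, 0], test_pos[:, 1]] = 0.0
            train_Y = AssociationMatrix(train, Y.row_labels, Y.col_labels)
            scores = predict_fn(train_Y, Sm, Sd, config).values
            eval_mask = neg_mask.copy()
            eval_mask[test_pos[:, 0], test_pos[:, 1]] = True
            labels = np.zeros(Y.values.shape, dtype=int)
            labels[test_pos[:, 0], test_pos[:, 1]] = 1
            fold_aucs.append(roc_auc(scores[eval_mask], labels[eval_mask]))
    return CvResult.from_fold_aucs(fold_aucs, n_repeats, seed)


def grid_search(
    Y: AssociationMatrix,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    base_config: PipelineConfig,
    grid: dict[str, list[float]],
    n_repeats: int = 1,
    seed: int = 0,
) -> tuple[PipelineConfig, list[dict]]:
    """Exhaustive search over regularization weights by CV mean AUC.

    ``grid`` maps parameter names to candidate lists. ``lambda_dt`` couples
    lambda_d and lambda_t to a shared value; ``lambda_l``, ``lambda_d`` and
    ``lambda_t`` are searched independently when given. Ties keep the first
    grid point in iteration order.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ParameterError("grid must be non-empty")
    allowed = {"lambda_l", "lambda_d", "lambda_t", "lambda_dt"}
    unknown = set(grid) - allowed
    if unknown:
        raise ParameterError(f"unknown grid parameter(s): {sorted(unknown)}")
    names = list(grid)
    table: list[dict] = []
    best: tuple[float, PipelineConfig] | None = None
    for combo in itertools.product(*(grid[n] for n in names)):
        updates = dict(zip(names, combo))
        if "lambda_dt" in updates:
            shared = updates.pop("lambda_dt")
            updates["lambda_d"] = shared
            updates["lambda_t"] = shared
        cfg = replace(base_config, cmf=replace(base_config.cmf, **updates))
        res = five_fold_cv(Y, Sm, Sd, cfg, n_repeats=n_repeats, seed=seed)
        row = dict(zip(names, combo))
        row.update(mean_auc=res.mean_auc, std_auc=res.std_auc)
        table.append(row)
        if best is None or res.mean_auc > best[0]:
            best = (res.mean_auc, cfg)
    return best[1], table
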