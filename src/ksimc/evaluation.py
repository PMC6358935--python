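"""Evaluation protocols: ten-fold cross-validation, de-novo test, ROC/AUC.

Both protocols hold out known positives, rerun the whole pipeline —
similarity adjustment included — on the reduced training network, and ask
how highly the held-out pairs score among pairs never observed as positive
(the standard unlabelled-as-negative convention for link prediction).
Recomputing the adjustment inside each fold matters: adjusting the full
network first would let held-out edges leak into training through the
similarity-propagated 1s.

ROC curves are built by sweeping a score threshold: at each cutoff
TPR = TP/(TP+FN) and FPR = FP/(FP+TN); equal scores are grouped at a single
threshold and AUC is the trapezoidal integral, which equals the
tie-corrected Mann-Whitney statistic U/(n_pos*n_neg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .completion import SVTParams, svt_complete
from .io_formats import InteractionList, ProteinRecord, RunConfig
from .network import adjust_interactions, assemble_hetero, build_interaction_matrix
from .similarity import AlignmentParams, SimilarityMatrix, build_similarity_matrix

__all__ = [
    "FoldAssignment",
    "ROCResult",
    "CVResult",
    "ten_fold_split",
    "roc_points",
    "cross_validate",
    "de_novo_test",
]

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of the known positives into folds (sizes differ by <= 1)."""

    fold_of_pair: dict[Pair, int]
    n_folds: int
    seed: int

    def fold(self, label: int) -> frozenset[Pair]:
        return frozenset(p for p, f in self.fold_of_pair.items() if f == label)

    def folds(self) -> list[frozenset[Pair]]:
        return [self.fold(i) for i in range(1, self.n_folds + 1)]


@dataclass(frozen=True)
class ROCResult:
    """One ROC curve: descending thresholds, the (FPR, TPR) path and its AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def ten_fold_split(positives: Sequence[Pair] | frozenset[Pair], seed: int, n_folds: int = 10) -> FoldAssignment:
    """Uniform random partition of the positive pairs into ``n_folds`` folds.

    Deterministic for a fixed seed. Pairs are sorted before shuffling so the
    assignment depends only on the pair set and the seed, not on input order.
    """
    pairs = sorted(set(positives))
    if len(pairs) < n_folds:
        raise ValueError(f"need at least {n_folds} positives to make {n_folds} folds, got {len(pairs)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    assignment = {pairs[idx]: (pos % n_folds) + 1 for pos, idx in enumerate(perm)}
    return FoldAssignment(assignment, n_folds, seed)


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve and trapezoidal AUC from scores and binary labels.

    Equal scores collapse onto one threshold, so a block of ties produces a
    single diagonal segment — this is what makes the trapezoidal AUC equal
    the Mann-Whitney U statistic with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D sequences of equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # last index of each tie block of distinct scores, descending
    distinct = np.nonzero(np.diff(s_sorted))[0]
    block_ends = np.r_[distinct, len(s_sorted) - 1]
    tp = np.cumsum(l_sorted)[block_ends]
    fp = np.cumsum(1 - l_sorted)[block_ends]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=s_sorted[block_ends], fpr=fpr, tpr=tpr, auc=auc)


@dataclass(frozen=True)
class CVResult:
    """Per-fold AUCs plus the pooled (micro-averaged) ROC over all folds."""

    fold_aucs: tuple[float, ...]
    pooled: ROCResult
    assignment: FoldAssignment

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))


def _similarities(
    kinases: Sequence[ProteinRecord],
    substrates: Sequence[ProteinRecord],
    sim_kin: SimilarityMatrix | None,
    sim_sub: SimilarityMatrix | None,
    align_params: AlignmentParams | None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    if sim_kin is None:
        sim_kin = build_similarity_matrix(kinases, align_params)
    if sim_sub is None:
        sim_sub = build_similarity_matrix(substrates, align_params)
    return sim_kin, sim_sub


def _svt_params(config: RunConfig) -> SVTParams:
    return SVTParams(tau=config.tau, delta=config.delta, max_iter=config.max_iter, tol=config.tol)


def run_pipeline_scores(
    interactions: InteractionList,
    sim_kin: SimilarityMatrix,
    sim_sub: SimilarityMatrix,
    config: RunConfig,
) -> np.ndarray:
    """adjust -> assemble -> complete -> extract, returning the m x n score block."""
    mat = build_interaction_matrix(interactions)
    adjusted = adjust_interactions(mat, sim_sub=sim_sub, sim_kin=sim_kin, t=config.t, mode=config.adjust_mode)
    hs = assemble_hetero(sim_kin, adjusted, sim_sub, omega_policy=config.omega_policy)
    result = svt_complete(hs, _svt_params(config))
    logger.debug(
        "completion: %d iterations, final residual %.3g, converged=%s",
        result.iterations,
        result.residual_trace[-1],
        result.converged,
    )
    return result.score_block


def cross_validate(
    kinases: Sequence[ProteinRecord],
    substrates: Sequence[ProteinRecord],
    interactions: InteractionList,
    config: RunConfig,
    n_folds: int = 10,
    sim_kin: SimilarityMatrix | None = None,
    sim_sub: SimilarityMatrix | None = None,
    align_params: AlignmentParams | None = None,
    inspect: Callable[[int, np.ndarray, frozenset, frozenset], None] | None = None,
) -> CVResult:
    """Ten-fold cross-validation of the full pipeline.

    For each fold the held-out positives are removed from the interaction
    matrix *before* the similarity adjustment, the pipeline runs on the
    training network, and the held-out positives are scored against every
    pair never observed as positive (training positives are excluded from
    the ranked pool). Per-fold AUCs and the pooled ROC over all folds'
    score/label pairs are returned.

    ``inspect(fold, training_matrix, test_pairs, train_pairs)`` is invoked
    with the pre-adjustment training matrix of every fold, for leakage
    instrumentation.
    """
    sim_kin, sim_sub = _similarities(kinases, substrates, sim_kin, sim_sub, align_params)
    assignment = ten_fold_split(interactions.pairs, config.seed, n_folds)
    folds = assignment.folds()
    all_positive = set(interactions.pairs)
    assert frozenset().union(*folds) == frozenset(all_positive)
    kpos = {k: i for i, k in enumerate(interactions.kinase_ids)}
    spos = {s: j for j, s in enumerate(interactions.substrate_ids)}

    fold_aucs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold_idx, test_pairs in enumerate(folds, 1):
        if not test_pairs:
            raise ValueError(f"fold {fold_idx} has no test positives")
        train_pairs = frozenset(all_positive - test_pairs)
        train_il = interactions.with_pairs(train_pairs)
        train_mat = build_interaction_matrix(train_il)
        for k, s in test_pairs:  # no-leakage guard, before any adjustment
            assert train_mat.values[kpos[k], spos[s]] == 0, f"held-out pair ({k}, {s}) present in training matrix"
        if inspect is not None:
            inspect(fold_idx, train_mat.values.copy(), test_pairs, train_pairs)
        scores = run_pipeline_scores(train_il, sim_kin, sim_sub, config)
        label_grid = np.zeros(scores.shape, dtype=np.int8)  # -1 = excluded (training positive)
        for k, s in train_pairs:
            label_grid[kpos[k], spos[s]] = -1
        for k, s in test_pairs:
            label_grid[kpos[k], spos[s]] = 1
        keep = label_grid >= 0
        fold_scores = scores[keep]
        fold_labels = label_grid[keep]
        roc = roc_points(fold_scores, fold_labels)
        fold_aucs.append(roc.auc)
        pooled_scores.append(fold_scores)
        pooled_labels.append(fold_labels)
        logger.info("fold %d/%d: %d test positives, AUC %.4f", fold_idx, n_folds, len(test_pairs), roc.auc)
    pooled = roc_points(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    logger.info("pooled AUC %.4f (per-fold mean %.4f)", pooled.auc, float(np.mean(fold_aucs)))
    return CVResult(tuple(fold_aucs), pooled, assignment)


def de_novo_test(
    kinases: Sequence[ProteinRecord],
    substrates: Sequence[ProteinRecord],
    interactions: InteractionList,
    kinase_id: str,
    config: RunConfig,
    sim_kin: SimilarityMatrix | None = None,
    sim_sub: SimilarityMatrix | None = None,
    align_params: AlignmentParams | None = None,
    inspect: Callable[[np.ndarray, frozenset], None] | None = None,
) -> ROCResult:
    """De-novo evaluation for one kinase.

    All known interactions of the queried kinase are deleted, the pipeline
    is rerun on the remainder, and the ROC is computed over that kinase's
    row only: its true substrates are the positives, every other substrate
    a negative. Models the arrival of a kinase with no annotated substrate.
    """
    if kinase_id not in interactions.kinase_ids:
        raise ValueError(f"unknown kinase id {kinase_id!r}")
    removed = frozenset(p for p in interactions.pairs if p[0] == kinase_id)
    if not removed:
        raise ValueError(f"kinase {kinase_id!r} has no known substrate; de-novo test undefined")
    true_subs = {s for _, s in removed}
    if len(true_subs) == len(interactions.substrate_ids):
        raise ValueError(f"kinase {kinase_id!r} interacts with every substrate; no negatives available")
    sim_kin, sim_sub = _similarities(kinases, substrates, sim_kin, sim_sub, align_params)
    train_il = interactions.with_pairs(interactions.pairs - removed)
    train_mat = build_interaction_matrix(train_il)
    row = interactions.kinase_ids.index(kinase_id)
    assert not train_mat.values[row].any(), "queried kinase still has edges in the training matrix"
    if inspect is not None:
        inspect(train_mat.values.copy(), removed)
    scores = run_pipeline_scores(train_il, sim_kin, sim_sub, config)
    labels = np.array([1 if s in true_subs else 0 for s in interactions.substrate_ids])
    return roc_points(scores[row], labels)
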