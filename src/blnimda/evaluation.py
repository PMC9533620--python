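"""Cross-validation, ROC/AUC, threshold sweep and top-k ranking.

Evaluation follows the masked-recomputation protocol: for every fold the
held-out known links are removed from the association matrix, the GIP
kernels and integrated similarities are rebuilt on the masked matrix
(so no label information leaks through the kernel profiles), the
pipeline is rerun, and the held-out pairs' scores are compared with the
scores of the global negative pool (all pairs unlinked in the *full*
matrix) under that same fold's model.

AUC is computed rank-based -- the probability that a positive outranks
a negative, ties counted one half -- which equals the trapezoidal area
under the threshold-swept ROC curve.  The reported cross-validation AUC
is the mean of the per-fold AUCs (per-left-out-pair AUCs for LOOCV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .data_io import AssociationMatrix, Params, ValidationError
from .profile_kernels import SimilarityInputs, integrated_similarities
from .scoring import ScoreBundle, combined_type_labels, score_pipeline

__all__ = [
    "CvResult",
    "roc_auc",
    "loocv",
    "kfold_cv",
    "t_sweep",
    "topk",
    "shuffled_label_auc",
]


@dataclass
class CvResult:
    """Outcome of one cross-validation run."""

    auc: float
    tpr: np.ndarray
    fpr: np.ndarray
    per_fold_auc: list[float]
    fold_assignments: np.ndarray  # fold id per positive, row-major pair order
    left_out_scores: np.ndarray  # held-out score per positive (first repeat)
    seed: int | None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "per_fold_auc": list(map(float, self.per_fold_auc)),
            "seed": self.seed,
            "config": self.config,
        }


def _check_scores(name: str, scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size == 0:
        raise ValidationError(f"{name} score array is empty")
    if not np.isfinite(scores).all():
        raise ValidationError(f"{name} scores contain NaN or infinity")
    return scores


def roc_auc(
    scores_pos: np.ndarray, scores_neg: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Rank-based AUC plus the threshold-swept ROC curve.

    Returns ``(auc, fpr, tpr)``.  The AUC is the Mann-Whitney statistic
    (ties counted 1/2) and agrees with trapezoidal integration of the
    returned curve to numerical precision.
    """
    pos = _check_scores("positive", scores_pos)
    neg = _check_scores("negative", scores_neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size
    )
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(labels, np.concatenate([pos, neg]))
    return float(auc), fpr, tpr


def _fold_score_matrix(
    A: AssociationMatrix,
    inputs: SimilarityInputs,
    params: Params,
    held_out: np.ndarray,
    refit_similarity: bool = True,
    cached=None,
) -> np.ndarray:
    masked = A.with_masked(held_out)
    if refit_similarity or cached is None:
        fms, fds = integrated_similarities(masked, inputs, params)
    else:
        fms, fds = cached
    return score_pipeline(masked, fms, fds, params).Sf


def _run_folds(
    A: AssociationMatrix,
    inputs: SimilarityInputs,
    params: Params,
    folds: list[np.ndarray],
    refit_similarity: bool,
) -> tuple[list[float], np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Score every fold; returns per-fold AUCs and pooled curve material."""
    negatives = A.values == 0
    positives = A.positive_pairs()
    pair_to_idx = {tuple(p): i for i, p in enumerate(positives)}
    left_out = np.full(len(positives), np.nan)
    cached = None
    if not refit_similarity:
        cached = integrated_similarities(A, inputs, params)
    fold_aucs: list[float] = []
    pos_pool: list[np.ndarray] = []
    neg_pool: list[np.ndarray] = []
    for fold_pairs in folds:
        sf = _fold_score_matrix(
            A, inputs, params, fold_pairs, refit_similarity, cached
        )
        fold_pos = sf[fold_pairs[:, 0], fold_pairs[:, 1]]
        fold_neg = sf[negatives]
        auc, _, _ = roc_auc(fold_pos, fold_neg)
        fold_aucs.append(auc)
        pos_pool.append(fold_pos)
        neg_pool.append(fold_neg)
        for pair, score in zip(fold_pairs, fold_pos):
            left_out[pair_to_idx[tuple(pair)]] = score
    return fold_aucs, left_out, pos_pool, neg_pool


def loocv(
    A: AssociationMatrix,
    inputs: SimilarityInputs,
    params: Params | None = None,
    refit_similarity: bool = True,
) -> CvResult:
    """Leave-one-out cross-validation over all known links.

    Each known link in turn is removed, kernels and integrated
    similarities are rebuilt on the masked matrix, and the link's score
    is ranked against the negative pool scored under the same fold.
    ``refit_similarity=False`` is a fast approximation that reuses the
    full-data integrated similarities across folds; it leaks the
    held-out link through the kernel profiles and is not the faithful
    protocol.
    """
    params = params or Params()
    positives = A.positive_pairs()
    if len(positives) < 2:
        raise ValidationError("LOOCV needs at least 2 known associations")
    folds = [positives[i : i + 1] for i in range(len(positives))]
    fold_aucs, left_out, pos_pool, neg_pool = _run_folds(
        A, inputs, params, folds, refit_similarity
    )
    auc = float(np.mean(fold_aucs))
    _, fpr, tpr = roc_auc(np.concatenate(pos_pool), np.concatenate(neg_pool))
    return CvResult(
        auc=auc,
        tpr=tpr,
        fpr=fpr,
        per_fold_auc=fold_aucs,
        fold_assignments=np.arange(len(positives)),
        left_out_scores=left_out,
        seed=None,
        config={
            "mode": "loocv",
            "refit_similarity": refit_similarity,
            "T": params.T,
        },
    )


def kfold_cv(
    A: AssociationMatrix,
    inputs: SimilarityInputs,
    params: Params | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    refit_similarity: bool = True,
) -> CvResult:
    """Repeated k-fold cross-validation over the known links.

    Known links are partitioned uniformly at random into k groups; each
    group in turn is masked and scored as in :func:`loocv`.  The
    reported AUC is the mean per-fold AUC over all folds and repeats.
    Fold assignments (first repeat) and held-out scores are retained for
    exact replay.  With k equal to the number of known links the fold
    structure -- and therefore every held-out score -- coincides with
    LOOCV.
    """
    params = params or Params()
    if k < 2:
        raise ValidationError("k must be >= 2")
    positives = A.positive_pairs()
    if len(positives) < k:
        raise ValidationError(
            f"cannot split {len(positives)} known associations into {k} folds"
        )
    rng = np.random.default_rng(seed)
    all_aucs: list[float] = []
    first_left_out = None
    first_assignments = None
    pos_pool: list[np.ndarray] = []
    neg_pool: list[np.ndarray] = []
    for repeat in range(repeats):
        order = rng.permutation(len(positives))
        assignment = np.empty(len(positives), dtype=int)
        folds = []
        for fold_id, chunk in enumerate(np.array_split(order, k)):
            assignment[chunk] = fold_id
            folds.append(positives[chunk])
        fold_aucs, left_out, rep_pos, rep_neg = _run_folds(
            A, inputs, params, folds, refit_similarity
        )
        all_aucs.extend(fold_aucs)
        pos_pool.extend(rep_pos)
        neg_pool.extend(rep_neg)
        if repeat == 0:
            first_left_out = left_out
            first_assignments = assignment
    auc = float(np.mean(all_aucs))
    _, fpr, tpr = roc_auc(np.concatenate(pos_pool), np.concatenate(neg_pool))
    return CvResult(
        auc=auc,
        tpr=tpr,
        fpr=fpr,
        per_fold_auc=all_aucs,
        fold_assignments=first_assignments,
        left_out_scores=first_left_out,
        seed=seed,
        config={
            "mode": "kfold",
            "k": k,
            "repeats": repeats,
            "refit_similarity": refit_similarity,
            "T": params.T,
        },
    )


def t_sweep(
    A: AssociationMatrix,
    inputs: SimilarityInputs,
    t_values,
    params: Params | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Mean k-fold AUC for each weak-similarity threshold T.

    Returns the (T, mean_auc) table and the argmax T (ties resolve to
    the smallest T).  The same seed is reused for every T so fold
    assignments are identical across the sweep.
    """
    t_values = list(t_values)
    if not t_values:
        raise ValidationError("t_values must be non-empty")
    base = params or Params()
    rows = []
    for T in t_values:
        swept = Params(
            T=T,
            delta=base.delta,
            beta_star_d=base.beta_star_d,
            beta_star_m=base.beta_star_m,
        )
        result = kfold_cv(A, inputs, swept, k=k, repeats=repeats, seed=seed)
        rows.append({"T": float(T), "mean_auc": result.auc})
    table = pd.DataFrame(rows)
    best_t = float(table.loc[table["mean_auc"].idxmax(), "T"])
    return table, best_t


def topk(
    bundle: ScoreBundle,
    A: AssociationMatrix,
    entity_id: str,
    k: int,
    direction: str = "mirnas-for-disease",
) -> pd.DataFrame:
    """Top-k novel candidates for one entity, known partners excluded.

    Candidates are ranked by final score descending, ties broken by
    identifier; the returned frame carries rank, id, score and the
    combined association-type label.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    labels = combined_type_labels(bundle)
    if direction == "mirnas-for-disease":
        h = A.index.disease_position(entity_id)
        ids = A.index.mirna_ids
        scores = bundle.Sf[:, h]
        known = A.values[:, h]
        types = labels[:, h]
    elif direction == "diseases-for-mirna":
        g = A.index.mirna_position(entity_id)
        ids = A.index.disease_ids
        scores = bundle.Sf[g, :]
        known = A.values[g, :]
        types = labels[g, :]
    else:
        raise ValueError(
            "direction must be 'mirnas-for-disease' or 'diseases-for-mirna'"
        )
    candidates = [
        (ids[i], float(scores[i]), str(types[i]))
        for i in range(len(ids))
        if known[i] == 0
    ]
    candidates.sort(key=lambda c: (-c[1], c[0]))
    rows = [
        {"rank": r + 1, "id": cid, "score": score, "association_type": label}
        for r, (cid, score, label) in enumerate(candidates[:k])
    ]
    return pd.DataFrame(rows, columns=["rank", "id", "score", "association_type"])


def shuffled_label_auc(
    A: AssociationMatrix,
    inputs: SimilarityInputs,
    params: Params | None = None,
    n_shuffles: int = 50,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation null: AUC of the scorer against shuffled positive labels.

    The pipeline is run once on the full data; then, for each shuffle, a
    random set of cells of the same size as the known-link set is
    treated as pseudo-positives and ranked against the remaining cells.
    Because the pseudo-labels are independent of the scores, the mean
    AUC concentrates at 0.5 for any scorer; deviations flag a broken
    ranking statistic.
    """
    params = params or Params()
    rng = np.random.default_rng(seed)
    fms, fds = integrated_similarities(A, inputs, params)
    scores = score_pipeline(A, fms, fds, params).Sf.ravel()
    n_pos = A.n_positives
    if not 0 < n_pos < scores.size:
        raise ValidationError("need both positive and negative cells to shuffle")
    aucs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        idx = rng.permutation(scores.size)
        auc, _, _ = roc_auc(scores[idx[:n_pos]], scores[idx[n_pos:]])
        aucs[i] = auc
    return float(aucs.mean()), aucs
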