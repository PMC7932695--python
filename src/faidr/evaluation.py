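"""ROC/AUC evaluation, protein-level cross-validation, and the held-out-IDR
protocol.

Protein-level performance uses k-fold cross-validation over proteins (never
splitting a protein's IDRs across folds), scoring held-out proteins with the
uniform-prior average of per-IDR probabilities.  IDR-level performance trains
on protein-level labels for 80% of proteins and scores the individual IDRs of
the held-out 20% against independent IDR-resolved ground truth (e.g. mapped
phosphosites or targeting-signal coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import AnnotationTable, FeatureTable, IDRLabelSet
from .model import EMConfig, fit_faidr, labels_for_function, predict_idr, predict_protein

__all__ = ["ROCResult", "auc", "roc_curve", "protein_cv", "heldout_idr_eval"]


class EvaluationError(ValueError):
    pass


@dataclass
class ROCResult:
    """An ROC curve: (FPR, TPR) points from (0,0) to (1,1) plus its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"need both classes to evaluate (got {n_pos} positives, {n_neg} negatives)"
        )
    return n_pos, n_neg


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count 0.5 per pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos, n_neg = _check_classes(labels)
    ranks = rankdata(scores)  # midranks
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Threshold sweep over unique scores, descending; trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos, n_neg = _check_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # keep one point per distinct threshold (last index of each tied block)
    last = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=area, n_pos=n_pos, n_neg=n_neg)


def _partition(
    proteins: list[str],
    labels: dict[str, int],
    k: int,
    rng: np.random.Generator,
    stratified: bool,
) -> list[list[str]]:
    if stratified:
        folds: list[list[str]] = [[] for _ in range(k)]
        for cls in (1, 0):
            members = [p for p in proteins if labels[p] == cls]
            perm = [members[i] for i in rng.permutation(len(members))]
            for i, p in enumerate(perm):
                folds[i % k].append(p)
        return folds
    perm = [proteins[i] for i in rng.permutation(len(proteins))]
    return [list(perm[i::k]) for i in range(k)]


def protein_cv(
    table: FeatureTable,
    annotations: AnnotationTable,
    function: str,
    k: int = 5,
    config: EMConfig | None = None,
    seed: int = 0,
    stratified: bool = False,
) -> dict:
    """k-fold cross-validated protein-level AUC for one function.

    Proteins are randomly divided into k folds; each fold is scored by a model
    trained on the other k-1 folds, using the uniform-prior protein
    probability.  Returns per-fold AUCs and their mean.
    """
    cfg = config or EMConfig()
    labels = labels_for_function(table, annotations, function)
    proteins = [p for p in table.protein_index if p in labels]
    rng = np.random.default_rng(seed)
    folds = _partition(proteins, labels, k, rng, stratified)
    fold_aucs = []
    for fold in folds:
        test_set = set(fold)
        train = table.subset_proteins([p for p in proteins if p not in test_set])
        test = table.subset_proteins(fold)
        y_test = np.array([labels[p] for p in test.protein_index])
        if len(set(y_test.tolist())) < 2:
            raise EvaluationError(
                "a fold contains a single class; rerun with stratified=True"
            )
        fit = fit_faidr(train, labels, cfg, function_name=function)
        scores = predict_protein(fit, test)
        fold_aucs.append(auc(scores, y_test))
    return {
        "function": function,
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.mean(fold_aucs)),
        "folds": [list(f) for f in folds],
    }


def heldout_idr_eval(
    table: FeatureTable,
    annotations: AnnotationTable,
    function: str,
    idr_labels: IDRLabelSet,
    holdout_fraction: float = 0.2,
    config: EMConfig | None = None,
    seed: int = 0,
) -> ROCResult:
    """Train on protein labels for 80% of proteins; score held-out IDRs.

    The held-out proteins' IDRs are scored with the per-IDR logistic
    probability and compared to the IDR-level ground-truth labels, which were
    never seen in training.  ``n_pos`` in the result is the number of positive
    IDRs in the held-out set.
    """
    cfg = config or EMConfig()
    labels = labels_for_function(table, annotations, function)
    proteins = [p for p in table.protein_index if p in labels]
    rng = np.random.default_rng(seed)
    n_hold = max(1, int(round(holdout_fraction * len(proteins))))
    perm = [proteins[i] for i in rng.permutation(len(proteins))]
    holdout = set(perm[:n_hold])
    train = table.subset_proteins([p for p in proteins if p not in holdout])
    test = table.subset_proteins(holdout)
    label_map = idr_labels.as_dict()
    missing = [i for i in test.idr_ids if i not in label_map]
    if missing:
        raise EvaluationError(
            f"{len(missing)} held-out IDRs lack ground-truth labels (e.g. {missing[0]!r})"
        )
    y_idr = np.array([label_map[i] for i in test.idr_ids])
    if y_idr.sum() == 0:
        raise EvaluationError("no positive IDR in the held-out set")
    fit = fit_faidr(train, labels, cfg, function_name=function)
    scores = predict_idr(fit, test)
    return roc_curve(scores, y_idr)
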