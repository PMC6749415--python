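"""Model validation: repeated double cross-validation, ROC/AUC, ablation.

Double (nested) cross-validation separates model selection from
performance estimation: the inner loop picks the number of latent
variables by misclassification on inner folds of the outer-training set;
the outer loop predicts the held-out fold with that choice. Repeating the
whole procedure over many random stratified fold draws gives mean +/- sd
sensitivity and specificity, which is how a small heterogeneous cohort is
honestly summarized without an external test set.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ..datatypes import DcvResult
from .plsda import classify, coef_for_components, fit_plsda

__all__ = ["roc_auc", "cv_predictions", "cv_misclassification", "repeated_double_cv", "ablation_rerun"]

logger = logging.getLogger(__name__)


def roc_auc(yhat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC over all decision thresholds.

    Equals the Mann-Whitney statistic U/(n1*n0) (ties counted 1/2).
    Returns (points, auc) with points an (m, 2) array of (FPR, TPR).
    """
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-yhat, kind="stable")
    ys = y[order]
    scores = yhat[order]
    tp = np.cumsum(ys == 1)
    fp = np.cumsum(ys == 0)
    # keep only the last point of each tied-score block
    distinct = np.append(np.diff(scores) != 0, True)
    tpr = np.concatenate([[0.0], tp[distinct] / n1])
    fpr = np.concatenate([[0.0], fp[distinct] / n0])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _fold_seed(seed: int, *parts: int) -> int:
    return int(np.random.SeedSequence([seed, *parts]).generate_state(1)[0] % (2**31 - 1))


def _stratified_folds(y: np.ndarray, k: int, seed: int):
    counts = np.bincount(y.astype(int))
    if np.any(counts[counts > 0] < k):
        raise ValueError(f"cannot build {k} stratified folds; a class has too few samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cv_predictions(
    X: np.ndarray, y: np.ndarray, A_max: int, k: int, seed: int
) -> np.ndarray:
    """Stratified k-fold CV predictions for every component count 1..A_max.

    Returns an (n, A_max) array; one PLS fit per fold yields the
    predictions of all truncated models. Columns beyond a fold's effective
    rank repeat the deepest available model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    preds = np.empty((n, A_max))
    for tr, te in _stratified_folds(y.astype(int), k, seed):
        a_cap = min(A_max, len(tr) - 1, p)
        model = fit_plsda(X[tr], y[tr], a_cap, scale=True)
        coefs = coef_for_components(model)  # (p, a_eff)
        Xte = (X[te] - model.x_mean) / model.x_scale
        block = Xte @ coefs + model.y_mean  # (n_te, a_eff)
        if block.shape[1] < A_max:
            pad = np.repeat(block[:, -1:], A_max - block.shape[1], axis=1)
            block = np.concatenate([block, pad], axis=1)
        preds[te] = block
    return preds


def cv_misclassification(
    X: np.ndarray,
    y: np.ndarray,
    A_grid: np.ndarray | list[int],
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[float, int]:
    """Minimum CV misclassification rate over the A grid, and the A chosen
    (smallest A on ties)."""
    A_grid = np.asarray(sorted(A_grid), dtype=int)
    preds = cv_predictions(X, y, int(A_grid.max()), k, seed)
    errors = [
        float(np.mean(classify(preds[:, a - 1], threshold) != y)) for a in A_grid
    ]
    best = int(np.argmin(errors))
    return errors[best], int(A_grid[best])


def repeated_double_cv(
    X: np.ndarray,
    y: np.ndarray,
    outer_k: int = 5,
    inner_k: int = 5,
    n_repetitions: int = 30,
    A_grid: np.ndarray | list[int] | None = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> DcvResult:
    """Repeated double (nested) cross-validation of the PLS-DA classifier.

    Per repetition: a fresh stratified outer split; on each outer-training
    set an inner stratified CV picks the number of latent variables from
    ``A_grid`` (default 1..10 capped by rank) by minimum misclassification;
    the refitted model predicts the held-out fold. Every sample is
    predicted exactly once per repetition. Sensitivity, specificity (at
    the Y = 0.5 rule) and AUC are computed per repetition and summarized
    as mean +/- sd across repetitions. Fully reproducible from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    if outer_k < 2 or inner_k < 2:
        raise ValueError("outer_k and inner_k must be >= 2")
    if A_grid is None:
        cap = min(10, p, n - 1)
        A_grid = list(range(1, cap + 1))

    preds = np.empty((n_repetitions, n))
    chosen = np.zeros((n_repetitions, outer_k), dtype=int)
    sens = np.empty(n_repetitions)
    spec = np.empty(n_repetitions)
    auc = np.empty(n_repetitions)
    mis_pos = np.empty(n_repetitions, dtype=int)
    mis_neg = np.empty(n_repetitions, dtype=int)

    for rep in range(n_repetitions):
        folds = _stratified_folds(y, outer_k, _fold_seed(seed, rep))
        for f, (tr, te) in enumerate(folds):
            _, a_best = cv_misclassification(
                X[tr], y[tr], A_grid, k=inner_k,
                seed=_fold_seed(seed, rep, f), threshold=threshold,
            )
            a_best = min(a_best, len(tr) - 1, p)
            model = fit_plsda(X[tr], y[tr], a_best, scale=True)
            preds[rep, te] = model.predict(X[te])
            chosen[rep, f] = model.n_components
        calls = classify(preds[rep], threshold)
        pos, neg = y == 1, y == 0
        sens[rep] = float((calls[pos] == 1).mean())
        spec[rep] = float((calls[neg] == 0).mean())
        mis_pos[rep] = int((calls[pos] == 0).sum())
        mis_neg[rep] = int((calls[neg] == 1).sum())
        _, auc[rep] = roc_auc(preds[rep], y)

    return DcvResult(
        predictions=preds,
        chosen_components=chosen,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        misclassified_pos=mis_pos,
        misclassified_neg=mis_neg,
        threshold=threshold,
        seed=seed,
    )


def ablation_rerun(
    X: np.ndarray,
    y: np.ndarray,
    drop_sets: list[list[int]],
    outer_k: int = 5,
    inner_k: int = 5,
    n_repetitions: int = 10,
    threshold: float = 0.5,
    seed: int = 0,
) -> list[dict]:
    """Re-test the classifier with variable subsets removed.

    Each drop set is removed in turn and the identical repeated-dCV
    protocol (same seed, hence the same fold draws) is rerun; the table
    reports sensitivity/specificity deltas against the all-variable
    reference, with the reference's between-repetition sd as the noise
    band.
    """
    X = np.asarray(X, dtype=float)
    ref = repeated_double_cv(
        X, y, outer_k, inner_k, n_repetitions, threshold=threshold, seed=seed
    )
    rows = [
        {
            "dropped": (),
            "sensitivity": ref.sensitivity_mean,
            "specificity": ref.specificity_mean,
            "d_sensitivity": 0.0,
            "d_specificity": 0.0,
            "sd_sensitivity": ref.sensitivity_sd,
            "sd_specificity": ref.specificity_sd,
        }
    ]
    for drop in drop_sets:
        drop = sorted(set(int(i) for i in drop))
        if any(i < 0 or i >= X.shape[1] for i in drop):
            raise ValueError(f"drop set {drop} out of range")
        keep = [j for j in range(X.shape[1]) if j not in drop]
        res = repeated_double_cv(
            X[:, keep], y, outer_k, inner_k, n_repetitions,
            threshold=threshold, seed=seed,
        )
        rows.append(
            {
                "dropped": tuple(drop),
                "sensitivity": res.sensitivity_mean,
                "specificity": res.specificity_mean,
                "d_sensitivity": res.sensitivity_mean - ref.sensitivity_mean,
                "d_specificity": res.specificity_mean - ref.specificity_mean,
                "sd_sensitivity": res.sensitivity_sd,
                "sd_specificity": res.specificity_sd,
            }
        )
    return rows
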