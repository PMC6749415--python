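"""Model diagnostics: selectivity ratios and the PCA batch-structure check.

The selectivity ratio ranks variables by how much of their variance lies
on the target-projected component of a fitted PLS model — an
explained-to-residual variance ratio per variable. Reporting tiers at 0.1
(strong) and 0.07 (moderate) are conventional for flagging the most
discriminating metabolites.

The PCA batch check looks for unwanted structure tied to acquisition
batches (analysis day): principal components of the autoscaled table are
tested for association with the batch factor by one-way ANOVA.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import f_oneway
from sklearn.decomposition import PCA

from ..datatypes import PlsDaModel

__all__ = ["selectivity_ratio", "sr_tiers", "pca_batch_check"]

SR_SENTINEL = 1e12  # documented clamp for variables with zero residual


def selectivity_ratio(model: PlsDaModel, X: np.ndarray) -> np.ndarray:
    """Per-variable selectivity ratio via target projection.

    With ``b`` the PLS regression vector on the (scaled) data ``X``:
    ``t_TP = X b / ||b||``, ``p_TP = X^T t_TP / (t_TP^T t_TP)``, and
    ``SR_j = ||t_TP p_TP,j||^2 / ||x_j - t_TP p_TP,j||^2``. A variable
    fully explained by the target component (zero residual) is clamped to
    ``SR_SENTINEL``.
    """
    b = model.coef
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("regression vector is zero; selectivity ratio undefined")
    X = (np.asarray(X, dtype=float) - model.x_mean) / model.x_scale
    t = X @ (b / nb)
    tt = float(t @ t)
    if tt == 0:
        raise ValueError("target-projection scores are all zero")
    p_tp = X.T @ t / tt
    explained = tt * p_tp**2
    total = (X**2).sum(axis=0)
    residual = total - explained
    sr = np.where(residual > 1e-12 * np.maximum(total, 1e-30),
                  explained / np.maximum(residual, 1e-300),
                  SR_SENTINEL)
    return sr


def sr_tiers(sr: np.ndarray, strong: float = 0.1, moderate: float = 0.07) -> dict:
    """Split variables into the conventional reporting tiers."""
    sr = np.asarray(sr, dtype=float)
    return {
        "strong": np.nonzero(sr > strong)[0],
        "moderate": np.nonzero((sr > moderate) & (sr <= strong))[0],
        "below": np.nonzero(sr <= moderate)[0],
    }


def pca_batch_check(
    X: np.ndarray,
    batch_labels: np.ndarray,
    n_components: int = 5,
    alpha: float = 0.01,
    autoscale: bool = True,
) -> dict:
    """Test leading principal components for association with batch.

    Returns a report with PC scores, per-PC ANOVA p-values for the batch
    factor, the flagged PCs at level ``alpha``, and an overall pass flag
    (pass = no PC associated with batch, i.e. no day-of-analysis
    structure).
    """
    X = np.asarray(X, dtype=float)
    batches = np.asarray(batch_labels)
    uniq = np.unique(batches)
    if uniq.size < 2:
        raise ValueError("at least 2 batches are required")
    if autoscale:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    pvals = np.array(
        [
            f_oneway(*(scores[batches == b, j] for b in uniq)).pvalue
            for j in range(k)
        ]
    )
    flagged = np.nonzero(pvals < alpha)[0]
    return {
        "scores": scores,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "pvalues": pvals,
        "flagged_pcs": flagged,
        "alpha": alpha,
        "passed": flagged.size == 0,
    }
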