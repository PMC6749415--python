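"""PLS1 discriminant analysis (NIPALS with single-Y deflation).

The class variable is coded BPH = 0 / PCa = 1 and regressed by partial
least squares; a sample is called positive when its predicted Y-value
reaches the discriminating threshold of 0.5 (a tie at exactly 0.5 goes to
the positive class). NIPALS is used rather than a black-box fit so the
weights W, scores T, loadings P and Y-loadings q are available exactly as
the VIP and selectivity-ratio formulas require them.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import PlsDaModel

__all__ = ["fit_plsda", "classify", "coef_for_components"]


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    center: bool = True,
    scale: bool = False,
) -> PlsDaModel:
    """Fit an A-component PLS1 model of the coded class variable.

    ``X`` is expected already autoscaled (see
    :func:`~metabopipe.chemometrics.preprocess.log10_autoscale`); set
    ``scale=True`` to autoscale inside the fit (as the cross-validation
    loops do, so scaling is always learned on training samples only).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present in y")
    if not (1 <= A <= min(n - 1, p)):
        raise ValueError(f"A={A} out of range for n={n}, p={p}")

    x_mean = X.mean(axis=0) if center else np.zeros(p)
    if scale:
        sd = X.std(axis=0, ddof=1)
        x_scale = np.where(sd > 0, sd, 1.0)
    else:
        x_scale = np.ones(p)
    y_mean = float(y.mean())

    Xa = (X - x_mean) / x_scale
    ya = y - y_mean
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    ssy = np.zeros(A)
    a_eff = 0
    for a in range(A):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break  # nothing left to model
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        pa = Xa.T @ t / tt
        qa = float(ya @ t) / tt
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        ssy[a] = qa**2 * tt
        a_eff = a + 1
    W, P, T, q, ssy = W[:, :a_eff], P[:, :a_eff], T[:, :a_eff], q[:a_eff], ssy[:a_eff]
    if a_eff == 0:
        raise ValueError("X carries no covariance with y; cannot fit any component")
    b = W @ np.linalg.solve(P.T @ W, q)
    return PlsDaModel(
        n_components=a_eff,
        weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=q,
        coef=b,
        y_mean=y_mean,
        x_mean=x_mean,
        x_scale=x_scale,
        ssy=ssy,
    )


def coef_for_components(model: PlsDaModel) -> np.ndarray:
    """Regression vectors for every truncation 1..A of the model.

    Column a-1 is the coefficient vector of the a-component model; this is
    what makes picking A by cross-validation cheap (one fit, all A).
    """
    A = model.n_components
    p = model.weights.shape[0]
    out = np.zeros((p, A))
    ptw = model.x_loadings.T @ model.weights
    for a in range(1, A + 1):
        out[:, a - 1] = model.weights[:, :a] @ np.linalg.solve(
            ptw[:a, :a], model.y_loadings[:a]
        )
    return out


def classify(yhat: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary call from predicted Y-values: 1 iff ``yhat >= threshold``."""
    return (np.asarray(yhat, dtype=float) >= threshold).astype(int)
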