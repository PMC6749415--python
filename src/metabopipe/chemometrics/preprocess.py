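"""Feature-table preprocessing for classification.

The semiquantitative concentrations are log10 transformed (to even out the
right-skewed within-class distributions) and autoscaled (per-column mean 0,
standard deviation 1) before any PLS modeling.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from ..datatypes import FeatureTable

__all__ = ["log10_autoscale"]

logger = logging.getLogger(__name__)


def log10_autoscale(
    table, pseudo: float | None = None, ddof: int = 1
) -> tuple[np.ndarray, dict]:
    """``x -> log10(x + pseudo)`` then column-wise autoscaling.

    Parameters
    ----------
    table : FeatureTable, DataFrame or 2-D array of non-negative values.
    pseudo : pseudo-count added before the log. ``None`` (default) uses
        half the smallest positive value of each column, which keeps exact
        zeros finite without distorting the occupied range.
    ddof : degrees of freedom for the scaling standard deviation (1, the
        sample sd, matching common chemometrics practice).

    Returns
    -------
    (X_scaled, record)
        ``record`` holds the means, sds, kept column indices/names and the
        pseudo-counts, sufficient to apply the identical transform to new
        samples. Zero-variance columns are dropped with a warning.
    """
    if isinstance(table, FeatureTable):
        df = table.values
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(np.asarray(table, dtype=float))
    X = df.values.astype(float)
    if np.any(X < 0):
        raise ValueError("negative entries cannot be log-transformed")

    if pseudo is None:
        pseudos = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            pos = X[:, j][X[:, j] > 0]
            pseudos[j] = 0.5 * pos.min() if pos.size else 1.0
        # a column of exact zeros still maps to a constant; dropped below
        pseudos = np.where((X > 0).any(axis=0), pseudos, 1.0)
    else:
        pseudos = np.full(X.shape[1], float(pseudo))

    with np.errstate(divide="ignore"):
        L = np.log10(X + pseudos[None, :])
    if not np.all(np.isfinite(L)):
        raise ValueError("log10 produced non-finite values; use a positive pseudo-count")

    sds = L.std(axis=0, ddof=ddof)
    keep = sds > 0
    if not np.all(keep):
        dropped = list(df.columns[~keep])
        warnings.warn(f"dropping {len(dropped)} zero-variance column(s): {dropped[:5]}")
        logger.warning("dropping zero-variance columns: %s", dropped)
    L = L[:, keep]
    means = L.mean(axis=0)
    sds_kept = L.std(axis=0, ddof=ddof)
    Z = (L - means[None, :]) / sds_kept[None, :]
    record = {
        "means": means,
        "sds": sds_kept,
        "pseudo": pseudos[keep],
        "kept_columns": list(df.columns[keep]),
        "kept_mask": keep,
        "ddof": ddof,
    }
    return Z, record
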