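"""Core in-memory containers for the GC-MS metabolomics pipeline.

The central object is the three-way array (samples x retention time x m/z)
produced by binning full-scan electron-impact chromatograms onto a unit-m/z
grid. Downstream stages attach factor models, feature tables and
classification results to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThreeWayArray",
    "SpectrumRecord",
    "GroundTruth",
    "SyntheticDataset",
    "Interval",
    "Parafac2Model",
    "ComponentLabel",
    "FeatureTable",
    "WarpingPath",
    "PlsDaModel",
    "DcvResult",
    "SelectionResult",
]


@dataclass
class ThreeWayArray:
    """Samples x RT-scans x m/z-bins data cube for one derivatization channel.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_rt, n_mz)
        Non-negative binned intensities.
    rt_axis : ndarray, shape (n_rt,)
        Retention time in seconds at each scan index, strictly increasing.
    mz_axis : ndarray, shape (n_mz,)
        Integer m/z bin centers, strictly increasing.
    sample_ids : sequence of str
    channel_tag : {"TMS", "TFA"}
        Which derivatization channel the cube belongs to.
    """

    data: np.ndarray
    rt_axis: np.ndarray
    mz_axis: np.ndarray
    sample_ids: Sequence[str]
    channel_tag: str = "TMS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.rt_axis = np.asarray(self.rt_axis, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (samples x RT x m/z)")
        n, j, m = self.data.shape
        if len(self.rt_axis) != j:
            raise ValueError("rt_axis length does not match data")
        if len(self.mz_axis) != m:
            raise ValueError("mz_axis length does not match data")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match data")
        if np.any(np.diff(self.rt_axis) <= 0):
            raise ValueError("rt_axis must be strictly increasing")
        if np.any(np.diff(np.asarray(self.mz_axis, dtype=float)) <= 0):
            raise ValueError("mz_axis must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_rt(self) -> int:
        return self.data.shape[1]

    @property
    def n_mz(self) -> int:
        return self.data.shape[2]

    def tic(self) -> np.ndarray:
        """Total ion current traces, shape (n_samples, n_rt)."""
        return self.data.sum(axis=2)


@dataclass
class SpectrumRecord:
    """A named EI mass spectrum as (m/z, intensity) peak pairs."""

    name: str
    mz: np.ndarray
    intensity: np.ndarray
    base_peak_value: float = 999.0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if len(np.unique(self.mz)) != len(self.mz):
            raise ValueError("m/z values must be unique")

    def normalized(self, base: float | None = None) -> "SpectrumRecord":
        """Return a copy scaled so the base peak equals ``base``."""
        base = self.base_peak_value if base is None else base
        top = self.intensity.max() if self.intensity.size else 0.0
        inten = self.intensity * (base / top) if top > 0 else self.intensity
        return SpectrumRecord(self.name, self.mz.copy(), inten, base)


@dataclass
class GroundTruth:
    """Latent structure underlying a synthetic dataset.

    spectra : (n_mz, R) non-negative, unit-norm columns
    elution : list of (n_rt, R) non-negative per-sample profiles
    scores : (n_samples, R) non-negative true relative concentrations
    class_labels : (n_samples,) 0 = BPH-like, 1 = PCa-like
    effect_log2fc : (R,) log2 fold-change of class-mean scores
    shift : (n_samples,) integer per-sample retention shift in scan points
    """

    spectra: np.ndarray
    elution: list[np.ndarray]
    scores: np.ndarray
    class_labels: np.ndarray
    effect_log2fc: np.ndarray
    shift: np.ndarray
    baseline_params: dict = field(default_factory=dict)
    noise_sd: float = 0.0


@dataclass
class SyntheticDataset:
    tensor: ThreeWayArray
    truth: GroundTruth
    creatinine: np.ndarray
    channel_tag: str = "TMS"
    snr_db: float | None = None
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Interval:
    """Half-open RT scan range [start, stop) on one channel's cube."""

    start: int
    stop: int
    channel_tag: str = "TMS"
    r_hint: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ValueError(f"invalid interval [{self.start}, {self.stop})")


@dataclass
class Parafac2Model:
    """Fitted interval-wise PARAFAC2 factor set.

    The model is ``X_k ~= B_k diag(d_k) C^T`` with ``B_k = P_k F``:
    per-sample elution profiles sharing a constant cross-product
    ``B_k^T B_k = F^T F``, non-negative spectra ``C`` (unit-norm columns)
    and non-negative sample scores ``D`` (rows ``d_k``).
    """

    rank: int
    spectra: np.ndarray            # C, (n_mz, R)
    scores: np.ndarray             # D, (n_samples, R)
    elution: list[np.ndarray]      # B_k, (interval_len, R) each
    coupling: np.ndarray           # F, (R, R)
    sse_history: np.ndarray
    fit_percent: float
    iterations_used: int
    converged: bool
    interval: Interval | None = None

    def cross_product_residual(self) -> float:
        """Max over samples of relative deviation of B_k^T B_k from B_0^T B_0."""
        g0 = self.elution[0].T @ self.elution[0]
        denom = np.linalg.norm(g0)
        if denom == 0:
            return 0.0
        return max(
            np.linalg.norm(b.T @ b - g0) / denom for b in self.elution
        )


@dataclass
class ComponentLabel:
    label: str                      # baseline | noise | compound
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in {"baseline", "noise", "compound"}:
            raise ValueError(f"unknown component label {self.label!r}")


@dataclass
class FeatureTable:
    """Samples x compounds relative-concentration matrix with provenance.

    ``values`` is a DataFrame (rows = samples, columns = compounds);
    ``provenance`` is a DataFrame indexed like the columns with channel,
    interval bounds, RT apex and any notes; ``creatinine`` is per-sample.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    creatinine: pd.Series | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("relative concentrations must be non-negative")


@dataclass
class WarpingPath:
    """Piecewise-linear COW correspondence between sample and target axes."""

    target_nodes: np.ndarray
    sample_nodes: np.ndarray
    slack: int
    benefit: float

    def __post_init__(self) -> None:
        self.target_nodes = np.asarray(self.target_nodes, dtype=int)
        self.sample_nodes = np.asarray(self.sample_nodes, dtype=int)
        if np.any(np.diff(self.target_nodes) <= 0) or np.any(
            np.diff(self.sample_nodes) <= 0
        ):
            raise ValueError("warping path nodes must be strictly increasing")

    def source_coordinates(self) -> np.ndarray:
        """Fractional source index for every target index (linear in-segment)."""
        return np.interp(
            np.arange(self.target_nodes[-1] + 1),
            self.target_nodes.astype(float),
            self.sample_nodes.astype(float),
        )


@dataclass
class PlsDaModel:
    """PLS1 discriminant model on autoscaled data (Y coded BPH=0, PCa=1)."""

    n_components: int
    weights: np.ndarray        # W, (p, A)
    x_loadings: np.ndarray     # P, (p, A)
    x_scores: np.ndarray       # T, (n, A)
    y_loadings: np.ndarray     # q, (A,)
    coef: np.ndarray           # b, (p,)
    y_mean: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    ssy: np.ndarray            # explained Y sum of squares per component

    def predict(self, x_raw: np.ndarray) -> np.ndarray:
        """Predict the coded class value for rows of ``x_raw`` (pre-scaling units)."""
        xa = (np.asarray(x_raw, dtype=float) - self.x_mean) / self.x_scale
        return xa @ self.coef + self.y_mean


@dataclass
class DcvResult:
    """Repeated double cross-validation summary."""

    predictions: np.ndarray      # (n_repetitions, n_samples) CV-predicted y-hat
    chosen_components: np.ndarray  # (n_repetitions, outer_k)
    sensitivity: np.ndarray      # per repetition
    specificity: np.ndarray
    auc: np.ndarray
    misclassified_pos: np.ndarray
    misclassified_neg: np.ndarray
    threshold: float
    seed: int

    @property
    def sensitivity_mean(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def sensitivity_sd(self) -> float:
        return float(np.std(self.sensitivity, ddof=1)) if len(self.sensitivity) > 1 else 0.0

    @property
    def specificity_mean(self) -> float:
        return float(np.mean(self.specificity))

    @property
    def specificity_sd(self) -> float:
        return float(np.std(self.specificity, ddof=1)) if len(self.specificity) > 1 else 0.0

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc))

    def summary(self) -> dict:
        return {
            "sensitivity_mean": self.sensitivity_mean,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity_mean": self.specificity_mean,
            "specificity_sd": self.specificity_sd,
            "auc_mean": self.auc_mean,
            "auc_sd": float(np.std(self.auc, ddof=1)) if len(self.auc) > 1 else 0.0,
            "misclassified_pos_mean": float(np.mean(self.misclassified_pos)),
            "misclassified_neg_mean": float(np.mean(self.misclassified_neg)),
            "n_repetitions": int(len(self.sensitivity)),
            "threshold": self.threshold,
        }


@dataclass
class SelectionResult:
    """Outcome of a variable-selection step with a replayable trace."""

    selected: np.ndarray          # indices into the input variable set
    method: str
    trace: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
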