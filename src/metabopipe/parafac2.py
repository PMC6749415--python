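"""Interval-wise PARAFAC2 deconvolution of GC-MS data cubes.

The model for an RT interval is, per sample k,

    X_k  ~=  B_k diag(d_k) C^T,      B_k = P_k F,  P_k^T P_k = I,

so every sample shares one spectral matrix ``C`` (m/z x R) and one elution
shape subspace, while elution profiles ``B_k`` may shift and reshape per
sample subject to the constant cross-product constraint
``B_k^T B_k = F^T F``. Scores ``d_k`` are the per-sample relative
concentrations (uniform response factor of 1). Fitting is alternating
least squares in the direct form: orthonormal ``P_k`` by Procrustes (SVD),
then one CP-ALS sweep on the projected slabs ``Y_k = P_k^T X_k`` with
non-negativity (NNLS) on spectra and scores. Every update is an exact
conditional minimizer, so the squared error is non-increasing at each
iteration.

Baseline and detector noise appear as extra components; a rule-based
classifier labels each component baseline / noise / compound (with manual
override), and only compound components enter the feature table.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.signal import find_peaks

from .datatypes import (
    ComponentLabel,
    FeatureTable,
    Interval,
    Parafac2Model,
    SpectrumRecord,
    ThreeWayArray,
)

__all__ = [
    "fit_parafac2",
    "select_rank",
    "classify_components",
    "extract_relative_concentrations",
    "creatinine_normalize",
    "match_spectrum",
    "propose_intervals",
    "read_intervals",
    "write_intervals",
    "deconvolve_tensor",
    "tucker_congruence",
    "match_factors",
]

logger = logging.getLogger(__name__)


def _nnls_columns(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||G x - b||, x >= 0 for every column b of B."""
    out = np.empty((B.shape[1], G.shape[1]))
    for j in range(B.shape[1]):
        out[j], _ = nnls(G, B[:, j])
    return out


def _init_factors(
    slabs: list[np.ndarray], R: int, how: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    K = len(slabs)
    M = slabs[0].shape[1]
    if how == "svd":
        xtx = np.zeros((M, M))
        for x in slabs:
            xtx += x.T @ x
        vals, vecs = np.linalg.eigh(xtx)
        C = np.abs(vecs[:, ::-1][:, :R])
    else:
        C = rng.random((M, R)) + 0.1
    C /= np.maximum(np.linalg.norm(C, axis=0), 1e-12)
    D = np.ones((K, R))
    F = np.eye(R)
    return F, C, D


def fit_parafac2(
    slabs: list[np.ndarray] | np.ndarray,
    R: int,
    nonneg_modes: tuple[str, ...] = ("spectra", "scores"),
    max_iter: int = 10_000,
    tol: float = 1e-8,
    seed: int = 0,
    n_starts: int = 3,
    interval: Interval | None = None,
) -> Parafac2Model:
    """Fit a PARAFAC2 model to one interval's slab set.

    Parameters
    ----------
    slabs : K slabs of shape (interval_len, n_mz), or a 3-D array.
    R : number of components.
    nonneg_modes : subset of {"spectra", "scores"}; elution profiles are
        left unconstrained (the direct-fit algorithm cannot constrain them;
        negative excursions are available as a diagnostic).
    max_iter : iteration cap (default honors the conventional 10,000).
    tol : relative change in SSE below which ALS stops.
    n_starts : multi-start count; start 0 is SVD-based, the rest random.
        The start with the lowest final SSE is returned.

    Returns
    -------
    Parafac2Model with converged=False (not an exception) if the cap was
    reached before the tolerance.
    """
    slabs = [np.asarray(x, dtype=float) for x in slabs]
    K = len(slabs)
    J, M = slabs[0].shape
    if R < 1:
        raise ValueError("R must be >= 1")
    if J < R:
        raise ValueError("interval length must be >= R")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    sstot = sum(float((x**2).sum()) for x in slabs)
    if sstot == 0:
        raise ValueError("interval is all-zero")

    rng = np.random.default_rng(seed)
    best: Parafac2Model | None = None
    for start in range(max(n_starts, 1)):
        F, C, D = _init_factors(slabs, R, "svd" if start == 0 else "random", rng)
        history: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # -- orthonormal per-sample bases (Procrustes)
            Y = np.empty((K, R, M))
            proj_ss = 0.0
            P_list = []
            for k in range(K):
                target = slabs[k] @ C @ (D[k][:, None] * F.T)
                U, _, Vt = np.linalg.svd(target, full_matrices=False)
                P = U @ Vt
                P_list.append(P)
                Y[k] = P.T @ slabs[k]
                proj_ss += float((Y[k] ** 2).sum())

            # -- one CP-ALS sweep on the projected slabs
            # F (unconstrained)
            num = np.zeros((R, R))
            den = np.zeros((R, R))
            ctc = C.T @ C
            for k in range(K):
                num += Y[k] @ C @ np.diag(D[k])
                den += np.outer(D[k], D[k]) * ctc
            F = np.linalg.solve(den + 1e-12 * np.eye(R), num.T).T

            # C
            G = np.concatenate([F * D[k][None, :] for k in range(K)], axis=0)
            Yst = Y.reshape(K * R, M)
            if "spectra" in nonneg_modes:
                C = _nnls_columns(G, Yst)
            else:
                C = np.linalg.lstsq(G, Yst, rcond=None)[0].T
            norms = np.maximum(np.linalg.norm(C, axis=0), 1e-12)
            C /= norms
            D *= norms[None, :]

            # D
            H = np.stack([np.outer(F[:, r], C[:, r]).ravel() for r in range(R)], axis=1)
            if "scores" in nonneg_modes:
                for k in range(K):
                    D[k], _ = nnls(H, Y[k].ravel())
            else:
                D = np.linalg.lstsq(H, Y.reshape(K, -1).T, rcond=None)[0].T

            # normalize F columns into D
            fn = np.maximum(np.linalg.norm(F, axis=0), 1e-12)
            F = F / fn
            D = D * fn[None, :]

            # SSE via the projection identity
            resid = 0.0
            for k in range(K):
                resid += float(((Y[k] - F @ np.diag(D[k]) @ C.T) ** 2).sum())
            sse = sstot - proj_ss + resid
            history.append(sse)
            if len(history) > 1:
                prev = history[-2]
                if prev > 0 and (prev - sse) / prev < tol:
                    converged = True
                    break

        model = Parafac2Model(
            rank=R,
            spectra=C,
            scores=D,
            elution=[P @ F for P in P_list],
            coupling=F,
            sse_history=np.asarray(history),
            fit_percent=100.0 * (1.0 - history[-1] / sstot),
            iterations_used=it,
            converged=converged,
            interval=interval,
        )
        if best is None or model.sse_history[-1] < best.sse_history[-1]:
            best = model
    assert best is not None
    return best


def select_rank(
    slabs: list[np.ndarray] | np.ndarray,
    R_max: int,
    fit_gain_threshold: float = 1.0,
    **fit_kwargs,
) -> tuple[int, dict]:
    """Recommend a component count for one interval.

    Fits R = 1..R_max and returns the smallest R whose marginal fit gain
    (percentage points of explained variation going to R+1) falls below
    ``fit_gain_threshold``; if every gain exceeds the threshold, R_max is
    recommended. An interval that stays poorly explained even at R_max
    (below ``low_fit_floor`` percent) is treated as structureless: 1 is
    recommended with the low-fit flag raised, so no components are wasted
    on noise-only RT ranges. The full fit report is returned for audit.
    """
    if R_max < 1:
        raise ValueError("R_max must be >= 1")
    fit_kwargs.setdefault("max_iter", 500)
    low_fit_floor = fit_kwargs.pop("low_fit_floor", 50.0)
    fits = {}
    for r in range(1, R_max + 1):
        fits[r] = fit_parafac2(slabs, r, **fit_kwargs).fit_percent
    if fits[R_max] < low_fit_floor:
        recommended = 1
    else:
        recommended = R_max
        for r in range(1, R_max):
            if fits[r + 1] - fits[r] < fit_gain_threshold:
                recommended = r
                break
    report = {
        "fit_percent": fits,
        "threshold": fit_gain_threshold,
        "low_fit_flag": fits[recommended] < low_fit_floor,
    }
    return recommended, report


def _spectral_entropy(col: np.ndarray) -> float:
    p = np.abs(col)
    s = p.sum()
    if s == 0:
        return 1.0
    p = p / s
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(col)))


def _profile_diagnostics(profile: np.ndarray) -> tuple[float, int]:
    """(coefficient of variation, number of local maxima above 10% of apex)."""
    prof = np.clip(profile, 0.0, None)
    mean = prof.mean()
    cv = float(prof.std() / mean) if mean > 0 else np.inf
    if prof.max() > 0:
        peaks, _ = find_peaks(prof, height=0.1 * prof.max())
        n_modes = int(len(peaks))
        if n_modes == 0 and prof.max() > 0:
            n_modes = 1  # apex at an edge
    else:
        n_modes = 0
    return cv, n_modes


def classify_components(
    model: Parafac2Model,
    flatness_cv: float = 0.35,
    entropy_threshold: float = 0.85,
    min_offset_frac: float = 0.5,
    override: dict[int, str] | None = None,
) -> list[ComponentLabel]:
    """Label each component baseline / noise / compound.

    Deterministic rules on the fitted factors: a near-flat mean elution
    profile (low coefficient of variation) holding a nonzero offset across
    the whole interval (minimum at least ``min_offset_frac`` of the
    maximum) is baseline; a high-entropy (white-ish) spectrum whose
    profile fails unimodality is noise; everything else is a compound.
    ``override`` maps component index -> label and wins.
    """
    override = override or {}
    mean_prof = np.mean(np.stack(model.elution, axis=0), axis=0)  # (J, R)
    labels = []
    for r in range(model.rank):
        cv, n_modes = _profile_diagnostics(mean_prof[:, r])
        entropy = _spectral_entropy(model.spectra[:, r])
        prof = np.clip(mean_prof[:, r], 0, None)
        offset_frac = float(prof.min() / prof.max()) if prof.max() > 0 else 0.0
        diag = {
            "profile_cv": cv,
            "n_modes": n_modes,
            "spectral_entropy": entropy,
            "offset_frac": offset_frac,
            "score_cv": float(
                model.scores[:, r].std() / model.scores[:, r].mean()
            )
            if model.scores[:, r].mean() > 0
            else np.inf,
        }
        if r in override:
            labels.append(ComponentLabel(override[r], diag))
            continue
        if cv < flatness_cv and offset_frac > min_offset_frac:
            labels.append(ComponentLabel("baseline", diag))
        elif entropy > entropy_threshold and n_modes != 1:
            labels.append(ComponentLabel("noise", diag))
        else:
            labels.append(ComponentLabel("compound", diag))
    return labels


def extract_relative_concentrations(
    models: list[Parafac2Model],
    labels: list[list[ComponentLabel]],
    sample_ids: list[str] | None = None,
    creatinine: np.ndarray | None = None,
    rt_axis: np.ndarray | None = None,
) -> FeatureTable:
    """Collect compound components into a samples x compounds feature table.

    A compound's per-sample value is its score ``D[k, r]`` scaled by the
    norms of its (unit-normalized) spectrum and mean elution profile, so
    the value is TIC-like at a uniform response factor of 1. Compounds from
    overlapping intervals with close RT apexes are both kept, flagged
    ``duplicate_suspect`` for manual merging.
    """
    if len(models) != len(labels):
        raise ValueError("one label list per model is required")
    cols, prov_rows, names = [], [], []
    for model, labs in zip(models, labels):
        if len(labs) != model.rank:
            raise ValueError("every component needs a label")
        iv = model.interval or Interval(0, model.elution[0].shape[0])
        mean_prof = np.mean(np.stack(model.elution, axis=0), axis=0)
        for r, lab in enumerate(labs):
            if lab.label != "compound":
                continue
            spec_norm = float(np.linalg.norm(model.spectra[:, r]))
            prof = np.clip(mean_prof[:, r], 0.0, None)
            prof_norm = float(np.linalg.norm(prof))
            values = model.scores[:, r] * spec_norm * prof_norm
            apex_scan = iv.start + int(np.argmax(prof))
            name = f"{iv.channel_tag}_rt{apex_scan}_i{iv.start}c{r}"
            cols.append(np.clip(values, 0.0, None))
            names.append(name)
            prov_rows.append(
                {
                    "channel": iv.channel_tag,
                    "interval_start": iv.start,
                    "interval_stop": iv.stop,
                    "component": r,
                    "rt_apex_scan": apex_scan,
                    "rt_apex_s": float(rt_axis[apex_scan])
                    if rt_axis is not None
                    else np.nan,
                    "note": "",
                }
            )
    if not cols:
        values = pd.DataFrame(index=sample_ids or [])
        return FeatureTable(values=values, provenance=pd.DataFrame(), creatinine=None)
    n = len(cols[0])
    ids = sample_ids if sample_ids is not None else [f"S{k:03d}" for k in range(n)]
    values = pd.DataFrame(np.column_stack(cols), index=ids, columns=names)
    prov = pd.DataFrame(prov_rows, index=names)
    # flag suspected duplicates from overlapping intervals
    for i in range(len(prov)):
        for j in range(i + 1, len(prov)):
            a, b = prov.iloc[i], prov.iloc[j]
            overlap = (
                a["channel"] == b["channel"]
                and a["interval_start"] < b["interval_stop"]
                and b["interval_start"] < a["interval_stop"]
                and (a["interval_start"], a["interval_stop"])
                != (b["interval_start"], b["interval_stop"])
            )
            if overlap and abs(a["rt_apex_scan"] - b["rt_apex_scan"]) <= 2:
                prov.iloc[i, prov.columns.get_loc("note")] = "duplicate_suspect"
                prov.iloc[j, prov.columns.get_loc("note")] = "duplicate_suspect"
                logger.warning(
                    "compounds %s and %s look like duplicates across "
                    "overlapping intervals",
                    prov.index[i],
                    prov.index[j],
                )
    creat = pd.Series(creatinine, index=ids) if creatinine is not None else None
    return FeatureTable(values=values, provenance=prov, creatinine=creat)


def creatinine_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample's row by its urinary creatinine value."""
    if table.creatinine is None:
        raise ValueError("feature table carries no creatinine values")
    creat = np.asarray(table.creatinine, dtype=float)
    bad = np.nonzero(creat <= 0)[0]
    if bad.size:
        names = [str(table.values.index[i]) for i in bad]
        raise ValueError(f"non-positive creatinine for sample(s): {', '.join(names)}")
    values = table.values.div(creat, axis=0)
    prov = table.provenance.copy()
    if "note" in prov.columns:
        prov["note"] = (prov["note"].astype(str) + ";creatinine_normalized").str.lstrip(";")
    return FeatureTable(
        values=values, provenance=prov, creatinine=table.creatinine, normalized=True
    )


# ---------------------------------------------------------------------------
# Spectral matching (NIST-style match factor against a user-supplied library)


def _on_common_grid(a: SpectrumRecord, b: SpectrumRecord) -> tuple[np.ndarray, np.ndarray]:
    bins_a = np.rint(a.mz).astype(int)
    bins_b = np.rint(b.mz).astype(int)
    lo = min(bins_a.min(), bins_b.min())
    hi = max(bins_a.max(), bins_b.max())
    va = np.zeros(hi - lo + 1)
    vb = np.zeros(hi - lo + 1)
    np.add.at(va, bins_a - lo, a.intensity)
    np.add.at(vb, bins_b - lo, b.intensity)
    return va, vb


def match_spectrum(
    query: SpectrumRecord, library: list[SpectrumRecord]
) -> list[tuple[str, float]]:
    """Rank library entries by a NIST-style match factor (0-999).

    The factor is a cosine-squared weighted dot product on square-root
    intensities over integer m/z bins:
    ``999 * (sum_i sqrt(q_i * l_i))^2 / (sum_i q_i * sum_i l_i)``.
    Ties are broken by library order (stable sort).
    """
    if not library:
        raise ValueError("library is empty")
    factors = []
    for rec in library:
        q, l = _on_common_grid(query, rec)
        denom = q.sum() * l.sum()
        if denom == 0:
            factors.append(0.0)
            continue
        num = float(np.sqrt(q * l).sum()) ** 2
        factors.append(999.0 * num / denom)
    order = np.argsort(-np.asarray(factors), kind="stable")
    return [(library[i].name, factors[i]) for i in order]


# ---------------------------------------------------------------------------
# Intervals


def propose_intervals(
    x: ThreeWayArray,
    min_prominence_frac: float = 0.05,
    min_width: int = 5,
    r_hint: int = 3,
) -> list[Interval]:
    """Heuristic interval proposal from the mean TIC (peak picking with
    valley splitting) for unattended runs; hand-curated interval files are
    the first-class input."""
    tic = x.tic().mean(axis=0)
    peaks, _ = find_peaks(tic, prominence=min_prominence_frac * tic.max())
    if len(peaks) == 0:
        return [Interval(0, x.n_rt, x.channel_tag, r_hint)]
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(tic[a:b])))
    bounds.append(x.n_rt)
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s >= min_width:
            out.append(Interval(int(s), int(e), x.channel_tag, r_hint))
    return out


def read_intervals(path: str | Path) -> list[Interval]:
    """Interval CSV: columns channel, start_scan, stop_scan, R_hint."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out.append(
                Interval(
                    int(row["start_scan"]),
                    int(row["stop_scan"]),
                    row.get("channel", "TMS"),
                    int(row["R_hint"]) if row.get("R_hint") else None,
                )
            )
    return out


def write_intervals(intervals: list[Interval], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "start_scan", "stop_scan", "R_hint"])
        for iv in intervals:
            w.writerow([iv.channel_tag, iv.start, iv.stop, iv.r_hint or ""])


def deconvolve_tensor(
    x: ThreeWayArray,
    intervals: list[Interval],
    R_default: int = 3,
    creatinine: np.ndarray | None = None,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    seed: int = 0,
    n_starts: int = 3,
    classify_kwargs: dict | None = None,
) -> tuple[FeatureTable, list[Parafac2Model]]:
    """Fit, classify and semiquantify every interval of one channel's cube."""
    models, labels = [], []
    for iv in intervals:
        if iv.stop > x.n_rt:
            raise ValueError(f"interval {iv} exceeds the RT axis")
        slabs = [x.data[k, iv.start : iv.stop, :] for k in range(x.n_samples)]
        r = iv.r_hint or R_default
        model = fit_parafac2(
            slabs, r, max_iter=max_iter, tol=tol, seed=seed, n_starts=n_starts,
            interval=iv,
        )
        models.append(model)
        labels.append(classify_components(model, **(classify_kwargs or {})))
    table = extract_relative_concentrations(
        models,
        labels,
        sample_ids=list(x.sample_ids),
        creatinine=creatinine,
        rt_axis=x.rt_axis,
    )
    return table, models


# ---------------------------------------------------------------------------
# Factor-recovery scoring (used by tests and quality reports)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two factor vectors (sign-insensitive)."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(abs(a @ b) / (na * nb))


def match_factors(estimated: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal column permutation (Hungarian) maximizing summed congruence.

    Returns (permutation applied to estimated columns, per-pair congruences
    in truth-column order).
    """
    from scipy.optimize import linear_sum_assignment

    R = truth.shape[1]
    cost = np.empty((R, R))
    for i in range(R):
        for j in range(R):
            cost[i, j] = -tucker_congruence(truth[:, i], estimated[:, j])
    rows, cols = linear_sum_assignment(cost)
    cong = -cost[rows, cols]
    return cols, cong
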