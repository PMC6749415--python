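"""Correlation optimized warping (COW) of chromatographic signals.

COW splits the target trace into segments of roughly equal length and finds,
by dynamic programming, the placement of segment boundaries on the sample
trace — each boundary free to move by at most ``slack`` points from its
nominal position increment — that maximizes the summed per-segment Pearson
correlation after linear interpolation of each sample segment onto the
target segment length. For a data cube the warp is computed on each
sample's total ion current (TIC) and the same piecewise-linear time map is
applied to every m/z channel, preserving within-scan spectral integrity.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solveh_banded

from .datatypes import ThreeWayArray, WarpingPath

__all__ = ["cow_align", "align_tensor", "subtract_baseline", "apply_warp"]


def _segment_correlation(
    a: np.ndarray, b: np.ndarray, floor_a: float = 0.0, floor_b: float = 0.0
) -> float:
    """Pearson correlation; 0 (not NaN) for degenerate segments.

    A segment is degenerate when it is constant, or when its standard
    deviation falls below the supplied floor — a signal-free stretch whose
    fluctuations are noise carries no alignment information, and scoring
    it 0 stops the path from chasing noise correlations there.
    """
    if a.std() <= floor_a or b.std() <= floor_b:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b) / (na * nb)


def _nodes(length: int, n_segments: int) -> np.ndarray:
    return np.round(np.linspace(0, length - 1, n_segments + 1)).astype(int)


def cow_align(
    target: np.ndarray,
    sample: np.ndarray,
    segment_len: int,
    slack: int,
    min_std_frac: float = 0.05,
) -> tuple[np.ndarray, WarpingPath]:
    """Warp ``sample`` onto ``target``'s grid by segmented COW.

    Parameters
    ----------
    target, sample : 1-D signals, each of length >= 2 * segment_len.
    segment_len : nominal target segment length in points.
    slack : maximum deviation of each segment's sample-side length from its
        nominal value, ``0 <= slack < segment_len``.
    min_std_frac : segments whose standard deviation is below this fraction
        of the whole signal's are scored 0 (degenerate), so signal-free
        stretches do not steer the path.

    Returns
    -------
    (warped, path)
        ``warped`` has the target's length; ``path`` carries the optimal
        boundary placements and the summed correlation (benefit).
    """
    target = np.asarray(target, dtype=float)
    sample = np.asarray(sample, dtype=float)
    if len(target) < 2 * segment_len or len(sample) < 2 * segment_len:
        raise ValueError("signals must be at least 2 * segment_len long")
    if not (0 <= slack < segment_len):
        raise ValueError("require 0 <= slack < segment_len")

    lt, ls = len(target), len(sample)
    n_seg = max(1, int(round((lt - 1) / segment_len)))
    t_nodes = _nodes(lt, n_seg)
    s_nominal = _nodes(ls, n_seg)
    seg_lens = np.diff(s_nominal)  # nominal sample-side segment lengths

    # Feasible sample positions per node: forward and backward cumulative
    # slack bounds, with the two endpoints pinned.
    lo = np.empty(n_seg + 1, dtype=int)
    hi = np.empty(n_seg + 1, dtype=int)
    lo[0] = hi[0] = 0
    for i in range(1, n_seg + 1):
        lo[i] = lo[i - 1] + seg_lens[i - 1] - slack
        hi[i] = hi[i - 1] + seg_lens[i - 1] + slack
    blo, bhi = ls - 1, ls - 1
    lo[n_seg] = hi[n_seg] = ls - 1
    for i in range(n_seg - 1, 0, -1):
        blo, bhi = blo - seg_lens[i] - slack, bhi - seg_lens[i] + slack
        lo[i] = max(lo[i], blo)
        hi[i] = min(hi[i], bhi)
        if lo[i] > hi[i]:
            raise ValueError("no feasible warping path; increase slack")

    # DP over node positions. Candidate segment lengths are visited in
    # order of increasing deviation from nominal with strictly-improving
    # updates, so correlation ties (flat or noise-only segments) resolve to
    # the least-warping path.
    floor_t = min_std_frac * float(target.std())
    floor_s = min_std_frac * float(sample.std())
    best: list[dict[int, float]] = [{0: 0.0}]
    back: list[dict[int, int]] = [{}]
    for i in range(1, n_seg + 1):
        tlen = t_nodes[i] - t_nodes[i - 1] + 1
        tseg = target[t_nodes[i - 1] : t_nodes[i] + 1]
        grid = np.linspace(0.0, 1.0, tlen)
        deltas = sorted(range(-slack, slack + 1), key=abs)
        cur: dict[int, float] = {}
        bk: dict[int, int] = {}
        for u in sorted(range(lo[i], hi[i] + 1), key=lambda x: abs(x - s_nominal[i])):
            for delta in deltas:
                v = u - (seg_lens[i - 1] + delta)
                if v not in best[i - 1]:
                    continue
                sseg = np.interp(grid * (u - v), np.arange(u - v + 1), sample[v : u + 1])
                cand = best[i - 1][v] + _segment_correlation(tseg, sseg, floor_t, floor_s)
                if cand > cur.get(u, -np.inf) + 1e-12:
                    cur[u] = cand
                    bk[u] = v
        best.append(cur)
        back.append(bk)

    end = ls - 1
    benefit = best[n_seg][end]
    s_nodes = [end]
    for i in range(n_seg, 0, -1):
        s_nodes.append(back[i][s_nodes[-1]])
    s_nodes.reverse()
    path = WarpingPath(
        target_nodes=t_nodes, sample_nodes=np.array(s_nodes), slack=slack, benefit=benefit
    )
    return apply_warp(sample, path), path


def _stretch_factors(path: WarpingPath) -> np.ndarray:
    """Per-target-point source/target length ratio (piecewise constant)."""
    t_len = np.diff(path.target_nodes)
    s_len = np.diff(path.sample_nodes)
    factors = np.repeat(s_len / t_len, t_len)
    return np.append(factors, factors[-1])


def apply_warp(
    signal: np.ndarray, path: WarpingPath, conserve_intensity: bool = True
) -> np.ndarray:
    """Resample a 1-D signal onto the target grid along a warping path.

    Linear interpolation inside segments; with ``conserve_intensity`` each
    segment is additionally scaled by its source/target length ratio (the
    Jacobian of the time map), so integrated peak area is preserved under
    stretching and compression.
    """
    src = path.source_coordinates()
    out = np.interp(src, np.arange(len(signal)), np.asarray(signal, dtype=float))
    if conserve_intensity:
        out = out * _stretch_factors(path)
    return out


def _pick_reference(tics: np.ndarray, rule: str | int) -> int:
    """Reference sample: the one whose TIC has the highest median Pearson
    correlation to all other samples' TICs."""
    if isinstance(rule, (int, np.integer)):
        return int(rule)
    if rule != "median_tic":
        raise ValueError(f"unknown reference rule {rule!r}")
    c = np.corrcoef(tics)
    np.fill_diagonal(c, np.nan)
    med = np.nanmedian(c, axis=1)
    return int(np.argmax(med))


def align_tensor(
    x: ThreeWayArray,
    reference_rule: str | int = "median_tic",
    segment_len: int = 40,
    slack: int = 5,
    axis: str = "rt",
    max_rounds: int = 5,
    improvement_tol: float = 1e-3,
) -> tuple[ThreeWayArray, list[WarpingPath]]:
    """COW-align every sample of a data cube to a reference.

    For ``axis='rt'`` the warp is computed on each sample's TIC against the
    reference TIC and applied to every m/z channel of that sample. Warping
    is iterated until the mean TIC correlation to the reference improves by
    less than ``improvement_tol`` (a quantitative surrogate for visual
    inspection), up to ``max_rounds``. For ``axis='mz'`` the same 1-D
    algorithm is applied to mean spectra (rarely needed on integer-binned
    EI data; provided for completeness).
    """
    if axis not in {"rt", "mz"}:
        raise ValueError("axis must be 'rt' or 'mz'")
    data = x.data.copy()
    if axis == "mz":
        data = np.transpose(data, (0, 2, 1))
    tics = data.sum(axis=2)
    ref = _pick_reference(tics, reference_rule)
    if not np.any(tics[ref]):
        raise ValueError("reference sample TIC is identically zero")

    ref_trace = tics[ref].copy()
    n_seg = max(1, int(round((len(ref_trace) - 1) / segment_len)))
    identity = WarpingPath(
        target_nodes=_nodes(data.shape[1], n_seg),
        sample_nodes=_nodes(data.shape[1], n_seg),
        slack=slack,
        benefit=float(n_seg),
    )
    paths: list[WarpingPath] = [identity] * data.shape[0]
    prev_corr = float(
        np.mean(
            [_segment_correlation(ref_trace, data[k].sum(axis=1))
             for k in range(data.shape[0])]
        )
    )
    for _ in range(max_rounds):
        # build the round's candidate and commit it only if it improves the
        # mean TIC correlation to the reference by at least the tolerance
        cand = data.copy()
        cand_paths = list(paths)
        corrs = []
        base = np.arange(data.shape[1])
        for k in range(data.shape[0]):
            if k == ref:
                corrs.append(1.0)
                continue
            trace = data[k].sum(axis=1)
            pre = _segment_correlation(ref_trace, trace)
            _, path = cow_align(ref_trace, trace, segment_len, slack)
            src = path.source_coordinates()
            fac = _stretch_factors(path)
            warped = np.empty_like(cand[k])
            for m in range(data.shape[2]):
                warped[:, m] = np.interp(src, base, data[k, :, m]) * fac
            post = _segment_correlation(ref_trace, warped.sum(axis=1))
            # a warp that degrades this sample's agreement with the
            # reference is discarded (the sample keeps its current state)
            if post > pre:
                cand[k] = warped
                cand_paths[k] = path
                corrs.append(post)
            else:
                corrs.append(pre)
        mean_corr = float(np.mean(corrs))
        if mean_corr - prev_corr < improvement_tol:
            break
        data, paths, prev_corr = cand, cand_paths, mean_corr

    if axis == "mz":
        data = np.transpose(data, (0, 2, 1))
    aligned = ThreeWayArray(
        data=data,
        rt_axis=x.rt_axis.copy(),
        mz_axis=np.asarray(x.mz_axis).copy(),
        sample_ids=list(x.sample_ids),
        channel_tag=x.channel_tag,
    )
    return aligned, paths


def _asls(y: np.ndarray, lam: float = 1e5, p: float = 0.01, n_iter: int = 10) -> np.ndarray:
    """Asymmetric least squares baseline (Whittaker smoother with
    asymmetric weights), solved as a pentadiagonal system."""
    n = len(y)
    # banded (upper) form of lam * D2'D2 with D2 the second-difference matrix
    d = np.full(n, 6.0)
    d[[0, -1]] = 1.0
    d[[1, -2]] = 5.0
    e = np.full(n - 1, -4.0)
    e[[0, -1]] = -2.0
    ab0 = np.zeros((3, n))
    ab0[0, 2:] = lam * 1.0
    ab0[1, 1:] = lam * e
    ab0[2, :] = lam * d
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        ab = ab0.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def subtract_baseline(
    x: ThreeWayArray,
    method: str = "asls",
    lam: float = 1e5,
    p: float = 0.01,
    clip: bool = True,
) -> ThreeWayArray:
    """Subtract a slowly varying baseline from every (sample, m/z) RT trace.

    ``asls`` uses asymmetric least squares (peaks are up-weighted out of the
    fit); ``linear`` fits and removes a straight line per trace. This step
    is cosmetic for visualization — the PARAFAC2 stage models baseline
    components explicitly — and is off by default in the pipeline.
    """
    if method not in {"asls", "linear"}:
        raise ValueError(f"unknown baseline method {method!r}")
    data = x.data.copy()
    n, j, m = data.shape
    t = np.arange(j, dtype=float)
    for k in range(n):
        for mm in range(m):
            trace = data[k, :, mm]
            if not np.any(trace):
                continue
            if method == "linear":
                coef = np.polyfit(t, trace, 1)
                base = np.polyval(coef, t)
            else:
                base = _asls(trace, lam=lam, p=p)
            data[k, :, mm] = trace - base
    if clip:
        np.clip(data, 0.0, None, out=data)
    return ThreeWayArray(
        data=data,
        rt_axis=x.rt_axis.copy(),
        mz_axis=np.asarray(x.mz_axis).copy(),
        sample_ids=list(x.sample_ids),
        channel_tag=x.channel_tag,
    )
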