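"""Synthetic GC-MS three-way data with known ground truth.

Emulates the structure of urinary-metabolomics cubes: tens of co-eluting
components with sparse EI spectra, per-sample retention shifts, column-bleed
baseline and additive detector noise, plus a two-class design in which a
subset of components is over- or under-expressed.

Two elution modes are offered:

``exact_parafac2``
    Per-sample profiles are circular shifts (orthonormal permutations) of a
    common template, so the elution Gram matrix ``B_k^T B_k`` is constant
    across samples to machine precision — exactly the structural assumption
    of the PARAFAC2 model, which makes factor-recovery tests sharp.

``shifted_gaussian``
    Profiles are Gaussians re-evaluated at shifted centers with edge
    truncation; this mildly violates the model and leaves real retention
    misalignment for the warping stage to fix.
"""

from __future__ import annotations

import numpy as np

from .datatypes import GroundTruth, SyntheticDataset, ThreeWayArray

__all__ = [
    "generate_spectra",
    "generate_elution",
    "generate_scores",
    "assemble_tensor",
    "make_dataset",
    "feature_scenario",
    "DEFAULT_SCENARIO",
]

# Desk-scale defaults for the end-to-end study conditions: two classes of
# 43 and 48 samples, 20 discriminating compounds among 150 uninformative
# features, within-class concentration CV of 30%.
DEFAULT_SCENARIO = {
    "n_samples": 91,
    "class_fractions": (43 / 91, 48 / 91),
    "n_markers": 20,
    "n_noise_features": 150,
    "marker_log2fc_min": 1.0,
    "marker_log2fc_max": 2.0,
    "cv_within": 0.30,
}


def generate_spectra(
    n_mz: int,
    R: int,
    peaks_per_spectrum: int,
    seed: int,
    congruence_max: float = 0.9,
    max_tries: int = 500,
) -> np.ndarray:
    """Draw R sparse, non-negative, unit-norm EI-like spectra.

    Each spectrum has exactly ``peaks_per_spectrum`` nonzero integer-m/z
    bins with log-normal peak heights. Columns are rejection-sampled until
    every pairwise congruence (cosine) is below ``congruence_max`` so the
    components are identifiable.

    Returns
    -------
    ndarray of shape (n_mz, R)
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if peaks_per_spectrum < 1:
        raise ValueError("peaks_per_spectrum must be >= 1")
    if n_mz <= peaks_per_spectrum:
        raise ValueError("n_mz must exceed peaks_per_spectrum")
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    tries = 0
    while len(cols) < R:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not draw {R} spectra with pairwise congruence "
                f"< {congruence_max} after {max_tries} attempts"
            )
        tries += 1
        col = np.zeros(n_mz)
        support = rng.choice(n_mz, size=peaks_per_spectrum, replace=False)
        col[support] = rng.lognormal(mean=0.0, sigma=0.8, size=peaks_per_spectrum)
        col /= np.linalg.norm(col)
        if all(float(col @ c) < congruence_max for c in cols):
            cols.append(col)
    return np.column_stack(cols)


def _gaussian_profiles(
    n_rt: int, centers: np.ndarray, widths: np.ndarray
) -> np.ndarray:
    t = np.arange(n_rt)[:, None]
    return np.exp(-0.5 * ((t - centers[None, :]) / widths[None, :]) ** 2)


def generate_elution(
    n_rt: int,
    R: int,
    n_samples: int,
    mode: str = "shifted_gaussian",
    shift_max: int = 0,
    seed: int = 0,
    width_range: tuple[float, float] = (2.0, 5.0),
    margin_frac: float = 0.2,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-sample elution profile matrices plus the true shift vector.

    Peak centers are spread over the interior of the RT window (a margin of
    ``margin_frac * n_rt`` plus the maximum shift keeps peaks away from the
    edges). In ``exact_parafac2`` mode sample k's profiles are the template
    circularly shifted by ``shift[k]`` points — a permutation, hence the
    profile Gram matrix is identical across samples. In ``shifted_gaussian``
    mode the Gaussians are re-evaluated at shifted centers.
    """
    if mode not in {"exact_parafac2", "shifted_gaussian"}:
        raise ValueError(f"unknown elution mode {mode!r}")
    if shift_max >= n_rt:
        raise ValueError("shift_max must be smaller than n_rt")
    rng = np.random.default_rng(seed)
    margin = int(np.ceil(margin_frac * n_rt)) + shift_max
    lo, hi = margin, n_rt - margin
    if hi <= lo:
        raise ValueError("RT window too short for the requested margin and shifts")
    centers = np.sort(rng.uniform(lo, hi, size=R))
    widths = rng.uniform(*width_range, size=R)
    template = _gaussian_profiles(n_rt, centers, widths)
    shifts = (
        rng.integers(-shift_max, shift_max + 1, size=n_samples)
        if shift_max > 0
        else np.zeros(n_samples, dtype=int)
    )
    profiles: list[np.ndarray] = []
    for s in shifts:
        if mode == "exact_parafac2":
            profiles.append(np.roll(template, int(s), axis=0))
        else:
            profiles.append(_gaussian_profiles(n_rt, centers + s, widths))
    return profiles, shifts


def generate_scores(
    n_samples: int,
    R: int,
    class_fractions: tuple[float, float],
    effect_log2fc: np.ndarray | float,
    cv_within: float,
    seed: int = 0,
    base_level: float | np.ndarray = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class log-normal relative concentrations.

    ``class_fractions`` is (fraction of class 1 / PCa-like, fraction of
    class 0 / BPH-like); counts are realized exactly by rounding. Component
    r's class-1 mean is ``2**effect_log2fc[r]`` times its class-0 mean, and
    within-class values are log-normal with coefficient of variation
    ``cv_within``.

    Returns (scores, labels): (n_samples, R) non-negative and (n_samples,).
    """
    if not np.isclose(sum(class_fractions), 1.0):
        raise ValueError("class fractions must sum to 1")
    if cv_within <= 0:
        raise ValueError("cv_within must be positive")
    effect = np.broadcast_to(np.asarray(effect_log2fc, dtype=float), (R,))
    base = np.broadcast_to(np.asarray(base_level, dtype=float), (R,))
    rng = np.random.default_rng(seed)
    n1 = int(round(n_samples * class_fractions[0]))
    labels = np.zeros(n_samples, dtype=int)
    labels[:n1] = 1
    labels = labels[rng.permutation(n_samples)]
    # log-normal with the requested mean: mu = log(mean) - sigma^2/2
    sigma = np.sqrt(np.log1p(cv_within**2))
    class_mean = base[None, :] * np.power(2.0, effect[None, :] * labels[:, None])
    mu = np.log(class_mean) - sigma**2 / 2
    scores = rng.lognormal(mean=mu, sigma=sigma)
    return scores, labels


def _bleed_baseline(
    n_rt: int, n_mz: int, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Column-bleed-like baseline: rising low-order polynomial in RT times a
    smooth decaying m/z envelope."""
    t = np.linspace(0, 1, n_rt)
    drift = amplitude * (0.3 + 0.7 * t**2 + 0.1 * rng.uniform() * t)
    envelope = np.exp(-np.arange(n_mz) / max(n_mz / 4, 1.0))
    envelope /= envelope.max()
    return np.outer(drift, envelope)


def assemble_tensor(
    truth: GroundTruth,
    baseline_amplitude: float = 0.0,
    noise_sd: float | None = 0.0,
    seed: int = 0,
    snr_db: float | None = None,
    heteroscedastic: bool = False,
    clip_negative: bool = True,
    channel_tag: str = "TMS",
    scan_period_s: float = 1.0 / 2.28,
    mz_start: int = 40,
) -> SyntheticDataset:
    """Build the data cube ``X_k = B_k diag(d_k) C^T + baseline_k + noise_k``.

    If ``snr_db`` is given it overrides ``noise_sd``: the noise standard
    deviation is set so that ``10 log10(sum signal^2 / E sum noise^2)``
    equals the requested value; the realized SNR (from the drawn noise) is
    recorded on the dataset.
    """
    rng = np.random.default_rng(seed)
    n_samples, R = truth.scores.shape
    n_rt = truth.elution[0].shape[0]
    n_mz = truth.spectra.shape[0]
    if truth.spectra.shape[1] != R or len(truth.elution) != n_samples:
        raise ValueError("ground-truth factor shapes are inconsistent")

    signal = np.empty((n_samples, n_rt, n_mz))
    for k in range(n_samples):
        signal[k] = (truth.elution[k] * truth.scores[k][None, :]) @ truth.spectra.T

    baseline = (
        _bleed_baseline(n_rt, n_mz, baseline_amplitude, rng)
        if baseline_amplitude > 0
        else np.zeros((n_rt, n_mz))
    )

    if snr_db is not None:
        signal_power = float(np.mean(signal**2))
        noise_sd = float(np.sqrt(signal_power / 10 ** (snr_db / 10)))
    noise_sd = float(noise_sd or 0.0)

    if noise_sd > 0:
        if heteroscedastic:
            local_sd = noise_sd * np.sqrt(np.maximum(signal, 0.0) / max(signal.mean(), 1e-30))
            noise = rng.normal(0.0, 1.0, size=signal.shape) * local_sd
        else:
            noise = rng.normal(0.0, noise_sd, size=signal.shape)
    else:
        noise = np.zeros_like(signal)

    data = signal + baseline[None, :, :] + noise
    if clip_negative:
        np.clip(data, 0.0, None, out=data)

    realized_snr = (
        10 * np.log10(np.sum(signal**2) / np.sum(noise**2))
        if noise_sd > 0
        else None
    )

    tensor = ThreeWayArray(
        data=data,
        rt_axis=scan_period_s * np.arange(n_rt),
        mz_axis=np.arange(mz_start, mz_start + n_mz),
        sample_ids=[f"S{k:03d}" for k in range(n_samples)],
        channel_tag=channel_tag,
    )
    truth.baseline_params = {"amplitude": baseline_amplitude}
    truth.noise_sd = noise_sd
    creatinine = rng.lognormal(mean=np.log(10.0), sigma=0.4, size=n_samples)
    return SyntheticDataset(
        tensor=tensor,
        truth=truth,
        creatinine=creatinine,
        channel_tag=channel_tag,
        snr_db=realized_snr,
        params={
            "seed": seed,
            "noise_sd": noise_sd,
            "baseline_amplitude": baseline_amplitude,
            "heteroscedastic": heteroscedastic,
            "clip_negative": clip_negative,
        },
    )


def make_dataset(
    n_samples: int = 40,
    n_rt: int = 300,
    n_mz: int = 80,
    R: int = 12,
    peaks_per_spectrum: int = 6,
    mode: str = "shifted_gaussian",
    shift_max: int = 3,
    class_fractions: tuple[float, float] = (43 / 91, 48 / 91),
    effect_log2fc: np.ndarray | float | None = None,
    cv_within: float = 0.30,
    baseline_amplitude: float = 0.0,
    noise_sd: float | None = 0.0,
    snr_db: float | None = None,
    heteroscedastic: bool = False,
    seed: int = 0,
    channel_tag: str = "TMS",
    margin_frac: float = 0.2,
) -> SyntheticDataset:
    """One-call generator combining spectra, elution, scores and assembly.

    Defaults are desk-scale (40 x 300 x 80, a dozen components); the
    full-cohort shapes are supported but slow for routine testing. By
    default a quarter of the components get |log2FC| = 1 effects with
    alternating sign, the rest none.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    if effect_log2fc is None:
        effect_log2fc = np.zeros(R)
        n_eff = max(R // 4, 1)
        effect_log2fc[:n_eff] = [1.0 if i % 2 == 0 else -1.0 for i in range(n_eff)]
    spectra = generate_spectra(n_mz, R, peaks_per_spectrum, seed=int(sub[0]))
    elution, shifts = generate_elution(
        n_rt, R, n_samples, mode=mode, shift_max=shift_max, seed=int(sub[1]),
        margin_frac=margin_frac,
    )
    scores, labels = generate_scores(
        n_samples, R, class_fractions, effect_log2fc, cv_within, seed=int(sub[2])
    )
    truth = GroundTruth(
        spectra=spectra,
        elution=elution,
        scores=scores,
        class_labels=labels,
        effect_log2fc=np.broadcast_to(np.asarray(effect_log2fc, float), (R,)).copy(),
        shift=shifts,
    )
    return assemble_tensor(
        truth,
        baseline_amplitude=baseline_amplitude,
        noise_sd=noise_sd,
        snr_db=snr_db,
        heteroscedastic=heteroscedastic,
        seed=int(sub[3]),
        channel_tag=channel_tag,
    )


def feature_scenario(
    seed: int = 0,
    n_samples: int | None = None,
    n_markers: int | None = None,
    n_noise_features: int | None = None,
    cv_within: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Feature-table-level study scenario for the classification stages.

    Generates the default two-class cohort (43 vs 48 samples) with
    ``n_markers`` discriminating compounds of |log2FC| in [1, 2] with
    alternating over/under-expression, buried among ``n_noise_features``
    compounds with no class effect.

    Returns
    -------
    X : (n_samples, n_features) positive relative concentrations
    y : (n_samples,) class labels (1 = PCa-like)
    marker_idx : indices of the true markers in X's columns
    effect_log2fc : per-feature true effect
    """
    cfg = DEFAULT_SCENARIO
    n = n_samples if n_samples is not None else cfg["n_samples"]
    nm = n_markers if n_markers is not None else cfg["n_markers"]
    nn = n_noise_features if n_noise_features is not None else cfg["n_noise_features"]
    cv = cv_within if cv_within is not None else cfg["cv_within"]
    rng = np.random.default_rng(seed)
    p = nm + nn
    effects = np.zeros(p)
    magnitudes = rng.uniform(cfg["marker_log2fc_min"], cfg["marker_log2fc_max"], size=nm)
    signs = np.where(np.arange(nm) % 2 == 0, 1.0, -1.0)
    marker_idx = rng.choice(p, size=nm, replace=False)
    effects[marker_idx] = signs * magnitudes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=p)  # spread of abundances
    X, y = generate_scores(
        n,
        p,
        cfg["class_fractions"],
        effects,
        cv,
        seed=int(rng.integers(0, 2**31 - 1)),
        base_level=base,
    )
    return X, y, np.sort(marker_idx), effects
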