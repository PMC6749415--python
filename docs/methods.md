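# Methods

This note documents the models and procedures implemented in `metabopipe`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

Untargeted GC–EIMS metabolomics of urine produces, per derivatization
channel (TMS and TFA), a three-way array of samples × retention-time scans
× integer m/z bins. The analytical goal is to discriminate prostate
carcinoma (PCa) from benign prostatic hyperplasia (BPH) and to rank the
metabolites driving the discrimination. The pipeline: align chromatograms,
deconvolve co-eluting compounds interval by interval with PARAFAC2,
semiquantify them at a uniform response factor, normalize to urinary
creatinine, and classify with PLS–DA after VIP and genetic-algorithm
variable selection, validated by repeated double cross-validation.

## Correlation optimized warping

COW divides the reference (target) trace into segments of nominal length
`segment_len` (default 40 scans) and optimizes, by dynamic programming,
the placement of the corresponding boundaries on the sample trace, each
segment's sample-side length free to deviate from nominal by at most
`slack` points (default 5). The benefit is the summed per-segment Pearson
correlation after linear interpolation of each sample segment onto the
target segment length.

Numerical choices:

- **Degenerate segments.** A constant segment's correlation is defined as
  0. The same value is assigned when a segment's standard deviation falls
  below `min_std_frac` (default 0.05) of the whole trace's: a signal-free
  stretch fluctuates only with detector noise, and its noise correlation
  would otherwise steer the path randomly.
- **Ties.** Candidate boundary placements are examined in order of
  increasing deviation from nominal with strictly-improving updates, so
  among equal-benefit paths the least-warping one wins. Uninformative
  regions therefore stay on the nominal grid.
- **Mass preservation.** The warped signal is scaled per segment by the
  source/target length ratio (the Jacobian of the piecewise-linear time
  map). Integrated peak area is then invariant under stretching, and the
  per-sample total intensity changes by well under 1 %.
- **Reference.** The sample whose TIC has the highest *median* correlation
  to all other samples' TICs (a robust "most typical sample" rule). The
  warp is computed on the TIC and the identical time map applied to every
  m/z channel, preserving within-scan spectral integrity.
- **Iteration.** Alignment rounds repeat until the mean TIC correlation to
  the reference improves by less than 0.001 (a quantitative surrogate for
  the visual inspection an operator would perform), with two guards: a
  round is only committed if it improves the mean, and an individual
  sample's warp is only committed if it improves that sample's own
  correlation.
- **m/z-axis warping** is available (the same 1-D algorithm applied to
  mean spectra) but off by default: integer-binned EI mass axes are
  nominally exact and we make no claim that warping them is useful.
- Baseline subtraction (asymmetric least squares, or a per-trace linear
  fit) is provided for visualization only and is off in the modeling path;
  the deconvolution model absorbs baseline into its own components.

## PARAFAC2 deconvolution

For an RT interval containing a handful of co-eluting compounds, the model
per sample k is

    X_k ≈ B_k diag(d_k) Cᵀ,   B_k = P_k F,   P_kᵀP_k = I,

with shared non-negative spectra `C` (columns unit-norm), non-negative
sample scores `d_k` (the relative concentrations) and per-sample elution
profiles `B_k` constrained to a constant cross-product `B_kᵀB_k = FᵀF` —
the structure that tolerates residual retention shifts.

Fitting is the classic direct-fit alternating least squares: `P_k` by
orthogonal Procrustes (SVD of `X_k C diag(d_k) Fᵀ`), then one CP-ALS sweep
on the projected slabs `Y_k = P_kᵀX_k`, with non-negative least squares
for `C` and `d_k` and an unconstrained solve for `F`. Every update is an
exact conditional minimizer, so the squared error is non-increasing at
every iteration (asserted in the tests to a relative tolerance of 1e−9).
Non-negativity is imposed on spectra and scores but **not** on `B_k`: the
direct-fit algorithm cannot constrain the profiles, and negative
excursions are surfaced as a diagnostic instead.

- **Convergence:** relative SSE change < 1e−8, cap 10,000 iterations
  (the conventional cap for this model family); hitting the cap returns a
  model flagged `converged=False` rather than raising.
- **Initialization:** start 0 from the eigenvectors of Σ X_kᵀX_k (absolute
  values), remaining starts random; 3 starts by default, best final SSE
  kept, all randomness seeded. Multi-start matters: on occasional
  instances the SVD start leads the ALS into a merged-components local
  optimum that a random restart escapes.
- **Interval definition** is operator-driven in practice; the pipeline
  accepts a CSV of (channel, start_scan, stop_scan, R_hint) and also
  offers a heuristic proposal (TIC peak picking with valley splitting) for
  unattended runs.
- **Component count:** `select_rank` fits R = 1..R_max and recommends the
  smallest R whose marginal fit gain drops below 1 percentage point. An
  interval still below 50 % fit at R_max is treated as structureless
  (recommend 1, flag raised) so components are not spent on noise-only
  ranges.

### Component triage and semiquantification

Each fitted component is labeled baseline, noise, or compound by
deterministic rules with configurable thresholds and a manual-override
file honored: near-flat mean elution profile (coefficient of variation
< 0.35) holding a nonzero offset across the interval (min/max > 0.5) →
baseline; normalized spectral entropy > 0.85 together with a non-unimodal
profile → noise; otherwise compound. Only compounds enter the feature
table. A compound's per-sample value is its score multiplied by the norms
of its unit-normalized spectrum and mean elution profile, making the value
TIC-like at a uniform response factor of 1 (no external calibration — the
values are comparable across samples, not across compounds). Rows are
divided by urinary creatinine. Compounds from overlapping intervals with
nearby apexes are both kept and flagged for manual merging.

Spectral identification against commercial libraries is out of scope; the
package exports MSP and provides a NIST-style match factor
(cosine-squared weighted dot product on square-root intensities over
integer bins, scaled to 0–999) against any user-supplied library.

## Classification

The semiquantitative table is log10-transformed (pseudo-count: half the
smallest positive value per column, so zeros stay finite without
distorting the occupied range) and autoscaled (sample sd, ddof = 1).
PLS1-DA is fit by NIPALS with single-Y deflation — chosen so the weights
W, scores T, loadings P and Y-loadings q exist exactly as the VIP and
selectivity-ratio formulas require. Y is coded BPH = 0 / PCa = 1 and a
sample is called positive at ŷ ≥ 0.5 (a tie at exactly 0.5 goes to the
positive class).

- **VIP:** VIPⱼ = √(p Σₐ (wⱼₐ/‖wₐ‖)² SSYₐ / Σₐ SSYₐ); the squared scores
  sum to p, making 1 the indifference point, and selection is strictly
  VIP > 1. The VIP model is fitted on all variables with the component
  count chosen by simple stratified CV beforehand.
- **GA:** one cycle of a binary-chromosome genetic algorithm (population
  64, 100 generations, tournament selection, single-point crossover at
  rate 0.8, bit-flip mutation at rate 0.01, elitism). Fitness is
  stratified 5-fold CV misclassification with the component count picked
  inside the same CV; RMSECV is added at weight 1e−3 as a tie-breaker —
  small enough that one misclassified sample always dominates, but it
  resolves the heavy ties a well-separated dataset produces toward
  better-calibrated subsets instead of leaving the choice to drift.
  A fitness cache keyed on the chromosome makes the run cheap. The full
  trace (per-generation best fitness, seed, final population) is recorded
  so a selection can be replayed.
- **Repeated double CV:** stratified 5 outer × 5 inner folds, 30
  repetitions by default. The inner loop picks the number of latent
  variables (grid 1–10 capped by rank) by minimum inner misclassification;
  the outer model predicts its held-out fold; every sample is predicted
  exactly once per repetition. Sensitivity, specificity (at the 0.5 rule)
  and trapezoidal AUC are computed per repetition and reported as
  mean ± sd. All fold draws derive from one seed.
- **Selectivity ratio:** on the target-projected component
  t = Xb/‖b‖, SRⱼ = ‖t pⱼ‖²/‖xⱼ − t pⱼ‖², with reporting tiers at 0.1 and
  0.07; a variable with zero residual is clamped to 1e12.
- **Ablation:** variables are removed one set at a time and the identical
  CV protocol (same seed, same fold draws) rerun; deltas are judged
  against the reference's between-repetition sd.
- **Batch check:** PCA on the autoscaled table with per-PC one-way ANOVA
  against the batch (analysis day) factor; the run passes if no leading PC
  associates with batch at α = 0.01.
- No multiple-testing correction is applied anywhere; distributions are
  displayed raw (boxplots) and the selection is validated by held-out
  classification, not by per-variable inference.
- "Over/under/comparable" expression calls use the sign of the class-mean
  difference of the autoscaled log values, with an equivalence band of
  0.1 sd below which a variable is called comparable.

## Synthetic data

The generator is the test bed: it produces cubes with known spectra,
elution profiles, scores, shifts and class effects so every stage can be
scored by parameter recovery.

- **Spectra:** sparse non-negative unit-norm columns (log-normal peak
  heights), rejection-sampled until all pairwise congruences are below
  0.9 so components are identifiable.
- **Elution:** Gaussians with widths 2–5 scans placed in the interior of
  the RT window (edge margin 20 % of the axis plus the maximum shift,
  mimicking the peak-free dead time and tail of real runs). Two modes:
  `exact_parafac2` applies per-sample circular shifts — orthonormal
  permutations, so the profile Gram matrix is constant to machine
  precision and the model assumption holds exactly; `shifted_gaussian`
  re-evaluates the Gaussians at shifted centers, which mildly violates
  the model and leaves genuine misalignment for COW.
- **Scores:** log-normal within class (CV 30 % by default), class-1 mean
  scaled by 2^log2FC per component; class sizes realized exactly
  (43 + 48 at the default cohort size of 91).
- **Nuisance:** column-bleed-like baseline (rising low-order polynomial in
  RT times a smooth decaying m/z envelope) and additive Gaussian noise
  clipped at zero, optionally heteroscedastic (sd ∝ √signal); noise can be
  set by target SNR in dB.
- **Creatinine** is drawn log-normal (median 10, σ_log 0.4) — a modeling
  convenience for exercising the normalization, not a claim about real
  urine.
- The default feature-level scenario for the classification stages: 91
  samples (43/48), 20 marker compounds with |log2FC| ∈ [1, 2] and
  alternating sign among 150 features with no class effect.
- Default desk-scale cube 40 × 300 × 80 with ~12 components; the
  full-cohort shapes (91 × 3099 × 612) are supported but not the default,
  keeping routine runs in minutes. Factor-recovery experiments use
  30 × 80 × 60 with R = 3 at 20 dB SNR over 10 seeds; the null behavior
  of the validated classifier is estimated on permutation-destroyed labels
  averaged over several independent permutation draws (a single fixed
  permutation retains idiosyncratic structure of order 1/√n).

What passing these tests shows — and does not. The generator realizes the
data *structure* (trilinear-with-shifts signal, sparse EI-like spectra,
log-normal concentrations, baseline, noise) but not derivatization
chemistry, isotope patterns, tailing peak shapes (EMG is available but
off), retention drift that varies along the run, or missing compounds.
Recovery and classification results on it validate the algorithms and
their implementation, not field performance on any particular instrument.

## Known limitations

- Elution non-negativity is not enforced (inherent to direct-fit
  PARAFAC2); strongly overlapped peaks can produce profiles with small
  negative lobes.
- The component triage is a heuristic stand-in for an operator; thresholds
  are exposed and an override file is honored, but unusual components
  (e.g., structured bleed) can be mislabeled.
- Cross-channel compounds are concatenated, never deduplicated.
- ALS can require thousands of iterations near convergence on noiseless
  data (swamps); the 10,000-iteration cap with multi-start has been
  sufficient in all tested conditions.
- The m/z-width discrepancy between channels observed in real exports
  (612 vs 652 bins for one stated acquisition range) is recorded as-is by
  the reader; the binning convention here is inclusive [40, 650] → 611
  unit bins.
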