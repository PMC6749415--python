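"""Variable selection: VIP filtering and genetic-algorithm refinement.

The selection proceeds in two passes, mirroring common chemometrics
practice on semiquantitative metabolite tables: first variables with
variable importance in projection (VIP) strictly above 1 are kept — the
VIP norm identity (the squared scores sum to the variable count) makes 1
the indifference point — then one cycle of a genetic algorithm over binary
inclusion chromosomes, with cross-validated PLS-DA misclassification as
the fitness, discards variables that do not help held-out classification.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import PlsDaModel, SelectionResult
from .plsda import fit_plsda
from .validation import cv_misclassification

__all__ = ["vip_scores", "vip_select", "ga_select"]


def vip_scores(model: PlsDaModel) -> np.ndarray:
    """Variable importance in projection for every variable.

    ``VIP_j = sqrt( p * sum_a (w_ja / ||w_a||)^2 * SSY_a / sum_a SSY_a )``
    where SSY_a is the Y sum of squares explained by component a. The
    squared scores sum exactly to p.
    """
    ssy = model.ssy
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    W = model.weights  # columns unit-norm from NIPALS
    wn = np.linalg.norm(W, axis=0)
    frac = (W / wn[None, :]) ** 2 @ (ssy / total)
    p = W.shape[0]
    return np.sqrt(p * frac)


def vip_select(
    X: np.ndarray,
    y: np.ndarray,
    A: int | None = None,
    threshold: float = 1.0,
    inner_k: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Keep variables with VIP strictly above ``threshold``.

    The VIP model is fitted to all variables with the number of components
    chosen by simple stratified CV (unless ``A`` is given). If nothing
    exceeds the threshold, the single highest-VIP variable is kept so the
    downstream model stays defined.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if A is None:
        cap = min(10, X.shape[1], X.shape[0] - 1)
        _, A = cv_misclassification(X, y, list(range(1, cap + 1)), k=inner_k, seed=seed)
    model = fit_plsda(X, y, A, scale=True)
    scores = vip_scores(model)
    selected = np.nonzero(scores > threshold)[0]
    if selected.size == 0:
        selected = np.array([int(np.argmax(scores))])
    return SelectionResult(
        selected=selected,
        method="vip",
        trace={"vip": scores, "A": model.n_components, "threshold": threshold},
    )


#: weight of the RMSECV tie-breaker in the default GA fitness; small enough
#: that one misclassified sample (1/n) always dominates it for n < 1000.
RMSECV_TIEBREAK = 1e-3


def _default_fitness(X, y, inner_k, A_max, threshold, seed):
    from .plsda import classify
    from .validation import cv_predictions

    def fitness(mask: np.ndarray) -> float:
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            return 2.0  # worse than any real chromosome
        a_cap = min(A_max, int(idx.size), X.shape[0] - 1)
        preds = cv_predictions(X[:, idx], y, a_cap, inner_k, seed)
        errs = np.mean(classify(preds, threshold) != y[:, None], axis=0)
        rmse = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
        # misclassification is the criterion; RMSECV breaks the heavy ties a
        # well-separated dataset produces, favouring better-calibrated subsets
        cost = errs + RMSECV_TIEBREAK * rmse
        return float(cost.min())

    return fitness


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    fitness=None,
    pop_size: int = 64,
    n_generations: int = 100,
    crossover_rate: float = 0.8,
    mutation_rate: float = 0.01,
    seed: int = 0,
    inner_k: int = 5,
    A_max: int = 10,
    threshold: float = 0.5,
    init_include_prob: float = 0.5,
    init_population: np.ndarray | None = None,
) -> SelectionResult:
    """One cycle of a binary-chromosome GA minimizing CV misclassification.

    Tournament selection, single-point crossover, bit-flip mutation, and
    elitism (the best individual survives unchanged), run for the full
    generation budget. ``fitness`` maps a boolean inclusion mask to a
    cost to minimize; the default is stratified ``inner_k``-fold PLS-DA
    misclassification with the component count picked by the same CV. The
    full trace (per-generation best fitness, seed, final population) is
    recorded so the selection can be replayed.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("GA needs at least 2 candidate variables")
    if fitness is None:
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present in y")
        fitness = _default_fitness(X, np.asarray(y, float), inner_k, A_max, threshold, seed)

    rng = np.random.default_rng(seed)
    if init_population is not None:
        pop = np.asarray(init_population, dtype=bool).copy()
        pop_size = pop.shape[0]
    else:
        pop = rng.random((pop_size, p)) < init_include_prob
        pop[pop.sum(axis=1) == 0, 0] = True  # no empty chromosomes at start

    cache: dict[bytes, float] = {}

    def evaluate(chrom: np.ndarray) -> float:
        key = np.packbits(chrom).tobytes()
        if key not in cache:
            cache[key] = float(fitness(chrom))
        return cache[key]

    fits = np.array([evaluate(c) for c in pop])
    best_idx = int(np.argmin(fits))
    best_chrom, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    history = [best_fit]

    for _ in range(n_generations):
        new_pop = [best_chrom.copy()]  # elitism
        while len(new_pop) < pop_size:
            # tournament selection, size 2
            i, j = rng.integers(pop_size, size=2)
            pa = pop[i] if fits[i] <= fits[j] else pop[j]
            i, j = rng.integers(pop_size, size=2)
            pb = pop[i] if fits[i] <= fits[j] else pop[j]
            ca, cb = pa.copy(), pb.copy()
            if rng.random() < crossover_rate:
                cut = int(rng.integers(1, p))
                ca = np.concatenate([pa[:cut], pb[cut:]])
                cb = np.concatenate([pb[:cut], pa[cut:]])
            for child in (ca, cb):
                if len(new_pop) >= pop_size:
                    break
                if mutation_rate > 0:
                    flips = rng.random(p) < mutation_rate
                    child = child ^ flips
                new_pop.append(child)
        pop = np.array(new_pop[:pop_size])
        fits = np.array([evaluate(c) for c in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = pop[gen_best].copy()
        history.append(best_fit)

    return SelectionResult(
        selected=np.nonzero(best_chrom)[0],
        method="ga",
        trace={
            "best_fitness_per_generation": np.asarray(history),
            "seed": seed,
            "pop_size": pop_size,
            "n_generations": n_generations,
            "crossover_rate": crossover_rate,
            "mutation_rate": mutation_rate,
            "n_evaluations": len(cache),
            "final_population": pop,
        },
    )
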