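"""Feature selection: information-gain filter, binary metaheuristic wrappers
(tunicate swarm, Aquila optimizer) and comparison baselines.

All wrapper selectors minimize the same fitness

    fitness = k1 * error + k2 * FSR

where ``error`` is the internally cross-validated 10-nearest-neighbour
misclassification rate on the candidate subset and FSR is the fraction of
features retained. Continuous swarm dynamics are binarized with a V-shaped
transfer function: a position bit is complemented when a uniform draw falls
below the transfer value of the continuous update, else retained.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import chi2_contingency, pearsonr
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureTable, SelectionMask

__all__ = [
    "FitnessEvaluator", "fitness", "vshape_transfer", "information_gain",
    "btsa_select", "aoa_select", "baseline_select", "levy_sigma",
]


# ---------------------------------------------------------------------------
# transfer function


def vshape_transfer(t: np.ndarray | float) -> np.ndarray | float:
    """V-shaped transfer ``(2/pi) * arctan((pi/2) |t|)``: 0 at 0, limit 1."""
    return (2.0 / np.pi) * np.arctan((np.pi / 2.0) * np.abs(t))


# ---------------------------------------------------------------------------
# wrapper fitness


def _knn_cv_error(
    X: np.ndarray, y: np.ndarray, folds: list[tuple[np.ndarray, np.ndarray]], k: int
) -> float:
    """Mean misclassification of a k-NN majority vote under fixed CV folds.

    Vectorized (distance matrix + argpartition); ties in the vote go to the
    lower class index.
    """
    errors = 0
    total = 0
    for train, test in folds:
        kk = min(k, len(train))
        d = cdist(X[test], X[train])
        nn = np.argpartition(d, kk - 1, axis=1)[:, :kk]
        votes = y[train][nn].sum(axis=1)
        pred = (2 * votes > kk).astype(int)
        errors += int(np.sum(pred != y[test]))
        total += len(test)
    return errors / total


@dataclass
class FitnessEvaluator:
    """Eq-style wrapper fitness: ``k1 * error + k2 * FSR``.

    The error term is the stratified internal-CV misclassification rate of a
    10-nearest-neighbour classifier on the masked table; evaluations are
    cached per mask. ``bind`` fixes the table (training data only) and the
    internal fold assignment.
    """

    k1: float = 0.99
    k2: float = 0.01
    knn_k: int = 10
    internal_folds: int = 3
    seed: int = 0
    _table: FeatureTable | None = field(default=None, repr=False)
    _folds: list | None = field(default=None, repr=False)
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.k1 <= 1 and 0 <= self.k2 <= 1):
            raise ValueError("k1 and k2 must lie in [0, 1]")

    def bind(self, table: FeatureTable) -> "FitnessEvaluator":
        self._table = table
        skf = StratifiedKFold(
            n_splits=self.internal_folds, shuffle=True, random_state=self.seed
        )
        self._folds = list(skf.split(table.values, table.labels))
        self._cache = {}
        return self

    def error(self, mask: np.ndarray) -> float:
        assert self._table is not None, "bind() a table first"
        mask = np.asarray(mask, dtype=bool)
        return _knn_cv_error(
            self._table.values[:, mask], self._table.labels, self._folds, self.knn_k
        )

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise ValueError("mask selects no features; repair before evaluation")
        key = mask.tobytes()
        if key not in self._cache:
            fsr = mask.sum() / mask.size
            self._cache[key] = self.k1 * self.error(mask) + self.k2 * fsr
        return self._cache[key]


def fitness(mask: np.ndarray, evaluator: FitnessEvaluator, table: FeatureTable) -> float:
    """Functional form: binds ``table`` if needed and evaluates the mask."""
    if evaluator._table is not table:
        evaluator.bind(table)
    return evaluator(mask)


# ---------------------------------------------------------------------------
# information gain filter


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def information_gain(
    table: FeatureTable, bins: int = 10, evaluator: FitnessEvaluator | None = None
) -> tuple[np.ndarray, SelectionMask]:
    """Per-feature information gain and the above-mean-IG mask.

    Features are discretized into equal-frequency bins; IG(F) = H(P) - H(P|F)
    with base-2 logs. Returns the score vector and a mask keeping features
    whose IG exceeds the mean IG (falling back to the single best feature if
    that set is empty).
    """
    y = table.labels
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("information gain needs at least two classes")
    h_p = _entropy(class_counts)
    n = table.n_samples
    scores = np.zeros(table.n_features)
    for j in range(table.n_features):
        col = table.values[:, j]
        edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
        binned = np.digitize(col, edges)
        h_cond = 0.0
        for b in np.unique(binned):
            sel = binned == b
            _, cc = np.unique(y[sel], return_counts=True)
            h_cond += sel.sum() / n * _entropy(cc)
        scores[j] = h_p - h_cond
    mask = scores > scores.mean()
    if not mask.any():
        mask[int(np.argmax(scores))] = True
    fsr = mask.sum() / mask.size
    fit = fitness(mask, evaluator, table) if evaluator is not None else 0.0
    return scores, SelectionMask(
        mask, fsr, fit, selector={"name": "ig", "bins": bins}
    )


# ---------------------------------------------------------------------------
# shared wrapper machinery


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Activate one uniformly random bit in any empty row."""
    empty = ~bits.any(axis=1)
    for i in np.where(empty)[0]:
        bits[i, rng.integers(bits.shape[1])] = True
    return bits


def _binarize_flip(
    bits: np.ndarray, continuous: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Flip rule: complement a bit where rand < TF(continuous update)."""
    flip = rng.random(bits.shape) < vshape_transfer(continuous)
    return np.where(flip, ~bits, bits)


@dataclass
class WrapperResult:
    best: SelectionMask
    trace: np.ndarray  # best-so-far fitness per generation


def _evaluate_population(
    bits: np.ndarray, evaluator: FitnessEvaluator
) -> np.ndarray:
    return np.array([evaluator(row) for row in bits])


# ---------------------------------------------------------------------------
# binary tunicate swarm


def btsa_select(
    table: FeatureTable,
    evaluator: FitnessEvaluator | None = None,
    pop: int = 100,
    generations: int = 1000,
    seed: int = 0,
    w_min: float = 1.0,
    w_max: float = 20.0,
) -> tuple[SelectionMask, np.ndarray]:
    """Binary tunicate swarm feature selection.

    Jet-propulsion dynamics: gravity/water-flow force ``T = G / S`` with
    ``G = k1 + k2 - W``, ``W = 2 k3``, social force
    ``S = w_min + k3 (w_max - w_min)``; distance to the best tunicate
    ``D = |B_best - r1 B|``; a move toward/away from the best depending on a
    coin flip, then the averaging update ``(B + B_best) / (2 + k1)``. The
    continuous update is binarized with the V-shaped flip rule. Elitist: the
    best mask ever seen is returned, so the trace is non-increasing.
    """
    if pop < 2:
        raise ValueError("pop must be >= 2")
    evaluator = (evaluator or FitnessEvaluator()).bind(table)
    rng = np.random.default_rng(seed)
    d = table.n_features

    # continuous pre-binarization positions evolve the swarm dynamics;
    # binary masks are what gets evaluated
    cont_pos = rng.random((pop, d))
    bits = cont_pos >= 0.5
    bits = _repair(bits, rng)
    fits = _evaluate_population(bits, evaluator)
    ibest = int(np.argmin(fits))
    best_bits, best_fit = bits[ibest].copy(), float(fits[ibest])
    best_cont = cont_pos[ibest].copy()

    trace = np.empty(generations)
    for g in range(generations):
        k1 = rng.random((pop, d))
        k2 = rng.random((pop, d))
        k3 = rng.random((pop, d))
        r1 = rng.random((pop, d))
        W = 2.0 * k3
        G = k1 + k2 - W
        S = w_min + k3 * (w_max - w_min)
        T = G / S
        D = np.abs(best_cont - r1 * cont_pos)
        coin = rng.random((pop, 1)) >= 0.5
        moved = np.where(coin, best_cont + T * D, best_cont - T * D)
        cont_pos = np.clip((moved + best_cont) / (2.0 + k1), 0.0, 1.0)
        bits = _repair(_binarize_flip(bits, cont_pos, rng), rng)
        fits = _evaluate_population(bits, evaluator)
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_bits = bits[gen_best].copy()
            best_cont = cont_pos[gen_best].copy()
        trace[g] = best_fit

    mask = SelectionMask(
        best_bits, best_bits.sum() / d, best_fit,
        selector={"name": "btsa", "pop": pop, "generations": generations,
                  "seed": seed, "w_min": w_min, "w_max": w_max},
    )
    return mask, trace


# ---------------------------------------------------------------------------
# binary Aquila optimizer


def levy_sigma(alpha: float = 0.5) -> float:
    """Scale of the Levy step: Gamma/sine expression evaluated at ``alpha``."""
    num = math.gamma(1 + alpha) * math.sin(math.pi * alpha / 2.0)
    den = math.gamma((1 + alpha) / 2.0) * alpha * 2.0 ** ((alpha - 1) / 2.0)
    return num / den


def _levy(rng: np.random.Generator, shape: tuple, c: float = 0.1, alpha: float = 0.5) -> np.ndarray:
    sigma = levy_sigma(alpha)
    mu = rng.random(shape)
    v = rng.random(shape)
    return c * mu * sigma / np.maximum(v, 1e-12) ** (1.0 / alpha)


def aoa_select(
    table: FeatureTable,
    evaluator: FitnessEvaluator | None = None,
    pop: int = 100,
    generations: int = 1000,
    seed: int = 0,
    lam: float = 0.5,
    sig: float = 0.5,
    w: float = 0.01,
) -> tuple[SelectionMask, np.ndarray]:
    """Binary Aquila-optimizer feature selection.

    Four hunting strategies: high-soar search around the population mean and
    contour flight with Levy steps and a log-spiral during the first two
    thirds of the iterations (expanded / focused exploration), then low-flight
    descent (``lam``/``sig`` fixed at 0.5) and a quality-factor-stabilized
    dive afterwards. Within each phase the pair is chosen with probability
    1/2 per agent. Continuous updates are binarized with the V-shaped flip
    rule; the returned mask is the elitist best.
    """
    if pop < 2:
        raise ValueError("pop must be >= 2")
    evaluator = (evaluator or FitnessEvaluator()).bind(table)
    rng = np.random.default_rng(seed)
    d = table.n_features
    LB, UB = 0.0, 1.0
    D1 = (np.arange(d) % 10) + 1  # integer spiral parameter, cycling 1..10
    theta = -w * D1 + 3.0 * np.pi / 2.0
    U_spiral = 0.00565

    cont_pos = rng.random((pop, d))
    bits = cont_pos >= 0.5
    bits = _repair(bits, rng)
    fits = _evaluate_population(bits, evaluator)
    ibest = int(np.argmin(fits))
    best_bits, best_fit = bits[ibest].copy(), float(fits[ibest])
    best_cont = cont_pos[ibest].copy()

    trace = np.empty(generations)
    for t in range(1, generations + 1):
        ymean = cont_pos.mean(axis=0)
        explore = t <= (2.0 / 3.0) * generations
        new_pos = np.empty_like(cont_pos)
        for i in range(pop):
            r = rng.random(d)
            if explore:
                if rng.random() < 0.5:
                    new_pos[i] = best_cont * (1 - t / generations) + (
                        ymean - best_cont * r
                    )
                else:
                    r1 = rng.uniform(1.0, 10.0)
                    rr = r1 * U_spiral * D1
                    z = rr * np.cos(theta)
                    y_sp = rr * np.sin(theta)
                    yr = cont_pos[rng.integers(pop)]
                    new_pos[i] = best_cont * _levy(rng, (d,)) + yr + (z - y_sp) * r
            else:
                if rng.random() < 0.5:
                    new_pos[i] = lam * (best_cont - ymean) + sig * (
                        (UB - LB) * r + LB
                    )
                else:
                    g1 = 2.0 * rng.random(d) - 1.0
                    g2 = 2.0 * (1.0 - t / generations)
                    qf = t ** ((2.0 * rng.random() - 1.0) / (1.0 - generations) ** 2)
                    new_pos[i] = (
                        qf * best_cont - g1 * cont_pos[i] * r
                        - g2 * _levy(rng, (d,)) + r * g1
                    )
        cont_pos = np.clip(new_pos, LB, UB)
        bits = _repair(_binarize_flip(bits, cont_pos, rng), rng)
        fits = _evaluate_population(bits, evaluator)
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_bits = bits[gen_best].copy()
            best_cont = cont_pos[gen_best].copy()
        trace[t - 1] = best_fit

    mask = SelectionMask(
        best_bits, best_bits.sum() / d, best_fit,
        selector={"name": "aoa", "pop": pop, "generations": generations, "seed": seed},
    )
    return mask, trace


# ---------------------------------------------------------------------------
# baselines


def _bpso(
    table: FeatureTable, evaluator: FitnessEvaluator, pop: int, generations: int,
    seed: int,
) -> tuple[SelectionMask, np.ndarray]:
    """Standard binary PSO with the V-shaped transfer flip rule."""
    rng = np.random.default_rng(seed)
    d = table.n_features
    c1 = c2 = 2.0
    bits = rng.random((pop, d)) < 0.5
    bits = _repair(bits, rng)
    vel = rng.uniform(-1, 1, (pop, d))
    fits = _evaluate_population(bits, evaluator)
    pbest_bits, pbest_fits = bits.copy(), fits.copy()
    ibest = int(np.argmin(fits))
    best_bits, best_fit = bits[ibest].copy(), float(fits[ibest])

    trace = np.empty(generations)
    for t in range(generations):
        inertia = 0.9 - 0.5 * t / max(1, generations - 1)
        r1 = rng.random((pop, d))
        r2 = rng.random((pop, d))
        vel = (
            inertia * vel
            + c1 * r1 * (pbest_bits.astype(float) - bits.astype(float))
            + c2 * r2 * (best_bits.astype(float) - bits.astype(float))
        )
        bits = _repair(_binarize_flip(bits, vel, rng), rng)
        fits = _evaluate_population(bits, evaluator)
        improved = fits < pbest_fits
        pbest_bits[improved] = bits[improved]
        pbest_fits[improved] = fits[improved]
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_bits = bits[gen_best].copy()
        trace[t] = best_fit
    return (
        SelectionMask(best_bits, best_bits.sum() / d, best_fit,
                      selector={"name": "bpso", "pop": pop,
                                "generations": generations, "seed": seed}),
        trace,
    )


def _baco(
    table: FeatureTable, evaluator: FitnessEvaluator, pop: int, generations: int,
    seed: int, rho: float = 0.2,
) -> tuple[SelectionMask, np.ndarray]:
    """Binary ant colony: per-feature pheromone = inclusion probability."""
    rng = np.random.default_rng(seed)
    d = table.n_features
    tau = np.full(d, 0.5)
    best_bits, best_fit = None, np.inf
    trace = np.empty(generations)
    for t in range(generations):
        bits = _repair(rng.random((pop, d)) < tau, rng)
        fits = _evaluate_population(bits, evaluator)
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_bits = bits[gen_best].copy()
        tau = np.clip((1 - rho) * tau + rho * best_bits.astype(float), 0.05, 0.95)
        trace[t] = best_fit
    return (
        SelectionMask(best_bits, best_bits.sum() / d, best_fit,
                      selector={"name": "baco", "pop": pop,
                                "generations": generations, "seed": seed}),
        trace,
    )


def baseline_select(
    table: FeatureTable,
    method: str,
    evaluator: FitnessEvaluator | None = None,
    pop: int = 20,
    generations: int = 50,
    seed: int = 0,
    bins: int = 4,
) -> SelectionMask:
    """Comparison selectors: ``chi2``, ``pcc`` filters and ``bpso``/``baco``
    wrappers driven by the same fitness as the swarm selectors."""
    evaluator = (evaluator or FitnessEvaluator()).bind(table)
    if method == "chi2":
        scores = np.zeros(table.n_features)
        y = table.labels
        for j in range(table.n_features):
            col = table.values[:, j]
            edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
            binned = np.digitize(col, edges)
            uniq = np.unique(binned)
            if len(uniq) < 2:
                continue  # constant feature: no association
            cont = np.array(
                [[np.sum((binned == b) & (y == c)) for c in (0, 1)] for b in uniq]
            )
            cont = cont[cont.sum(axis=1) > 0]
            if cont.shape[0] >= 2 and (cont.sum(axis=0) > 0).all():
                scores[j] = chi2_contingency(cont, correction=False)[0]
        mask = scores > scores.mean()
        if not mask.any():
            mask[int(np.argmax(scores))] = True
        return SelectionMask(mask, mask.sum() / mask.size, evaluator(mask),
                             selector={"name": "chi2", "bins": bins, "scores": scores})
    if method == "pcc":
        y = table.labels.astype(float)
        scores = np.zeros(table.n_features)
        for j in range(table.n_features):
            col = table.values[:, j]
            if col.std() == 0 or y.std() == 0:
                continue
            scores[j] = abs(pearsonr(col, y)[0])
        mask = scores > scores.mean()
        if not mask.any():
            mask[int(np.argmax(scores))] = True
        return SelectionMask(mask, mask.sum() / mask.size, evaluator(mask),
                             selector={"name": "pcc", "scores": scores})
    if method == "bpso":
        return _bpso(table, evaluator, pop, generations, seed)[0]
    if method == "baco":
        return _baco(table, evaluator, pop, generations, seed)[0]
    raise ValueError(f"unknown selection method {method!r}")
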