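"""Hybrid boosted classifiers and baselines.

Implements maximum-uncertainty LDA (MULDA), a generic AdaBoost loop shared
by the AdaBoost-MULDA and AdaBoost-RF hybrids, an AdaBoost.R2-style
regression booster coupled with ARIMA coefficient features, and the
time-weighted AdaBoost-SVM (TW-HASVM), plus the conventional baselines.

Weighted training is realized by weight-proportional resampling of size n;
when the weight vector is exactly uniform the full sample is used unchanged,
so a single boosting round reduces to the plain base learner.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .containers import FeatureTable

logger = logging.getLogger(__name__)

_EPS_ERR = 1e-10


# ---------------------------------------------------------------------------
# MULDA


@dataclass
class MULDAModel:
    """Maximum-uncertainty LDA: within-class spectrum floored at its mean.

    Eigenvalues of the scaled within-class scatter ``M_q = M_w / (n - c)``
    below their mean are raised to the mean (larger ones unchanged), the
    scatter is rebuilt, and the leading ``c - 1`` eigenvectors of
    ``(M_w*)^-1 M_b`` give the discriminant directions.
    """

    discriminants: np.ndarray  # d x (c-1)
    eigenvalues: np.ndarray
    regularized_eigenvalues: np.ndarray
    mean_eigenvalue: float
    class_means: dict[int, np.ndarray]


def regularize_spectrum(eigenvalues: np.ndarray) -> tuple[np.ndarray, float]:
    """Raise sub-mean eigenvalues to the mean; larger ones unchanged."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam_bar = float(lam.mean())
    return np.maximum(lam, lam_bar), lam_bar


def mulda_fit(X: np.ndarray, y: np.ndarray) -> MULDAModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    n, d = X.shape
    c = len(classes)
    if n <= c:
        raise ValueError("need more samples than classes")
    grand_mean = X.mean(axis=0)
    Mw = np.zeros((d, d))
    Mb = np.zeros((d, d))
    class_means = {}
    for cls in classes:
        Xc = X[y == cls]
        mu = Xc.mean(axis=0)
        class_means[int(cls)] = mu
        centered = Xc - mu
        Mw += centered.T @ centered
        diff = (mu - grand_mean)[:, None]
        Mb += len(Xc) * (diff @ diff.T)
    Mq = Mw / (n - c)
    lam, phi = np.linalg.eigh(Mq)
    lam_star, lam_bar = regularize_spectrum(lam)
    Mw_star = (phi * lam_star) @ phi.T * (n - c)
    try:
        A = np.linalg.solve(Mw_star, Mb)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"regularized within-class scatter singular: {exc}")
    evals, evecs = linalg.eig(A)
    order = np.argsort(-evals.real)
    W = evecs[:, order[: c - 1]].real
    return MULDAModel(
        discriminants=W,
        eigenvalues=lam,
        regularized_eigenvalues=lam_star,
        mean_eigenvalue=lam_bar,
        class_means={k: v @ W for k, v in class_means.items()},
    )


class MULDAKNN:
    """MULDA projection followed by a k-nearest-neighbour vote."""

    def __init__(self, knn_k: int = 10):
        self.knn_k = knn_k
        self.model: MULDAModel | None = None
        self._knn: KNeighborsClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MULDAKNN":
        self.model = mulda_fit(X, y)
        proj = X @ self.model.discriminants
        k = min(self.knn_k, len(y))
        self._knn = KNeighborsClassifier(n_neighbors=k).fit(proj, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._knn.predict(X @ self.model.discriminants)


# ---------------------------------------------------------------------------
# generic AdaBoost (Algorithm-1 style)


@dataclass
class BoostEnsemble:
    """Ordered weak learners with voting weights ``alpha_t``."""

    base_models: list = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)
    sample_weights_history: list[np.ndarray] = field(default_factory=list)

    @property
    def rounds(self) -> int:
        return len(self.base_models)

    def decision(self, X: np.ndarray) -> np.ndarray:
        agg = np.zeros(len(X))
        for model, alpha in zip(self.base_models, self.alphas):
            agg += alpha * np.where(model.predict(X) == 1, 1.0, -1.0)
        return agg

    def predict(self, X: np.ndarray) -> np.ndarray:
        # sign vote; ties (score 0) go to the lower class
        return (self.decision(X) > 0).astype(int)


def alpha_from_error(eps: float) -> float:
    """Voting weight ``0.5 * log((1 - eps) / eps)`` with clipped error."""
    eps = float(np.clip(eps, _EPS_ERR, 1.0 - _EPS_ERR))
    return 0.5 * float(np.log((1.0 - eps) / eps))


def _weighted_resample(
    rng: np.random.Generator, weights: np.ndarray
) -> np.ndarray:
    """Size-n resample proportional to weights; identity when uniform."""
    n = len(weights)
    if np.ptp(weights) < 1e-15:
        return np.arange(n)
    return rng.choice(n, size=n, p=weights)


def adaboost_fit(
    X: np.ndarray,
    y: np.ndarray,
    base_factory: Callable[[int], object],
    T: int = 50,
    seed: int = 0,
) -> BoostEnsemble:
    """Discrete AdaBoost with weight-proportional resampling.

    ``base_factory(round_seed)`` must return an unfitted classifier with
    ``fit``/``predict``. Early stop when a round's weighted error hits 0 or
    reaches 0.5 (logged); a first-round learner no better than chance yields
    an ensemble of one with a warning.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    rng = np.random.default_rng(seed)
    D = np.full(n, 1.0 / n)
    ens = BoostEnsemble()
    for t in range(T):
        idx = _weighted_resample(rng, D)
        model = base_factory(seed + t)
        model.fit(X[idx], y[idx])
        pred = model.predict(X)
        miss = pred != y
        eps = float(D[miss].sum())
        if eps >= 0.5:
            if ens.rounds == 0:
                logger.warning("adaboost: weak learner no better than chance "
                               "(eps=%.3f); ensemble of one", eps)
                ens.base_models.append(model)
                ens.alphas.append(alpha_from_error(eps))
                ens.errors.append(eps)
                ens.sample_weights_history.append(D.copy())
            else:
                logger.info("adaboost: early stop at round %d (eps=%.3f)", t + 1, eps)
            break
        alpha = alpha_from_error(eps)
        ens.base_models.append(model)
        ens.alphas.append(alpha)
        ens.errors.append(eps)
        D = D * np.where(miss, np.exp(alpha), np.exp(-alpha))
        D = D / D.sum()
        ens.sample_weights_history.append(D.copy())
        if eps <= _EPS_ERR:
            logger.info("adaboost: perfect round %d, stopping", t + 1)
            break
    return ens


def hybrid_adaboost_mulda(
    table: FeatureTable, T: int = 50, knn_k: int = 10, seed: int = 0
) -> BoostEnsemble:
    """AdaBoost over MULDA-projection + 10-NN weak learners."""
    return adaboost_fit(
        table.values, table.labels, lambda s: MULDAKNN(knn_k=knn_k), T=T, seed=seed
    )


def hybrid_adaboost_rf(
    table: FeatureTable, T: int = 50, n_trees: int = 10, max_depth: int = 3,
    seed: int = 0,
) -> BoostEnsemble:
    """AdaBoost over small depth-limited random forests."""
    return adaboost_fit(
        table.values, table.labels,
        lambda s: RandomForestClassifier(
            n_estimators=n_trees, max_depth=max_depth, random_state=s
        ),
        T=T, seed=seed,
    )


def boosting_error_bound(errors: list[float]) -> float:
    """Classical training-error bound ``prod_t 2 sqrt(eps_t (1 - eps_t))``."""
    return float(np.prod([2.0 * np.sqrt(e * (1.0 - e)) for e in errors]))


# ---------------------------------------------------------------------------
# ARIMA feature stage + AdaBoost.R2-style hybrid


@dataclass
class ARIMASpec:
    """Fitted ARIMA(k, d, l) summary used as a feature vector."""

    orders: tuple[int, int, int]
    ar_coefs: np.ndarray
    ma_coefs: np.ndarray
    residual_variance: float
    mean: float
    stationary: bool

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.ar_coefs, self.ma_coefs, [self.residual_variance, self.mean]]
        )

    @staticmethod
    def feature_names(orders: tuple[int, int, int]) -> list[str]:
        k, _, l = orders
        return (
            [f"arima_ar{i + 1}" for i in range(k)]
            + [f"arima_ma{i + 1}" for i in range(l)]
            + ["arima_sigma2", "arima_mu"]
        )


def arima_features(
    series: np.ndarray,
    orders: tuple[int, int, int] = (2, 1, 2),
    downsample: int = 1,
    adf_alpha: float = 0.05,
) -> ARIMASpec:
    """Fit ARIMA(k, d, l) and return its coefficients as features.

    Stationarity is screened with an augmented Dickey-Fuller test: if the
    unit-root null is rejected at ``adf_alpha`` the differencing order drops
    to 0. A non-convergent fit falls back to a pure AR fit with a warning.
    ``downsample`` decimates the series first (coefficient features only need
    the coarse dynamics).
    """
    from statsmodels.tsa.arima.model import ARIMA
    from statsmodels.tsa.stattools import adfuller

    k, d, l = orders
    if k < 0 or d < 0 or l < 0:
        raise ValueError("orders must be non-negative")
    x = np.asarray(series, dtype=float)
    if downsample > 1:
        x = x[::downsample]
    if len(x) - d < 20:
        raise ValueError("series too short after differencing")
    try:
        pval = adfuller(x, maxlag=min(10, len(x) // 10))[1]
        stationary = bool(pval < adf_alpha)
    except Exception:  # constant series etc.
        stationary = True
    d_eff = 0 if stationary else d
    mu = float(x.mean())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(x, order=(k, d_eff, l)).fit(method="hannan_rissanen")
        ar = np.asarray(res.arparams, dtype=float)
        ma = np.asarray(res.maparams, dtype=float)
        sigma2 = float(res.params[-1]) if "sigma2" in res.param_names else float(
            np.var(res.resid)
        )
    except Exception as exc:
        logger.warning("arima_features: ARIMA fit failed (%s); AR-only fallback", exc)
        from statsmodels.tsa.ar_model import AutoReg

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ar_res = AutoReg(np.diff(x, n=d_eff) if d_eff else x, lags=k).fit()
        ar = np.asarray(ar_res.params[1 : k + 1], dtype=float)
        ma = np.zeros(l)
        sigma2 = float(ar_res.sigma2)
    ar = np.pad(ar, (0, max(0, k - len(ar))))[:k]
    ma = np.pad(ma, (0, max(0, l - len(ma))))[:l]
    return ARIMASpec(
        orders=(k, d, l), ar_coefs=ar, ma_coefs=ma,
        residual_variance=sigma2, mean=mu, stationary=stationary,
    )


@dataclass
class ARIMAAdaBoostModel:
    """AdaBoost.R2-style booster over depth-1 regression trees.

    Trained on selected features augmented with per-segment ARIMA
    coefficients; the weighted-mean regression score thresholded at 0.5
    gives the class.
    """

    trees: list = field(default_factory=list)
    weights: list[float] = field(default_factory=list)

    def decision(self, X: np.ndarray) -> np.ndarray:
        num = np.zeros(len(X))
        for tree, w in zip(self.trees, self.weights):
            num += w * tree.predict(X)
        denom = sum(self.weights)
        return num / denom if denom > 0 else num

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) >= 0.5).astype(int)


def arima_adaboost_fit(
    X: np.ndarray, y: np.ndarray, T: int = 50, seed: int = 0
) -> ARIMAAdaBoostModel:
    """Boosted regression onto 0/1 targets (AdaBoost.R2 weighting).

    Per round: fit a depth-1 regression tree on a weight-proportional
    resample; per-sample absolute error scaled to [0, 1]; aggregate error
    ``eps_t``; stop when ``eps_t >= 0.5``; ``beta_t = eps_t / (1 - eps_t)``
    (clipped away from 0), connection weight ``w_t = 0.5 log(1 / beta_t)``,
    distribution update ``D propto D * beta_t**(1 - e_i)``.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y, dtype=float)
    n = len(y01)
    rng = np.random.default_rng(seed)
    D = np.full(n, 1.0 / n)
    model = ARIMAAdaBoostModel()
    for t in range(T):
        idx = _weighted_resample(rng, D)
        tree = DecisionTreeRegressor(max_depth=1, random_state=seed + t)
        tree.fit(X[idx], y01[idx])
        pred = tree.predict(X)
        abs_err = np.abs(pred - y01)
        max_err = abs_err.max()
        if max_err <= _EPS_ERR:
            # perfect round: single-tree ensemble
            model.trees = [tree]
            model.weights = [1.0]
            logger.info("arima_adaboost: perfect fit at round %d", t + 1)
            break
        e = abs_err / max_err
        eps = float(np.sum(D * e))
        if eps >= 0.5:
            if not model.trees:
                model.trees.append(tree)
                model.weights.append(1.0)
                logger.warning("arima_adaboost: first round eps=%.3f >= 0.5", eps)
            break
        beta = max(eps / (1.0 - eps), _EPS_ERR)
        model.trees.append(tree)
        model.weights.append(0.5 * float(np.log(1.0 / beta)))
        D = D * beta ** (1.0 - e)
        D = D / D.sum()
    if not model.trees:  # T=0 guarded earlier; defensive
        raise RuntimeError("no rounds trained")
    return model


def hybrid_arima_adaboost(
    selected: FeatureTable,
    arima_table: FeatureTable | None = None,
    T: int = 50,
    seed: int = 0,
) -> tuple[ARIMAAdaBoostModel, np.ndarray]:
    """Two-stage hybrid: augment selected features with ARIMA coefficients,
    then boost. Returns the model and the augmented training matrix."""
    if arima_table is not None:
        X = np.hstack([selected.values, arima_table.values])
    else:
        X = selected.values
    return arima_adaboost_fit(X, selected.labels, T=T, seed=seed), X


# ---------------------------------------------------------------------------
# TW-HASVM


def time_weight(t: int | np.ndarray, eta: float) -> np.ndarray:
    """Batch-age decay ``TW(t) = exp(-eta t)``; TW(0) = 1."""
    return np.exp(-eta * np.asarray(t, dtype=float))


@dataclass
class TWHASVMModel:
    """Time-weighted boosted polynomial-kernel SVMs."""

    eta: float
    batch_index: int
    svms: list = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)
    classes: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-class weighted vote; ties go to the lower class index."""
        X = np.asarray(X, dtype=float)
        scores = np.zeros((len(X), len(self.classes)))
        for svm, alpha in zip(self.svms, self.alphas):
            pred = svm.predict(X)
            for ci, cls in enumerate(self.classes):
                scores[:, ci] += alpha * (pred == cls)
        return self.classes[np.argmax(scores, axis=1)]


def tw_hasvm_fit(
    table: FeatureTable,
    eta: float = 0.25,
    batch_index: int | np.ndarray = 1,
    T: int = 20,
    poly_degree: int = 3,
    C: float = 1.0,
    seed: int = 0,
) -> TWHASVMModel:
    """Boosted polynomial-kernel SVMs with exponential batch-age weighting.

    Initial weights ``1/n`` are multiplied by ``TW(batch_index - 1)`` (a
    per-sample vector if ``batch_index`` is an array) and renormalized; each
    round trains an SVM on a weight-proportional resample, computes the
    weighted error, the voting weight ``0.5 log((1 - e)/e)``, and multiplies
    misclassified samples' weights by ``exp(alpha)``. With ``eta = 0`` (or a
    single batch) the scheme reduces to a plain AdaBoost of SVMs.
    """
    if not (0.0 <= eta <= 0.5):
        raise ValueError("eta must lie in [0, 0.5]")
    if T < 1:
        raise ValueError("T must be >= 1")
    X = table.values
    y = table.labels
    n = len(y)
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n) * time_weight(np.asarray(batch_index) - 1, eta)
    w = w / w.sum()
    model = TWHASVMModel(eta=eta, batch_index=int(np.max(batch_index)),
                         classes=np.unique(y))
    for t in range(T):
        w = w / w.sum()
        idx = _weighted_resample(rng, w)
        svm = SVC(kernel="poly", degree=poly_degree, C=C, random_state=seed + t)
        svm.fit(X[idx], y[idx])
        pred = svm.predict(X)
        miss = pred != y
        e = float(np.sum(w * miss) / np.sum(w))
        if e >= 0.5:
            if not model.svms:
                model.svms.append(svm)
                model.alphas.append(alpha_from_error(e))
                model.errors.append(e)
                logger.warning("tw_hasvm: first SVM no better than chance (e=%.3f)", e)
            else:
                logger.info("tw_hasvm: stop at round %d (e=%.3f)", t + 1, e)
            break
        e_clip = max(e, _EPS_ERR)
        alpha = 0.5 * float(np.log((1.0 - e_clip) / e_clip))
        model.svms.append(svm)
        model.alphas.append(alpha)
        model.errors.append(e)
        w = w * np.exp(alpha * miss)
        if e <= _EPS_ERR:
            logger.info("tw_hasvm: perfect round %d, stopping", t + 1)
            break
    return model


def tw_hasvm_predict(model: TWHASVMModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# baselines


def baseline_classifier(method: str, seed: int = 0, T: int = 50):
    """Conventional comparison classifiers: ``rf``, ``dt``, ``nbc``,
    ``adaboost`` (decision-stump AdaBoost via the in-package loop)."""
    if method == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if method == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if method == "nbc":
        return GaussianNB()
    if method == "adaboost":
        return _StumpAdaBoost(T=T, seed=seed)
    raise ValueError(f"unknown classifier method {method!r}")


class _StumpAdaBoost:
    """Plain AdaBoost with depth-1 decision-tree weak learners."""

    def __init__(self, T: int = 50, seed: int = 0):
        self.T = T
        self.seed = seed
        self.ensemble: BoostEnsemble | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_StumpAdaBoost":
        if len(np.unique(y)) < 2 or len(y) < 2:
            raise ValueError("need at least two samples and two classes")
        self.ensemble = adaboost_fit(
            X, y, lambda s: DecisionTreeClassifier(max_depth=1, random_state=s),
            T=self.T, seed=self.seed,
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.ensemble.predict(X)
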