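"""Cross-validated scoring of extractor x selector x classifier combinations.

Folds are stratified at the subject level: every segment inherits its
subject's fold, so no subject contributes to both a training and a test set
(identity leakage). All data-dependent stages — the standardizer, learned
feature maps (PCA/KPCA/RFM), the feature selector and the classifier — are
fitted on training subjects only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedKFold

from . import classify, extract, select
from .containers import BCGRecord, ConfusionMatrix, FeatureTable, SegmentSet
from .io import apply_standardize, segment_cohort, standardize

logger = logging.getLogger(__name__)

EXTRACTORS = ("kmeans", "modwt", "ewt", "pca", "kpca", "rfm")
SELECTORS = ("none", "ig", "btsa", "aoa", "chi2", "pcc", "bpso", "baco")
CLASSIFIERS = (
    "adaboost_mulda", "adaboost_rf", "arima_adaboost", "tw_hasvm",
    "rf", "dt", "nbc", "adaboost",
)

_LEARNED_EXTRACTORS = {"pca", "kpca", "rfm"}


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent accuracy ``100 (TP + TN) / (TP + TN + FP + FN)``."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


@dataclass
class CVResult:
    """Per-fold confusion matrices and accuracies for one pipeline cell."""

    extractor: str
    selector: str
    classifier: str
    fold_matrices: list[ConfusionMatrix]
    fold_accuracies: list[float]
    seed: int
    fold_assignment: dict[str, int]
    selected_masks: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


# ---------------------------------------------------------------------------
# per-cohort caches (stateless stages shared across folds and grid cells)


class CohortCache:
    """Segment-level tables that do not depend on fold assignment."""

    def __init__(self, records: list[BCGRecord], window_seconds: float = 300.0):
        self.records = records
        self.window_seconds = window_seconds
        self.segments: SegmentSet = segment_cohort(records, window_seconds)
        self._tables: dict[str, FeatureTable] = {}
        self._arima: FeatureTable | None = None

    def base_table(self, extractor: str, params: dict[str, Any], seed: int) -> FeatureTable:
        key = f"{extractor}:{sorted(params.items())}"
        if key not in self._tables:
            if extractor == "kmeans":
                self._tables[key] = extract.kmeans_features(
                    self.segments, seed=seed, **params
                )
            elif extractor == "modwt":
                self._tables[key] = extract.modwt_features(self.segments, **params)
            elif extractor == "ewt":
                self._tables[key] = extract.ewt_features(self.segments, **params)
            elif extractor in _LEARNED_EXTRACTORS:
                self._tables[key] = extract.segment_descriptors(self.segments)
            else:
                raise ValueError(f"unknown extractor {extractor!r}")
        return self._tables[key]

    def arima_table(self, orders=(2, 1, 2), downsample: int = 10) -> FeatureTable:
        if self._arima is None:
            rows = [
                classify.arima_features(seg, orders=orders, downsample=downsample).to_vector()
                for seg in self.segments.segments
            ]
            self._arima = FeatureTable(
                np.asarray(rows),
                classify.ARIMASpec.feature_names(orders),
                self.segments.labels.copy(),
                provenance={"extractor": "arima", "orders": orders,
                            "downsample": downsample},
                subject_ids=list(self.segments.subject_ids),
            )
        return self._arima


# ---------------------------------------------------------------------------
# stage runners


def _fit_extractor(
    name: str, train: FeatureTable, seed: int, params: dict[str, Any]
):
    """Fit a learned feature map on the training table; None for stateless."""
    if name == "pca":
        _, model = extract.pca_or_kpca_features(train, kernel="linear", **params)
        return model
    if name == "kpca":
        kw = {"kernel": "linear", "n_components": 4, **params}
        _, model = extract.pca_or_kpca_features(train, **kw)
        return model
    if name == "rfm":
        _, model = extract.rfm_features(train, seed=seed, **params)
        return model
    return None


def _run_selector(
    name: str, table: FeatureTable, seed: int, params: dict[str, Any]
) -> np.ndarray:
    params = dict(params)
    if name == "none":
        return np.ones(table.n_features, dtype=bool)
    evaluator = select.FitnessEvaluator(seed=seed)
    if name == "ig":
        _, mask = select.information_gain(
            table, bins=params.get("bins", 10), evaluator=evaluator
        )
        return mask.mask
    if name == "btsa":
        mask, _ = select.btsa_select(
            table, evaluator, pop=params.get("pop", 20),
            generations=params.get("generations", 20), seed=seed,
        )
        return mask.mask
    if name == "aoa":
        mask, _ = select.aoa_select(
            table, evaluator, pop=params.get("pop", 20),
            generations=params.get("generations", 20), seed=seed,
        )
        return mask.mask
    if name in ("chi2", "pcc", "bpso", "baco"):
        mask = select.baseline_select(
            table, name, evaluator, pop=params.get("pop", 20),
            generations=params.get("generations", 20), seed=seed,
            bins=params.get("bins", 4),
        )
        return mask.mask
    raise ValueError(f"unknown selector {name!r}")


def _fit_classifier(name: str, table: FeatureTable, seed: int, params: dict[str, Any]):
    params = dict(params)
    T = params.pop("T", 20)
    if name == "adaboost_mulda":
        return classify.hybrid_adaboost_mulda(
            table, T=T, knn_k=params.get("knn_k", 10), seed=seed
        )
    if name == "adaboost_rf":
        return classify.hybrid_adaboost_rf(
            table, T=T, n_trees=params.get("n_trees", 10),
            max_depth=params.get("max_depth", 3), seed=seed,
        )
    if name == "arima_adaboost":
        return classify.arima_adaboost_fit(table.values, table.labels, T=T, seed=seed)
    if name == "tw_hasvm":
        return classify.tw_hasvm_fit(
            table, eta=params.get("eta", 0.25),
            batch_index=params.get("batch_index", 1), T=T,
            poly_degree=params.get("poly_degree", 3), seed=seed,
        )
    if name in ("rf", "dt", "nbc", "adaboost"):
        model = classify.baseline_classifier(name, seed=seed, T=T)
        model.fit(table.values, table.labels)
        return model
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# cross-validation


def _subject_folds(
    records: list[BCGRecord], folds: int, seed: int
) -> dict[str, int]:
    sids = np.array([r.subject_id for r in records])
    labels = np.array([r.label for r in records])
    for cls in np.unique(labels):
        if np.sum(labels == cls) < folds:
            raise ValueError(
                f"need at least {folds} subjects per class for {folds}-fold CV"
            )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold_idx, (_, test_idx) in enumerate(skf.split(sids, labels)):
        for i in test_idx:
            assignment[sids[i]] = fold_idx
    return assignment


def cross_validate(
    records: list[BCGRecord],
    extractor: str = "kpca",
    selector: str = "aoa",
    classifier: str = "arima_adaboost",
    folds: int = 10,
    seed: int = 0,
    window_seconds: float = 300.0,
    extractor_params: dict | None = None,
    selector_params: dict | None = None,
    classifier_params: dict | None = None,
    cache: CohortCache | None = None,
) -> CVResult:
    """Stratified subject-level k-fold evaluation of one pipeline cell.

    Per fold: standardizer, learned feature map, selector and classifier are
    fitted on training subjects only and applied to the held-out subjects'
    segments. Fold assignment is reproducible from ``seed``.
    """
    extractor_params = extractor_params or {}
    selector_params = selector_params or {}
    classifier_params = classifier_params or {}
    if cache is None:
        cache = CohortCache(records, window_seconds)
    base = cache.base_table(extractor, extractor_params, seed)
    arima = cache.arima_table() if classifier == "arima_adaboost" else None

    assignment = _subject_folds(records, folds, seed)
    seg_folds = np.array([assignment[s] for s in cache.segments.subject_ids])

    matrices: list[ConfusionMatrix] = []
    accs: list[float] = []
    masks: list[np.ndarray] = []
    for fold in range(folds):
        test_rows = np.where(seg_folds == fold)[0]
        train_rows = np.where(seg_folds != fold)[0]
        train_base = base.subset_rows(train_rows)
        test_base = base.subset_rows(test_rows)
        if len(np.unique(train_base.labels)) < 2:
            raise ValueError(f"fold {fold}: a class is absent from training data")

        std_train, params = standardize(train_base)
        std_test = apply_standardize(test_base, params)

        model = _fit_extractor(extractor, std_train, seed, extractor_params)
        if model is not None:
            tr = model.transform(std_train)
            te = model.transform(std_test)
            tr, p2 = standardize(tr)
            te = apply_standardize(te, p2)
        else:
            tr, te = std_train, std_test

        mask = _run_selector(selector, tr, seed + fold, selector_params)
        masks.append(mask)
        tr_sel = tr.select(mask)
        te_sel = te.select(mask)

        if arima is not None:
            ar_tr = arima.subset_rows(train_rows)
            ar_te = arima.subset_rows(test_rows)
            ar_tr, p3 = standardize(ar_tr)
            ar_te = apply_standardize(ar_te, p3)
            tr_sel = FeatureTable(
                np.hstack([tr_sel.values, ar_tr.values]),
                tr_sel.feature_names + ar_tr.feature_names,
                tr_sel.labels, dict(tr_sel.provenance), tr_sel.subject_ids,
            )
            te_sel = FeatureTable(
                np.hstack([te_sel.values, ar_te.values]),
                te_sel.feature_names + ar_te.feature_names,
                te_sel.labels, dict(te_sel.provenance), te_sel.subject_ids,
            )

        clf = _fit_classifier(classifier, tr_sel, seed + fold, classifier_params)
        pred = clf.predict(te_sel.values)
        cm = ConfusionMatrix.from_predictions(te_sel.labels, pred)
        matrices.append(cm)
        accs.append(accuracy(cm))

    return CVResult(
        extractor=extractor, selector=selector, classifier=classifier,
        fold_matrices=matrices, fold_accuracies=accs, seed=seed,
        fold_assignment=assignment, selected_masks=masks,
    )


def permuted_label_cv(
    records: list[BCGRecord], seed: int = 0, **kwargs
) -> CVResult:
    """Cross-validate after permuting subject labels (leakage null check)."""
    rng = np.random.default_rng(seed)
    labels = np.array([r.label for r in records])
    permuted = rng.permutation(labels)
    shuffled = [
        BCGRecord(r.subject_id, r.channels, r.fs, int(lbl), dict(r.demographics))
        for r, lbl in zip(records, permuted)
    ]
    return cross_validate(shuffled, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# results grid


def results_grid(
    records: list[BCGRecord],
    extractors: list[str],
    selectors: list[str],
    classifiers: list[str],
    seed: int = 0,
    folds: int = 10,
    window_seconds: float = 300.0,
    **stage_params,
) -> tuple[pd.DataFrame, dict[tuple, CVResult | None]]:
    """Mean CV accuracy for every (extractor, selector, classifier) cell.

    Rows are extractors; columns are (selector, classifier) pairs, mirroring
    the one-table-per-selector presentation. A failing cell is recorded as
    NaN and the run continues.
    """
    cache = CohortCache(records, window_seconds)
    results: dict[tuple, CVResult | None] = {}
    columns = pd.MultiIndex.from_product([selectors, classifiers],
                                         names=["selector", "classifier"])
    grid = pd.DataFrame(index=pd.Index(extractors, name="extractor"),
                        columns=columns, dtype=float)
    for ext in extractors:
        for sel in selectors:
            for clf in classifiers:
                key = (ext, sel, clf)
                try:
                    res = cross_validate(
                        records, extractor=ext, selector=sel, classifier=clf,
                        folds=folds, seed=seed, window_seconds=window_seconds,
                        cache=cache, **stage_params,
                    )
                    results[key] = res
                    grid.loc[ext, (sel, clf)] = res.mean_accuracy
                except Exception as exc:  # cell failure must not kill the run
                    logger.error("grid cell %s failed: %s", key, exc)
                    results[key] = None
    return grid, results


def best_cell(grid: pd.DataFrame) -> tuple[tuple[str, str, str], float]:
    """(extractor, selector, classifier) triple of the best mean accuracy."""
    stacked = grid.stack(list(range(grid.columns.nlevels)), future_stack=True).dropna()
    (ext, sel, clf) = stacked.idxmax()
    return (ext, sel, clf), float(stacked.max())


# ---------------------------------------------------------------------------
# feature statistics battery


def feature_statistics(
    table: FeatureTable, folds: int = 5, seed: int = 0, knn_k: int = 10,
    bh_correction: bool = False,
) -> dict[str, Any]:
    """Descriptive class-separation statistics for a feature table.

    Per feature: Kruskal-Wallis and two-sided Wilcoxon rank-sum between
    classes (constant features skipped with a note); a Friedman test across
    feature columns; and Cohen's kappa between a reference 10-NN classifier's
    cross-validated predictions and the truth. Reported only — never used as
    a filter. Benjamini-Hochberg adjustment is available but off by default.
    """
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("feature statistics need at least two classes")
    per_feature = []
    for j, name in enumerate(table.feature_names):
        col = table.values[:, j]
        if col.std() == 0:
            per_feature.append(
                {"feature": name, "kruskal_stat": np.nan, "kruskal_p": np.nan,
                 "wilcoxon_stat": np.nan, "wilcoxon_p": np.nan,
                 "note": "constant feature; tests skipped"}
            )
            continue
        groups = [col[y == cls] for cls in np.unique(y)]
        ks, kp = stats.kruskal(*groups)
        ws, wp = stats.ranksums(groups[0], groups[1])
        per_feature.append(
            {"feature": name, "kruskal_stat": float(ks), "kruskal_p": float(kp),
             "wilcoxon_stat": float(ws), "wilcoxon_p": float(wp), "note": ""}
        )
    df = pd.DataFrame(per_feature)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        for col in ("kruskal_p", "wilcoxon_p"):
            ok = df[col].notna()
            adj = np.full(len(df), np.nan)
            if ok.any():
                adj[ok.to_numpy()] = multipletests(df.loc[ok, col], method="fdr_bh")[1]
            df[col + "_bh"] = adj

    non_constant = table.values[:, table.values.std(axis=0) > 0]
    if non_constant.shape[1] >= 3:
        fr_stat, fr_p = stats.friedmanchisquare(*non_constant.T)
    else:
        fr_stat, fr_p = np.nan, np.nan

    # reference-classifier agreement under CV
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    from sklearn.neighbors import KNeighborsClassifier

    for train, test in skf.split(table.values, y):
        k = min(knn_k, len(train))
        knn = KNeighborsClassifier(n_neighbors=k).fit(table.values[train], y[train])
        preds[test] = knn.predict(table.values[test])
    kappa = float(cohen_kappa_score(y, preds))

    return {
        "per_feature": df,
        "friedman_stat": float(fr_stat) if np.isfinite(fr_stat) else np.nan,
        "friedman_p": float(fr_p) if np.isfinite(fr_p) else np.nan,
        "cohen_kappa": kappa,
    }
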