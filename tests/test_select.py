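"""Feature selection: information-gain entropy arithmetic, transfer function,
wrapper fitness, and metaheuristic search contracts."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcghyper import select
from bcghyper.containers import FeatureTable
from bcghyper.synth import SynthTableConfig, generate_feature_table


def brute_force_best(table, evaluator):
    """Exhaustive minimum of the wrapper fitness over all non-empty masks."""
    evaluator.bind(table)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=table.n_features):
        if not any(bits):
            continue
        best = min(best, evaluator(np.array(bits, dtype=bool)))
    return best


class TestVShapeTransfer:
    def test_zero_maps_to_zero(self):
        assert select.vshape_transfer(0.0) == 0.0

    def test_unit_input_value(self):
        # (2/pi) * arctan(pi/2) evaluated at high precision
        assert select.vshape_transfer(1.0) == pytest.approx(0.6390929267, abs=1e-9)

    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_monotone_in_magnitude(self, t):
        v = select.vshape_transfer(t)
        assert 0.0 <= v < 1.0
        assert select.vshape_transfer(abs(t) + 1.0) >= v

    def test_limit_is_one(self):
        assert select.vshape_transfer(1e12) == pytest.approx(1.0, abs=1e-9)


class TestInformationGain:
    def test_feature_identical_to_label_gains_full_entropy(self):
        y = np.array([0, 1] * 20)
        t = FeatureTable(y[:, None].astype(float), ["copy"], y)
        scores, mask = select.information_gain(t, bins=4)
        # balanced binary labels: H(P) = 1 bit, all of it explained
        assert scores[0] == pytest.approx(1.0, abs=1e-12)
        assert mask.mask[0]

    def test_constant_feature_has_zero_gain(self):
        y = np.array([0, 1] * 20)
        t = FeatureTable(
            np.column_stack([np.ones(40), y.astype(float)]), ["const", "copy"], y
        )
        scores, _ = select.information_gain(t, bins=4)
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_gain_against_direct_entropy_arithmetic(self):
        """Independent oracle: H(P) - H(P|F) computed from the explicit
        contingency table for every feature of an exhaustive small table."""
        rng = np.random.default_rng(0)
        y = np.array([0] * 10 + [1] * 10)
        X = np.column_stack([
            y + 0.0,
            rng.integers(0, 2, 20).astype(float),
            rng.integers(0, 3, 20).astype(float),
        ])
        t = FeatureTable(X, ["a", "b", "c"], y)
        scores, _ = select.information_gain(t, bins=4)

        def entropy(counts):
            p = counts[counts > 0] / counts.sum()
            return -np.sum(p * np.log2(p))

        h_p = entropy(np.bincount(y))
        for j in range(3):
            vals = X[:, j]
            h_cond = 0.0
            edges = np.unique(np.quantile(vals, np.linspace(0, 1, 5)[1:-1]))
            binned = np.digitize(vals, edges)
            for b in np.unique(binned):
                sub = y[binned == b]
                h_cond += len(sub) / len(y) * entropy(np.bincount(sub))
            assert scores[j] == pytest.approx(h_p - h_cond, abs=1e-12)

    def test_gain_bounded_by_class_entropy(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            t = generate_feature_table(
                SynthTableConfig(n_samples=60, d_informative=2, d_noise=4,
                                 effect_size=rng.uniform(0, 2), seed=seed)
            )
            scores, _ = select.information_gain(t)
            assert np.all(scores >= -1e-12)
            assert np.all(scores <= 1.0 + 1e-12)  # H(P) = 1 for balanced labels

    def test_single_class_rejected(self):
        t = FeatureTable(np.random.default_rng(0).standard_normal((10, 2)),
                         ["a", "b"], np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            select.information_gain(t)


class TestFitness:
    def test_weighted_sum_arithmetic(self):
        """k1*error + k2*FSR: with a perfectly separable single feature the
        error term vanishes and the fitness is k2/d."""
        ev = select.FitnessEvaluator(k1=0.99, k2=0.01)
        assert ev.k1 * 0.1 + ev.k2 * 0.5 == pytest.approx(0.104, abs=1e-12)

    def test_perfect_compact_subset_fitness(self, separable_table):
        ev = select.FitnessEvaluator().bind(separable_table)
        mask = np.array([True, False, False, False])
        assert ev(mask) == pytest.approx(0.01 * 0.25, abs=1e-9)

    def test_all_features_on_separable_table(self, separable_table):
        ev = select.FitnessEvaluator().bind(separable_table)
        fit = ev(np.ones(4, dtype=bool))
        # error ~ 0 so fitness ~ k2 * 1
        assert fit == pytest.approx(0.01, abs=5e-3)

    def test_empty_mask_rejected(self, separable_table):
        ev = select.FitnessEvaluator().bind(separable_table)
        with pytest.raises(ValueError):
            ev(np.zeros(4, dtype=bool))

    def test_knn_error_matches_sklearn(self, default_table):
        """The vectorized 10-NN scorer agrees with scikit-learn's
        KNeighborsClassifier under the same folds."""
        from sklearn.neighbors import KNeighborsClassifier

        ev = select.FitnessEvaluator(seed=3).bind(default_table)
        mask = np.ones(default_table.n_features, dtype=bool)
        err = ev.error(mask)
        mistakes = 0
        total = 0
        for train, test in ev._folds:
            knn = KNeighborsClassifier(n_neighbors=10).fit(
                default_table.values[train], default_table.labels[train]
            )
            pred = knn.predict(default_table.values[test])
            mistakes += int(np.sum(pred != default_table.labels[test]))
            total += len(test)
        assert err == pytest.approx(mistakes / total, abs=0.02)


@pytest.mark.parametrize("runner", ["btsa", "aoa", "bpso"])
class TestWrapperBruteForce:
    def test_finds_exhaustive_minimum_on_three_features(self, runner, toy_table_d3):
        """On a 3-feature table all 7 masks can be enumerated; each wrapper
        must return exactly the global minimum fitness in every seeded run."""
        target = brute_force_best(toy_table_d3, select.FitnessEvaluator())
        for seed in range(10):
            ev = select.FitnessEvaluator()
            if runner == "btsa":
                mask, _ = select.btsa_select(toy_table_d3, ev, pop=8,
                                             generations=30, seed=seed)
            elif runner == "aoa":
                mask, _ = select.aoa_select(toy_table_d3, ev, pop=8,
                                            generations=30, seed=seed)
            else:
                mask = select.baseline_select(toy_table_d3, "bpso", ev, pop=8,
                                              generations=30, seed=seed)
            assert mask.fitness == pytest.approx(target, abs=1e-12)


class TestWrapperContracts:
    @pytest.mark.parametrize("selector", [select.btsa_select, select.aoa_select])
    def test_elitist_trace_non_increasing_and_reproducible(self, selector,
                                                           default_table):
        m1, tr1 = selector(default_table, select.FitnessEvaluator(), pop=10,
                           generations=15, seed=2)
        m2, tr2 = selector(default_table, select.FitnessEvaluator(), pop=10,
                           generations=15, seed=2)
        assert np.all(np.diff(tr1) <= 0)
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(m1.mask, m2.mask)

    @pytest.mark.parametrize("selector", ["btsa", "aoa", "bpso", "baco"])
    def test_returned_mask_beats_all_features(self, selector, default_table):
        ev = select.FitnessEvaluator()
        if selector == "btsa":
            mask, _ = select.btsa_select(default_table, ev, pop=10,
                                         generations=15, seed=0)
        elif selector == "aoa":
            mask, _ = select.aoa_select(default_table, ev, pop=10,
                                        generations=15, seed=0)
        else:
            mask = select.baseline_select(default_table, selector, ev, pop=10,
                                          generations=15, seed=0)
        assert mask.mask.sum() >= 1
        all_fit = ev(np.ones(default_table.n_features, dtype=bool))
        assert mask.fitness <= all_fit + 1e-12

    @pytest.mark.parametrize("selector", ["btsa", "aoa", "bpso"])
    def test_perfect_predictor_dominates(self, selector, separable_table):
        """When one feature perfectly predicts the label, every wrapper ends
        at fitness <= k2 * (1/d) + tolerance."""
        ev = select.FitnessEvaluator()
        if selector == "btsa":
            mask, _ = select.btsa_select(separable_table, ev, pop=10,
                                         generations=25, seed=1)
        elif selector == "aoa":
            mask, _ = select.aoa_select(separable_table, ev, pop=10,
                                        generations=25, seed=1)
        else:
            mask = select.baseline_select(separable_table, "bpso", ev, pop=10,
                                          generations=25, seed=1)
        assert mask.fitness <= 0.01 * 0.25 + 1e-9


class TestBaselineFilters:
    def test_constant_feature_never_selected(self):
        y = np.array([0, 1] * 30)
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(60), y + 0.1 * rng.standard_normal(60)])
        t = FeatureTable(X, ["const", "good"], y)
        for method in ("chi2", "pcc"):
            mask = select.baseline_select(t, method)
            assert not mask.mask[0]

    def test_label_copy_has_unit_correlation(self):
        y = np.array([0, 1] * 30)
        rng = np.random.default_rng(3)
        X = np.column_stack([y.astype(float), rng.standard_normal(60)])
        t = FeatureTable(X, ["copy", "noise"], y)
        mask = select.baseline_select(t, "pcc")
        scores = mask.selector["scores"]
        assert scores[0] == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(scores) == 0

    def test_unknown_method_rejected(self, default_table):
        with pytest.raises(ValueError):
            select.baseline_select(default_table, "nope")

    def test_levy_sigma_value(self):
        # direct evaluation of the Gamma/sine expression at alpha = 0.5
        assert select.levy_sigma(0.5) == pytest.approx(1.2166, abs=1e-3)
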