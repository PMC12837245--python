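import numpy as np
import pytest

from bcghyper.containers import FeatureTable
from bcghyper.synth import (
    SynthCohortConfig,
    SynthTableConfig,
    generate_bcg_cohort,
    generate_feature_table,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten 60-second subjects; enough for I/O and preprocessing tests."""
    cfg = SynthCohortConfig(n_normal=5, n_hyper=5, duration=60.0, seed=11)
    return generate_bcg_cohort(cfg)


@pytest.fixture(scope="session")
def default_table():
    """200 x (5 informative + 15 noise) Gaussian table, effect size 2."""
    return generate_feature_table(SynthTableConfig(seed=7))


@pytest.fixture(scope="session")
def toy_table_d3():
    """Three-feature table (one informative) for brute-force mask enumeration."""
    return generate_feature_table(
        SynthTableConfig(n_samples=60, d_informative=1, d_noise=2,
                         effect_size=3.0, seed=5)
    )


@pytest.fixture(scope="session")
def separable_table():
    """Perfectly separable one-feature-dominant table."""
    rng = np.random.default_rng(3)
    n = 80
    labels = np.array([0] * 40 + [1] * 40)
    values = rng.standard_normal((n, 4))
    values[:, 0] = np.where(labels == 1, 5.0, -5.0) + 0.1 * rng.standard_normal(n)
    return FeatureTable(values, ["sep", "n1", "n2", "n3"], labels)
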