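import numpy as np
import pytest

from harselect.features import extract_table
from harselect.objective import XGBoostAdapter
from harselect.synthetic import (
    ActivityModel,
    BenchmarkSpec,
    make_benchmark_features,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_model():
    """Compact activity model: 6 classes keeps signal tests fast."""
    return ActivityModel.default(n_classes=6, seed=0)


@pytest.fixture(scope="session")
def small_windows(small_model):
    return simulate_dataset(small_model, n_per_class=12, seed=3)


@pytest.fixture(scope="session")
def small_table(small_windows):
    return extract_table(small_windows)


@pytest.fixture(scope="session")
def benchmark_table():
    """Separable 3-class benchmark with 5 informative of 48 columns."""
    return make_benchmark_features(
        BenchmarkSpec(n_samples=600, n_features=48, k_informative=5,
                      class_separation=2.5, n_classes=3, seed=1)
    )


@pytest.fixture(scope="session")
def toy_regression_stumps():
    """Squared-error depth-1 ensemble on 8 features.

    With unit hessians and one feature per tree, the library's
    tree-path expectations coincide with uniform averaging over the
    training data, making the model a clean target for the exact
    Shapley oracle.
    """
    import xgboost

    rng = np.random.default_rng(42)
    X = rng.standard_normal((250, 8))
    y = 2.0 * X[:, 0] - X[:, 3] + 0.5 * X[:, 6] + 0.3 * rng.standard_normal(250)
    model = xgboost.XGBRegressor(
        n_estimators=60, learning_rate=0.3, max_depth=1,
        min_child_weight=1, random_state=0, n_jobs=1, tree_method="hist",
        base_score=0.5,
    )
    model.fit(X, y)
    return model, X


@pytest.fixture(scope="session")
def fitted_multiclass_adapter(small_table):
    adapter = XGBoostAdapter(n_estimators=40, learning_rate=0.3,
                             max_depth=3, min_child_weight=1)
    adapter.fit(small_table.values, small_table.labels)
    return adapter
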