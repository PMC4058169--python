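import numpy as np
import pytest

from swarmsvm import KernelSpec, KernelSVM, generate_synthetic


@pytest.fixture(scope="session")
def toy_linear_results():
    """Symmetric two-point problem: x1=(1,0) y=+1, x2=(-1,0) y=-1, C=10.

    The dual reduces to maximizing s - s^2/2 over s = a1 + a2 with
    a1 = a2, giving a1 = a2 = 1/2, b = 0 and dual objective 1/2.
    """
    X = np.array([[1.0, 0.0], [-1.0, 0.0]])
    y = np.array([1, -1])
    model = KernelSVM(X, y, kernel=KernelSpec("linear"), C=10.0)
    return model.fit(tolerance=1e-8)


@pytest.fixture(scope="session")
def separable_dataset():
    """Two Gaussian clusters 10 sigma apart: linearly separable with
    near-certainty, so a moderate-C SVM classifies it perfectly."""
    return generate_synthetic(
        n_per_class=(50, 50), n_features=4, separation=10.0, seed=42
    )


@pytest.fixture
def random_instances():
    """Small random SVM instances (3-6 points, both classes present)."""
    rng = np.random.default_rng(2024)
    instances = []
    while len(instances) < 12:
        n = int(rng.integers(3, 7))
        X = rng.normal(size=(n, 2))
        y = np.where(rng.uniform(size=n) < 0.5, 1, -1)
        if len(np.unique(y)) == 2:
            instances.append((X, y, float(rng.choice([0.5, 1.0, 10.0]))))
    return instances
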