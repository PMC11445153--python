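import numpy as np
import pytest

import ovauq


@pytest.fixture(scope="session")
def small_spec() -> ovauq.SyntheticSpec:
    """Well-separated 3-class dataset small enough for per-test training."""
    return ovauq.SyntheticSpec(
        class_counts=(120, 100, 110), n_features=12, separation=10.0, sigma=1.0, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec) -> ovauq.LabeledDataset:
    return ovauq.make_features(small_spec)


@pytest.fixture(scope="session")
def small_net_spec() -> ovauq.ReferenceNetSpec:
    return ovauq.ReferenceNetSpec(input_dim=12, hidden=(16, 8), dropout_rate=0.5)


@pytest.fixture(scope="session")
def fast_manifest() -> ovauq.RunManifest:
    """Scaled-down manifest for quick end-to-end runs in unit tests."""
    return ovauq.RunManifest(
        seed=5, n_passes=20, n_members=3, epochs=20, threshold=0.3,
        n_features=12, separation=10.0,
    )


@pytest.fixture(scope="session")
def trained_small_net(small_dataset, small_net_spec) -> ovauq.DropoutMLP:
    """One dropout net trained on the class-0-vs-rest small task."""
    task = ovauq.binarize(small_dataset, 0)
    net = ovauq.build_reference_net(small_net_spec, seed=3)
    net.fit(task.X, task.y, ovauq.TrainConfig(epochs=10, seed=3))
    return net
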