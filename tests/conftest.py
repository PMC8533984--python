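import numpy as np
import pytest

import qpicell as q


@pytest.fixture(scope="session")
def constants():
    return q.OpticalConstants()


@pytest.fixture(scope="session")
def default_dataset(constants):
    """The default labeled synthetic dataset: 9 classes x 50 cells."""
    spec = q.SyntheticDatasetSpec(n_cells_per_class=50, seed=0)
    return q.make_labeled_dataset(spec, constants)


@pytest.fixture(scope="session")
def default_feature_table(default_dataset, constants):
    return q.feature_table(default_dataset, constants)


@pytest.fixture(scope="session")
def default_amplitude_table(default_dataset):
    return q.amplitude_feature_table(default_dataset)


@pytest.fixture(scope="session")
def hela_states_model(constants):
    """SVM (quadratic kernel) trained on the HeLa live/apoptotic/necrotic task."""
    spec = q.SyntheticDatasetSpec(n_cells_per_class=40, lines=("HeLa",), seed=11)
    table = q.feature_table(q.make_labeled_dataset(spec, constants), constants)
    train, test = q.split_train_test(table, seed=0)
    model = q.train_classifier(train, q.ClassifierSpec(seed=0), task="states")
    accuracy = q.evaluate(model, test).accuracy_pct
    return model, accuracy


def disk_mask(shape, center, radius):
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (x - center[1]) ** 2 + (y - center[0]) ** 2 < radius**2
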