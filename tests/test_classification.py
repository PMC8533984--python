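"""Classifier training, evaluation, feature ranking and dynamics."""

import numpy as np
import pandas as pd
import pytest

import qpicell as q


def _blob_table(n_per_class=100, d=10, sep=10.0, seed=0):
    """Two linearly separable Gaussian blobs as a trivial sanity dataset."""
    rng = np.random.default_rng(seed)
    names = [f"f{i}" for i in range(d)]
    rows = []
    for cls, line in (("live", "HeLa"), ("necrotic", "A549")):
        center = np.zeros(d) if cls == "live" else np.full(d, sep / np.sqrt(d))
        X = rng.normal(size=(n_per_class, d)) + center
        for x in X:
            rows.append({**dict(zip(names, x)), "line_label": line, "state_label": cls})
    return pd.DataFrame(rows), names


def test_split_is_stratified_and_deterministic(default_feature_table):
    train, test = q.split_train_test(default_feature_table, seed=0)
    assert len(train) == 360 and len(test) == 90
    joint = test.line_label + "/" + test.state_label
    assert all(v == 10 for v in joint.value_counts())

    train2, test2 = q.split_train_test(default_feature_table, seed=0)
    assert train.cell_id.tolist() == train2.cell_id.tolist()


def test_split_guards():
    df = pd.DataFrame(
        dict(f0=[1.0, 2.0], line_label=["HeLa", "HeLa"], state_label=["live", "apoptotic"])
    )
    with pytest.raises(ValueError, match="fewer than 2"):
        q.split_train_test(df)
    with pytest.raises(ValueError, match="test_fraction"):
        q.split_train_test(df, test_fraction=0.0)


@pytest.mark.parametrize("family", ["svm", "knn", "ec"])
def test_separable_blobs_classified_perfectly(family):
    table, names = _blob_table()
    spec = q.ClassifierSpec(family=family, seed=0)
    model = q.train_classifier(table, spec, task="states", feature_names=names)
    report = q.evaluate(model, table)
    assert report.accuracy_pct == 100.0
    assert np.all(np.diag(report.confusion.to_numpy()) == 100)


def test_label_permutation_gives_chance_level(default_feature_table):
    """Accuracy under permuted labels stays within 3 binomial stds of 1/3."""
    accs = q.label_permutation_accuracy(
        default_feature_table,
        q.ClassifierSpec(seed=0),
        task="lines",
        n_permutations=10,
        seed=1,
    )
    n_test = int(0.2 * len(default_feature_table))
    chance = 100.0 / 3.0
    band = 3.0 * 100.0 * np.sqrt((1 / 3) * (2 / 3) / n_test)
    assert abs(accs.mean() - chance) < band


def test_nine_class_svm_accuracy(default_feature_table):
    train, test = q.split_train_test(default_feature_table, seed=0)
    model = q.train_classifier(
        train, q.ClassifierSpec(family="svm", svm_kernel="quadratic", seed=0),
        task="nine_class",
    )
    report = q.evaluate(model, test)
    assert report.accuracy_pct >= 90.0


def test_qpi_features_beat_amplitude_baseline(
    default_feature_table, default_amplitude_table
):
    spec = q.ClassifierSpec(family="svm", svm_kernel="quadratic", seed=0)
    tr, te = q.split_train_test(default_feature_table, seed=0)
    acc_qpi = q.evaluate(q.train_classifier(tr, spec, task="nine_class"), te).accuracy_pct
    tra, tea = q.split_train_test(default_amplitude_table, seed=0)
    acc_amp = q.evaluate(
        q.train_classifier(
            tra, spec, task="nine_class", feature_names=q.AMPLITUDE_FEATURE_NAMES
        ),
        tea,
    ).accuracy_pct
    assert acc_qpi - acc_amp >= 5.0


def test_evaluation_report_internal_identities(default_feature_table):
    train, test = q.split_train_test(default_feature_table, seed=3)
    model = q.train_classifier(train, q.ClassifierSpec(seed=0), task="lines")
    report = q.evaluate(model, test)
    cm = report.confusion.to_numpy()
    assert report.accuracy_pct == pytest.approx(100.0 * np.trace(cm) / cm.sum())
    assert cm.sum() == report.n_test
    # confusion rows sum to per-class test counts
    true = q.classification.task_labels(test, "lines").value_counts()
    for cls in report.confusion.index:
        assert cm[report.confusion.index.get_loc(cls)].sum() == true[cls]


def test_training_determinism(default_feature_table):
    train, test = q.split_train_test(default_feature_table, seed=0)
    spec = q.ClassifierSpec(family="ec", seed=5)
    a = q.evaluate(q.train_classifier(train, spec, task="nine_class"), test)
    b = q.evaluate(q.train_classifier(train, spec, task="nine_class"), test)
    assert a.accuracy_pct == b.accuracy_pct
    assert a.confusion.equals(b.confusion)


def test_feature_subset_curve_shape_and_informative_feature():
    rng = np.random.default_rng(0)
    n = 150
    rows = []
    for cls in ("live", "apoptotic", "necrotic"):
        shift = {"live": 0.0, "apoptotic": 6.0, "necrotic": 12.0}[cls]
        for _ in range(n):
            rows.append(
                dict(
                    informative=rng.normal(shift),
                    noise_a=rng.normal(),
                    noise_b=rng.normal(),
                    line_label="HeLa",
                    state_label=cls,
                )
            )
    table = pd.DataFrame(rows)
    curve = q.feature_subset_analysis(
        table,
        q.ClassifierSpec(seed=0),
        ranking=["informative", "noise_a", "noise_b"],
        task="states",
        seed=0,
    )
    assert len(curve) == 3
    assert curve.n_features.tolist() == [1, 2, 3]
    # accuracy flat (within sampling noise) after the informative feature
    assert curve.accuracy_pct.iloc[1] >= curve.accuracy_pct.iloc[0] - 5.0
    assert curve.accuracy_pct.iloc[0] > 85.0

    with pytest.raises(ValueError, match="empty"):
        q.feature_subset_analysis(table, q.ClassifierSpec(seed=0), ranking=[], task="states")


def test_time_series_fraction_dynamics(hela_states_model):
    """Recovered necrotic fraction tracks the simulated treatment mixture."""
    from scipy.stats import spearmanr

    model, accuracy = hela_states_model
    assert accuracy >= 90.0
    series = q.simulate_treatment_series(seed=5)
    result = q.classify_time_series(series.frames, model)
    tb = result.table
    assert (tb.n_cells > 0).all()
    sums = tb[["frac_live", "frac_apoptotic", "frac_necrotic"]].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    rho = spearmanr(tb.time_min, tb.frac_necrotic).statistic
    assert rho > 0.9


def test_time_series_live_only(hela_states_model):
    model, _ = hela_states_model
    series = q.simulate_treatment_series(
        n_timepoints=3, n_cells_per_frame=9,
        start_mix=(1, 0, 0), end_mix=(1, 0, 0), seed=8,
    )
    result = q.classify_time_series(series.frames, model)
    assert (result.table.frac_live >= 0.9).all()
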