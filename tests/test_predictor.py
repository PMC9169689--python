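"""Learned selector: training, prediction, CV protocol, search, curve."""

import numpy as np
import pytest

from spmvselect import (
    Dataset,
    FeatureVector,
    GeneratorConfig,
    PROFILES,
    SearchSpace,
    cross_validate,
    hyperparameter_search,
    learning_curve,
    load_model,
    predict,
    save_model,
    select_format,
    simulate_dataset,
    train,
)
from spmvselect.benchmark import FORMAT_PRIORITY, BenchmarkRecord, best_format_of
from spmvselect.predictor import PredictorModel

CFG = GeneratorConfig(size_set=(1000, 2000, 4000), fixed_nnz_set=(32, 128, 512),
                      density_range=(0.01, 1.0))


@pytest.fixture(scope="module")
def sim_dataset():
    return simulate_dataset(PROFILES["reference"], CFG, 200,
                            rng=np.random.default_rng(77))


@pytest.fixture(scope="module")
def trained(sim_dataset):
    return train(sim_dataset, architecture=(64, 64), learning_rate=3e-3,
                 epochs=120, seed=1)


def affine_dataset(n=300, seed=0):
    """Targets that are an exact affine function of two features."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        des = rng.uniform(0.01, 1.0)
        avgnzr = rng.uniform(1, 500)
        f = FeatureVector(n=100, m=1000, nnz=int(avgnzr * 100),
                          des=des, avgnzr=avgnzr, minnzr=0,
                          maxnzr=int(np.ceil(avgnzr)))
        g = {"csr": 1.0 + 2.0 * des, "ellpack_r": 3.0 - des,
             "dense": 0.5 + avgnzr / 250.0}
        records.append(BenchmarkRecord(
            features=f, gflops=g,
            time_s={k: 1.0 for k in g},
            best_format=best_format_of(g), sample_id=i))
    return Dataset(records=records, provenance={})


class TestTrain:
    def test_fits_affine_targets_to_low_heldout_error(self):
        ds = affine_dataset()
        model = train(Dataset(ds.records[:240], {}), architecture=(64, 64),
                      learning_rate=3e-3, epochs=250, seed=0)
        X = Dataset(ds.records[240:], {}).feature_matrix()
        Y = Dataset(ds.records[240:], {}).target_matrix()
        mse = float(np.mean((model.forward(X) - Y) ** 2))
        # targets have O(1) variance; an affine map should be near-exact
        assert mse < 1e-3

    def test_deterministic_under_seed(self, sim_dataset):
        m1 = train(sim_dataset, architecture=(16,), epochs=20, seed=3)
        m2 = train(sim_dataset, architecture=(16,), epochs=20, seed=3)
        for a, b in zip(m1.coefs, m2.coefs):
            assert np.array_equal(a, b)
        for a, b in zip(m1.intercepts, m2.intercepts):
            assert np.array_equal(a, b)

    def test_loss_decreases(self, trained):
        curve = trained.training_meta["loss_curve"]
        assert curve[-1] <= curve[0]

    def test_normalization_from_training_rows_only(self, sim_dataset):
        sub = Dataset(sim_dataset.records[:100], {})
        model = train(sub, architecture=(8,), epochs=10, seed=0)
        X = sub.feature_matrix()
        np.testing.assert_allclose(model.feature_mean, X.mean(axis=0))
        np.testing.assert_allclose(model.feature_std[X.std(axis=0) > 0],
                                   X.std(axis=0)[X.std(axis=0) > 0])

    def test_rejects_tiny_or_nonfinite_data(self, sim_dataset):
        with pytest.raises(ValueError):
            train(Dataset(sim_dataset.records[:1], {}))
        bad = affine_dataset(n=10)
        bad.records[0].gflops["csr"] = float("nan")
        with pytest.raises(ValueError):
            train(bad, epochs=5)


class TestPredictSelect:
    def test_pure_function_of_inputs(self, trained, sim_dataset):
        f = sim_dataset.records[0].features
        assert predict(trained, f) == predict(trained, f)

    def test_three_finite_outputs(self, trained, sim_dataset):
        out = predict(trained, sim_dataset.records[3].features)
        assert set(out) == set(FORMAT_PRIORITY)
        assert all(np.isfinite(v) for v in out.values())

    def test_predictions_respond_to_features(self, trained, sim_dataset):
        outs = {tuple(predict(trained, r.features).values())
                for r in sim_dataset.records[:20]}
        assert len(outs) > 1  # non-constant model

    def test_select_examples_and_ties(self, trained):
        model = trained
        # direct argmax semantics via the shared tie-break helper
        assert best_format_of(dict(zip(FORMAT_PRIORITY, (1.0, 2.0, 0.5)))) \
            == "ellpack_r"
        assert best_format_of(dict(zip(FORMAT_PRIORITY, (2.0, 2.0, 0.5)))) \
            == "csr"
        f = affine_dataset(n=2).records[0].features
        assert select_format(model, f) == best_format_of(predict(model, f))

    def test_ordering_recovery_on_noiseless_device(self, sim_dataset):
        """Trained on ample noiseless data, the predicted argmax matches
        the true ordering on >=90% of held-out points."""
        tr = Dataset(sim_dataset.records[:160], {})
        te = sim_dataset.records[160:]
        model = train(tr, architecture=(128, 128, 128), learning_rate=3e-3,
                      epochs=300, seed=0)
        hits = np.mean([select_format(model, r.features) == r.best_format
                        for r in te])
        assert hits >= 0.90


class TestSerialization:
    def test_json_roundtrip_bit_identical(self, trained, sim_dataset, tmp_path):
        path = tmp_path / "model.json"
        save_model(trained, path)
        back = load_model(path)
        X = sim_dataset.feature_matrix()
        assert np.array_equal(back.forward(X), trained.forward(X))


class TestCrossValidate:
    def test_fold_sizes_and_partition(self, sim_dataset):
        from sklearn.model_selection import RepeatedKFold
        n = len(sim_dataset)
        splitter = RepeatedKFold(n_splits=5, n_repeats=1, random_state=0)
        test_sets = [set(te) for _, te in splitter.split(np.arange(n))]
        assert sorted(len(s) for s in test_sets) == [40] * 5
        union = set().union(*test_sets)
        assert union == set(range(n))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not test_sets[i] & test_sets[j]

    def test_summary_shape_and_range(self, sim_dataset):
        res = cross_validate(sim_dataset, architecture=(16,), epochs=15,
                             folds=4, repeats=2, seed=0)
        assert len(res.per_fold) == 8
        assert 0.0 <= res.mean <= 1.0
        assert res.mean == pytest.approx(np.mean(res.per_fold))

    def test_majority_class_baseline_is_exact(self, sim_dataset):
        """A constant predictor scores exactly the majority-class share."""
        labels = sim_dataset.labels()
        counts = {f: int(np.sum(labels == f)) for f in FORMAT_PRIORITY}
        majority = max(counts, key=counts.__getitem__)
        # constant model: zero weights, bias favoring the majority format
        bias = np.array([1.0 if f == majority else 0.0
                         for f in FORMAT_PRIORITY])
        const = PredictorModel(
            feature_mean=np.zeros(7), feature_std=np.ones(7),
            hidden_layer_sizes=(), coefs=[np.zeros((7, 3))],
            intercepts=[bias])
        acc = np.mean([best_format_of(dict(zip(FORMAT_PRIORITY, row))) == lab
                       for row, lab in zip(const.forward(
                           sim_dataset.feature_matrix()), labels)])
        assert acc == counts[majority] / len(labels)

    def test_too_few_records_rejected(self, sim_dataset):
        with pytest.raises(ValueError):
            cross_validate(Dataset(sim_dataset.records[:3], {}), folds=5)


class TestHyperparameterSearch:
    def test_collapsed_space_returns_the_point(self, sim_dataset):
        space = SearchSpace(depth_range=(2, 2), width_range=(16, 16),
                            learning_rate_range=(3e-3, 3e-3), n_trials=1)
        res = hyperparameter_search(sim_dataset, space, seed=0, epochs=10)
        assert res.architecture == (16, 16)
        assert res.learning_rate == pytest.approx(3e-3)
        assert len(res.trials) == 1

    def test_best_is_max_over_trial_log(self, sim_dataset):
        space = SearchSpace(depth_range=(1, 2), width_range=(8, 32),
                            learning_rate_range=(1e-4, 1e-2), n_trials=3)
        res = hyperparameter_search(sim_dataset, space, seed=1, epochs=10)
        assert res.accuracy == max(t["accuracy"] for t in res.trials)
        assert all(space.width_range[0] <= w <= space.width_range[1]
                   for t in res.trials for w in t["architecture"])

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(n_trials=0)


class TestLearningCurve:
    def test_row_count_and_full_fraction_consistency(self, sim_dataset):
        rows = learning_curve(sim_dataset, fractions=(0.5, 1.0),
                              architecture=(16,), epochs=15,
                              folds=4, repeats=1, seed=0)
        assert len(rows) == 2
        ref = cross_validate(sim_dataset, architecture=(16,), epochs=15,
                             folds=4, repeats=1, seed=0)
        assert rows[1]["accuracy_mean"] == pytest.approx(ref.mean)
        assert rows[0]["n"] == 100

    def test_degenerate_fraction_rejected(self, sim_dataset):
        with pytest.raises(ValueError):
            learning_curve(sim_dataset, fractions=(0.001,), folds=5,
                           repeats=1)
        with pytest.raises(ValueError):
            learning_curve(sim_dataset, fractions=(1.5,), folds=5, repeats=1)
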