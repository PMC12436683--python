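import dataclasses

import numpy as np
import pytest
from sklearn.base import clone

from glylstm.encoder import CaseSpec, encode_matrix
from glylstm.properties import fit_scale_stats, load_builtin_property_set
from glylstm.rnn_model import (
    LSTMClassifier,
    ModelConfig,
    build_model,
    classify,
    load_model,
    predict_proba,
    save_model,
    train,
)
from glylstm.synthetic_data import SyntheticConfig, generate_separable


def _encoded_separable(n, seed=0, prop="IEP"):
    pset = load_builtin_property_set()
    recs = generate_separable(SyntheticConfig(n=n, seed=seed, planted_properties=(prop,)))
    stats = fit_scale_stats(recs, pset)
    X, y = encode_matrix(recs, CaseSpec.single(prop), pset, stats)
    return X, y


class TestModelConfig:
    def test_width_restricted_to_2_or_8(self):
        with pytest.raises(ValueError, match="input_width"):
            ModelConfig(input_width=3)
        assert ModelConfig(input_width=3, allow_any_width=True).input_width == 3

    def test_dropout_rate_one_rejected(self):
        with pytest.raises(ValueError, match="dropout1"):
            ModelConfig(dropout1=1.0)

    def test_round_trip_dict(self):
        cfg = ModelConfig(input_width=8, seed=42)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestBuildModel:
    def test_same_seed_gives_identical_initial_parameters(self):
        cfg = ModelConfig(input_width=8, seed=3)
        a, b = build_model(cfg), build_model(cfg)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_different_seed_gives_different_parameters(self):
        a = build_model(ModelConfig(input_width=2, seed=0))
        b = build_model(ModelConfig(input_width=2, seed=1))
        assert any(not np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_parameter_count_depends_only_on_width(self):
        n2a = build_model(ModelConfig(input_width=2, seed=0)).num_params()
        n2b = build_model(ModelConfig(input_width=2, seed=99)).num_params()
        n8 = build_model(ModelConfig(input_width=8, seed=0)).num_params()
        assert n2a == n2b
        # widening the input only grows the first LSTM kernel: 6 extra rows of 4*64
        assert n8 - n2a == 6 * 4 * 64

    def test_accepts_width_8_input(self):
        cfg = ModelConfig(input_width=8, seed=0)
        net = build_model(cfg)
        probs = net.forward(np.zeros((3, 31, 8), dtype=np.float32))
        assert probs.shape == (3, 2)
        with pytest.raises(ValueError, match="shape"):
            net.forward(np.zeros((3, 31, 2), dtype=np.float32))


class TestTrain:
    def test_empty_split_and_width_mismatch_rejected(self, tiny_model_config):
        X, y = _encoded_separable(40)
        net = build_model(tiny_model_config)
        with pytest.raises(ValueError, match="non-empty"):
            train(net, X[:0], X, tiny_model_config, train_labels=y[:0], val_labels=y)
        bad = dataclasses.replace(tiny_model_config, input_width=8)
        with pytest.raises(ValueError, match="width"):
            train(build_model(bad), X, X, bad, train_labels=y, val_labels=y)

    def test_loss_decreases_on_separable_toy_without_regularization(self):
        X, y = _encoded_separable(200, seed=1)
        cfg = ModelConfig(input_width=2, dropout1=0.0, dropout2=0.0, dropout3=0.0,
                          l2=0.0, max_epochs=5, patience=5, seed=0)
        tm = train(build_model(cfg), X, X, cfg, train_labels=y, val_labels=y)
        assert tm.history.train_loss[-1] < tm.history.train_loss[0]

    def test_history_bounded_and_best_epoch_restored(self):
        X, y = _encoded_separable(120, seed=2)
        cfg = ModelConfig(input_width=2, lstm1_units=8, lstm2_units=6, dense_units=4,
                          max_epochs=4, patience=2, seed=1)
        tm = train(build_model(cfg), X, X, cfg, train_labels=y, val_labels=y)
        h = tm.history
        assert len(h) <= cfg.max_epochs
        assert h.best_epoch == int(np.argmax(h.val_accuracy))
        # restored weights reproduce the best-epoch validation accuracy
        probs = tm.network.forward(X, training=False)
        acc = float(np.mean(probs.argmax(axis=1) == y))
        assert acc == pytest.approx(h.val_accuracy[h.best_epoch], abs=1e-9)

    def test_training_is_deterministic_given_seed(self, tiny_model_config):
        X, y = _encoded_separable(80, seed=3)
        t1 = train(build_model(tiny_model_config), X, X, tiny_model_config,
                   train_labels=y, val_labels=y)
        t2 = train(build_model(tiny_model_config), X, X, tiny_model_config,
                   train_labels=y, val_labels=y)
        assert t1.history.val_accuracy == t2.history.val_accuracy
        for k in t1.network.params:
            np.testing.assert_array_equal(t1.network.params[k], t2.network.params[k])


@pytest.fixture(scope="module")
def trained():
    X, y = _encoded_separable(150, seed=4)
    cfg = ModelConfig(input_width=2, lstm1_units=8, lstm2_units=6, dense_units=4,
                      max_epochs=2, patience=2, seed=0)
    return train(build_model(cfg), X, X, cfg, train_labels=y, val_labels=y), X


class TestPredictAndClassify:

    def test_pairs_sum_to_one_and_order_preserved(self, trained):
        tm, X = trained
        pairs = predict_proba(tm, X)
        assert pairs.shape == (len(X), 2)
        np.testing.assert_allclose(pairs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((pairs >= 0) & (pairs <= 1))

    def test_inference_is_repeatable(self, trained):
        tm, X = trained
        np.testing.assert_array_equal(predict_proba(tm, X), predict_proba(tm, X))

    def test_width_mismatch_rejected(self, trained):
        tm, _ = trained
        with pytest.raises(ValueError, match="width"):
            predict_proba(tm, np.zeros((2, 31, 8), dtype=np.float32))

    def test_classify_rules(self):
        pairs = np.array([[0.8, 0.2], [0.5, 0.5], [0.2, 0.8]])
        assert classify(pairs).tolist() == [1, 0, 0]

    def test_classify_rejects_unnormalized_pairs(self):
        with pytest.raises(ValueError, match="sums to"):
            classify(np.array([[0.7, 0.7]]))

    def test_save_load_round_trip(self, trained, tmp_path):
        tm, X = trained
        path = tmp_path / "model.npz"
        save_model(tm, path, extra_sidecar={"case": 1, "properties": ["IEP"]})
        loaded, sidecar = load_model(path)
        assert sidecar["properties"] == ["IEP"]
        np.testing.assert_allclose(predict_proba(loaded, X), predict_proba(tm, X),
                                   atol=1e-7)

    def test_load_without_sidecar_fails(self, trained, tmp_path):
        tm, _ = trained
        path = tmp_path / "model.npz"
        np.savez(path, **tm.network.params)
        with pytest.raises(FileNotFoundError, match="sidecar"):
            load_model(path)


class TestLSTMClassifierEstimator:
    def test_fit_predict_interface(self):
        X, y = _encoded_separable(200, seed=5)
        clf = LSTMClassifier(lstm1_units=8, lstm2_units=6, dense_units=4,
                             batch_size=16, max_epochs=15, patience=15, seed=0)
        clf.fit(X, y)
        assert clf.classes_.tolist() == [0, 1]
        proba = clf.predict_proba(X)
        assert proba.shape == (200, 2)
        preds = clf.predict(X)
        assert set(np.unique(preds)) <= {0, 1}
        # sklearn column order: column 1 is the positive (glycated) class
        np.testing.assert_array_equal(preds, (proba[:, 1] > proba[:, 0]).astype(int))
        assert clf.score(X, y) > 0.6

    def test_clone_and_get_params_round_trip(self):
        clf = LSTMClassifier(max_epochs=7, seed=3)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()

    def test_validation_data_overrides_internal_carve(self):
        X, y = _encoded_separable(120, seed=6)
        clf = LSTMClassifier(lstm1_units=8, lstm2_units=6, dense_units=4,
                             max_epochs=2, patience=2, seed=0)
        clf.fit(X[:80], y[:80], validation_data=(X[80:], y[80:]))
        assert len(clf.history_) <= 2
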