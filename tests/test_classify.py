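"""BiLSTM classifier: architecture contracts, training, metrics."""

import numpy as np
import pytest

from mayseg.classify import (
    BiLSTM,
    BiLSTMSpec,
    TrainConfig,
    build_model,
    evaluate,
    roc_auc_ovr,
    train,
)

TINY = BiLSTMSpec(input_dim=24, seq_len=4, hidden_units=6, fc_units=5, n_classes=3, dropout_rate=0.0, seed=0)


def separable_dataset(n_per_class=20, dim=120, seed=7):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1, 2], n_per_class)
    X = np.zeros((3 * n_per_class, dim))
    block = dim // 3
    for i, label in enumerate(y):
        X[i, label * block : (label + 1) * block] = 1.0 + 0.1 * rng.normal(size=block)
    return X, y


class TestModel:
    def test_output_is_probability_simplex(self, rng):
        m = build_model(TINY)
        probs = m.predict_proba(rng.normal(size=(5, 24)))
        assert probs.shape == (5, 3)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert probs.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-6)

    def test_same_seed_identical_parameters(self):
        p1 = build_model(TINY).params()
        p2 = build_model(TINY).params()
        assert all(np.array_equal(a, b) for a, b in zip(p1, p2))

    def test_layer_shapes(self):
        spec = BiLSTMSpec(input_dim=1126, seq_len=100, hidden_units=100, fc_units=50, n_classes=3)
        m = build_model(spec)
        assert spec.input_per_step == 12  # ceil(1126 / 100), final step zero-padded
        assert m.fwd.Wx.shape == (12, 400) and m.bwd.Wx.shape == (12, 400)
        assert m.W1.shape == (200, 50)  # concatenated BiLSTM width -> FC
        assert m.W2.shape == (50, 3)

    def test_gradients_match_finite_differences(self, rng):
        m = build_model(TINY)
        X = rng.normal(size=(4, 24))
        y = np.array([0, 1, 2, 1])
        loss, grads = m.loss_and_grads(X, y)
        eps = 1e-6
        for p, g in zip(m.params(), grads):
            for _ in range(3):
                idx = tuple(int(rng.integers(0, s)) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp, _ = m.loss_and_grads(X, y)
                p[idx] = old - eps
                lm, _ = m.loss_and_grads(X, y)
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(num, abs=1e-4, rel=1e-3)


class TestTrain:
    def test_overfits_separable_data(self):
        X, y = separable_dataset()
        spec = BiLSTMSpec(input_dim=120, seq_len=10, hidden_units=20, fc_units=20, n_classes=3, seed=0)
        m, trace = train(build_model(spec), X, y, TrainConfig(epochs=200, seed=0))
        assert np.all(np.isfinite(trace))
        assert evaluate(m, X, y).accuracy == 1.0

    def test_zero_epochs_leaves_model_unchanged(self):
        X, y = separable_dataset(5)
        m = build_model(BiLSTMSpec(input_dim=120, seq_len=10, hidden_units=8, n_classes=3, seed=1))
        before = [p.copy() for p in m.params()]
        m, trace = train(m, X, y, TrainConfig(epochs=0))
        assert len(trace) == 0
        assert all(np.array_equal(a, b) for a, b in zip(before, m.params()))

    def test_single_class_rejected(self):
        X = np.zeros((8, 24))
        with pytest.raises(ValueError):
            train(build_model(TINY), X, np.zeros(8, dtype=int), TrainConfig(epochs=1))

    def test_deterministic_training(self):
        X, y = separable_dataset(5)
        spec = BiLSTMSpec(input_dim=120, seq_len=10, hidden_units=8, n_classes=3, seed=2)
        m1, t1 = train(build_model(spec), X, y, TrainConfig(epochs=5, seed=3))
        m2, t2 = train(build_model(spec), X, y, TrainConfig(epochs=5, seed=3))
        assert np.array_equal(t1, t2)
        assert all(np.array_equal(a, b) for a, b in zip(m1.params(), m2.params()))

    def test_default_hyperparameters(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.batch_size == 32


class TestEvaluate:
    def test_binary_toy_confusion(self):
        # TP=9, FP=1, FN=1, TN=9 in the one-vs-rest reduction of class 0
        y = np.array([0] * 10 + [1] * 10)
        pred = np.array([0] * 9 + [1] + [1] * 9 + [0])
        tp, fp, fn, tn = 9, 1, 1, 9
        assert tp / (tp + fp) == pytest.approx(0.9)
        assert tp / (tp + fn) == pytest.approx(0.9)
        assert (tp + tn) / 20 == pytest.approx(0.9)
        confusion = np.zeros((2, 2), int)
        np.add.at(confusion, (y, pred), 1)
        assert confusion.tolist() == [[9, 1], [1, 9]]

    def test_report_identities(self, rng):
        X, y = separable_dataset(6)
        spec = BiLSTMSpec(input_dim=120, seq_len=10, hidden_units=8, n_classes=3, seed=4)
        m, _ = train(build_model(spec), X, y, TrainConfig(epochs=30, seed=0))
        rep = evaluate(m, X, y)
        assert rep.confusion.sum() == len(y)
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / len(y))
        if rep.precision + rep.recall > 0:
            assert 0.0 <= rep.f1 <= 1.0

    def test_empty_dataset_rejected(self):
        m = build_model(TINY)
        with pytest.raises(ValueError):
            evaluate(m, np.zeros((0, 24)), np.zeros(0, dtype=int))


class TestAUC:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert roc_auc_ovr(y, scores) == 1.0

    def test_matches_pairwise_concordance_oracle(self, rng):
        for trial in range(50):
            r = np.random.default_rng(trial)
            n = int(r.integers(6, 30))
            y = r.integers(0, 3, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = r.normal(size=(n, 3))
            aucs = []
            for cls in range(3):
                pos = np.where(y == cls)[0]
                neg = np.where(y != cls)[0]
                if len(pos) == 0 or len(neg) == 0:
                    continue
                conc = 0.0
                for i in pos:
                    for j in neg:
                        if scores[i, cls] > scores[j, cls]:
                            conc += 1.0
                        elif scores[i, cls] == scores[j, cls]:
                            conc += 0.5
                aucs.append(conc / (len(pos) * len(neg)))
            assert roc_auc_ovr(y, scores) == pytest.approx(np.mean(aucs), abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        y = rng.integers(0, 3, size=40)
        s = rng.normal(size=(40, 3))
        assert roc_auc_ovr(y, s) == pytest.approx(roc_auc_ovr(y, np.exp(s)), abs=1e-12)
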