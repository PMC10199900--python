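"""Event encoding, splits, Bayes baseline, LSTM, evaluation metrics."""

import numpy as np
import pytest
from scipy.stats import norm

import porecall as pc
from porecall.classify import encode_frame
from porecall.errors import InsufficientDataError, ValidationError
from porecall.lstm import SequenceClassifier, SequenceClassifierConfig

from conftest import make_encoded

FS = 100_000.0


def rect_event(depth=0.3, I0=3.0, dwell_n=60, ctx=30, label=None):
    """Noiseless rectangular event with context on both sides."""
    n = dwell_n + 2 * ctx
    w = np.full(n, I0)
    w[ctx: ctx + dwell_n] -= depth * I0
    return pc.EventRecord(
        start_index=1000 + ctx, end_index=1000 + ctx + dwell_n, sampling_rate=FS,
        I0_local=I0, dI=depth * I0, waveform=w, waveform_start=1000, label=label,
    )


class TestEncoding:
    def test_plateau_value(self):
        enc = pc.encode_event(rect_event(depth=0.3), L=64)
        mid = enc.waveform_vector[24:40]
        np.testing.assert_allclose(mid, 0.7, atol=1e-9)
        assert enc.scalar_features[0] == pytest.approx(0.3)

    def test_baseline_invariance(self):
        a = pc.encode_event(rect_event(depth=0.3, I0=1.0), L=64)
        b = pc.encode_event(rect_event(depth=0.3, I0=5.0), L=64)
        np.testing.assert_allclose(a.waveform_vector, b.waveform_vector, atol=1e-12)
        assert a.scalar_features == pytest.approx(b.scalar_features)

    def test_fixed_length_and_clipping(self):
        e = rect_event(depth=0.3)
        e.waveform[5] = 10.0  # spike far outside the physical range
        enc = pc.encode_event(e, L=48)
        assert enc.waveform_vector.size == 48
        assert enc.waveform_vector.min() >= -0.2
        assert enc.waveform_vector.max() <= 1.2

    def test_empty_waveform_rejected(self):
        e = rect_event()
        e.waveform = np.empty(0)
        with pytest.raises(ValidationError):
            pc.encode_event(e)


class TestSplit:
    def labels(self):
        return np.array(["G"] * 100 + ["A"] * 100, dtype=object)

    def test_exact_fractions_per_class(self):
        items = list(range(200))
        tr, va, te = pc.split_dataset(items, (0.7, 0.15, 0.15), seed=0,
                                      labels=self.labels())
        assert (len(tr), len(va), len(te)) == (140, 30, 30)
        y = self.labels()
        assert sum(y[i] == "G" for i in tr) == 70

    def test_partition_union_and_disjoint(self):
        items = list(range(200))
        tr, va, te = pc.split_dataset(items, seed=1, labels=self.labels())
        assert sorted(tr + va + te) == items

    def test_seed_reproducibility(self):
        items = list(range(200))
        a = pc.split_dataset(items, seed=2, labels=self.labels())
        b = pc.split_dataset(items, seed=2, labels=self.labels())
        assert a == b

    def test_small_class_error_names_class(self):
        labels = np.array(["G"] * 100 + ["A"] * 5, dtype=object)
        with pytest.raises(InsufficientDataError, match="A"):
            pc.split_dataset(list(range(105)), labels=labels)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            pc.split_dataset(list(range(200)), (0.5, 0.2, 0.2),
                             labels=self.labels())


class TestBayesBaseline:
    def test_separable_classes(self):
        enc = make_encoded({"a": (0.1, 0.01), "b": (0.7, 0.01)}, 300, seed=1)
        tr, va, te = pc.split_dataset(enc, seed=0)
        model = pc.train_bayes_baseline(tr)
        pred, proba = pc.classify(model, te)
        truth = [e.label for e in te]
        assert np.mean(pred == np.array(truth, dtype=object)) >= 0.999

    def test_accuracy_near_analytic_bayes_limit(self):
        # G/A at the published Device #4 separation; the quadrature
        # oracle integrates min(f_G, f_A)/2 for the Bayes error
        enc = make_encoded({"G": (0.229, 0.016), "A": (0.295, 0.021)}, 1500, seed=2)
        tr, va, te = pc.split_dataset(enc, seed=0)
        model = pc.train_bayes_baseline(tr)
        pred, _ = pc.classify(model, te)
        acc = np.mean(pred == np.array([e.label for e in te], dtype=object))
        grid = np.linspace(0, 0.6, 20001)
        bayes_err = 0.5 * np.trapezoid(
            np.minimum(norm.pdf(grid, 0.229, 0.016), norm.pdf(grid, 0.295, 0.021)),
            grid,
        )
        assert acc == pytest.approx(1 - bayes_err, abs=0.03)

    def test_single_class_rejected(self):
        enc = make_encoded({"a": (0.2, 0.01)}, 50, seed=3)
        _, S, y = encode_frame(enc)
        with pytest.raises(ValidationError):
            pc.GaussianBayesClassifier().fit(S, y)

    def test_probabilities_sum_to_one(self, encoded_ga):
        tr, va, te = pc.split_dataset(encoded_ga, seed=0)
        model = pc.train_bayes_baseline(tr)
        _, proba = pc.classify(model, te)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_events_empty_output(self, encoded_ga):
        tr, va, te = pc.split_dataset(encoded_ga, seed=0)
        model = pc.train_bayes_baseline(tr)
        pred, proba = pc.classify(model, [])
        assert pred.size == 0 and proba.shape == (0, 2)

    def test_training_replay_at_least_heldout(self, encoded_ga):
        tr, va, te = pc.split_dataset(encoded_ga, seed=0)
        model = pc.train_bayes_baseline(tr)
        acc = lambda split: np.mean(
            pc.classify(model, split)[0]
            == np.array([e.label for e in split], dtype=object)
        )
        assert acc(tr) >= acc(te) - 0.02


def lstm_xy(encoded):
    W, S, y = encode_frame(encoded)
    return np.hstack([W, S]), y


class TestSequenceClassifier:
    def test_separable_sanity(self):
        enc = make_encoded({"a": (0.15, 0.01), "b": (0.55, 0.01)}, 250, seed=4)
        tr, va, te = pc.split_dataset(enc, seed=0)
        Xt, yt = lstm_xy(tr)
        Xv, yv = lstm_xy(va)
        Xe, ye = lstm_xy(te)
        model = SequenceClassifier(lstm_hidden=16, epochs=30, seed=0).fit(
            Xt, yt, Xv, yv
        )
        assert model.score(Xe, ye) >= 0.99

    def test_shuffled_labels_give_chance_accuracy(self):
        enc = make_encoded({"a": (0.2, 0.02), "b": (0.3, 0.02)}, 150, seed=5)
        rng = np.random.default_rng(0)
        labels = rng.permutation([e.label for e in enc])
        for e, l in zip(enc, labels):
            e.label = l
        tr, va, te = pc.split_dataset(enc, seed=0)
        Xt, yt = lstm_xy(tr)
        Xv, yv = lstm_xy(va)
        Xe, ye = lstm_xy(te)
        model = SequenceClassifier(lstm_hidden=12, epochs=15, seed=0).fit(
            Xt, yt, Xv, yv
        )
        assert abs(model.score(Xe, ye) - 0.5) <= 0.05

    def test_seeded_training_reproducible(self):
        enc = make_encoded({"a": (0.2, 0.02), "b": (0.3, 0.02)}, 100, seed=6)
        tr, va, te = pc.split_dataset(enc, seed=0)
        Xt, yt = lstm_xy(tr)
        Xv, yv = lstm_xy(va)
        accs = []
        for _ in range(2):
            m = SequenceClassifier(lstm_hidden=8, epochs=8, seed=7).fit(
                Xt, yt, Xv, yv
            )
            accs.append(m.best_val_accuracy_)
        assert accs[0] == accs[1]

    def test_probabilities_sum_to_one(self):
        enc = make_encoded({"a": (0.2, 0.02), "b": (0.35, 0.02)}, 60, seed=8)
        X, y = lstm_xy(enc)
        m = SequenceClassifier(lstm_hidden=8, epochs=3, seed=0).fit(X, y)
        np.testing.assert_allclose(m.predict_proba(X).sum(axis=1), 1.0, atol=1e-9)

    def test_encoding_length_mismatch_rejected(self):
        enc = make_encoded({"a": (0.2, 0.02), "b": (0.35, 0.02)}, 60, seed=9)
        X, y = lstm_xy(enc)
        m = SequenceClassifier(lstm_hidden=8, epochs=2, seed=0).fit(X, y)
        with pytest.raises(ValidationError):
            m.predict(X[:, :-3])

    def test_four_fc_layers_enforced(self):
        with pytest.raises(ValidationError):
            SequenceClassifierConfig(fc_widths=(8, 8, 8))

    def test_backprop_matches_numerical_gradients(self):
        cfg = SequenceClassifierConfig(lstm_hidden=5, fc_widths=(4, 4, 3, 3))
        sc = SequenceClassifier(cfg)
        rng = np.random.default_rng(0)
        B, L, K = 3, 7, 2
        Wv = rng.normal(0.7, 0.2, (B, L))
        S = rng.normal(0, 1, (B, 2))
        Y = np.eye(K)[rng.integers(0, K, B)]
        params = sc._init_weights(K, rng)
        p, cache = sc._forward(Wv, S, params, want_cache=True)
        grads = sc._backward(Wv, S, Y, params, p, cache)

        def loss():
            out = sc._forward(Wv, S, params)
            return -np.mean(np.sum(Y * np.log(out + 1e-12), axis=1))

        eps = 1e-6
        for key in params:
            flat = params[key].ravel()
            for i in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                up = loss()
                flat[i] = orig - eps
                down = loss()
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[key].ravel()[i]
                assert analytic == pytest.approx(numeric, rel=1e-3, abs=1e-8)

    def test_sequence_model_tracks_bayes_baseline(self):
        # on scalar-generated data the Bayes baseline is the information
        # ceiling; the sequence model must come within 5 points of it
        enc = make_encoded({"G": (0.229, 0.016), "A": (0.295, 0.021)}, 300, seed=10)
        tr, va, te = pc.split_dataset(enc, seed=0)
        bayes = pc.train_bayes_baseline(tr)
        bayes_acc = np.mean(
            pc.classify(bayes, te)[0]
            == np.array([e.label for e in te], dtype=object)
        )
        Xt, yt = lstm_xy(tr)
        Xv, yv = lstm_xy(va)
        Xe, ye = lstm_xy(te)
        seq = SequenceClassifier(lstm_hidden=16, epochs=40, seed=0).fit(
            Xt, yt, Xv, yv
        )
        assert seq.score(Xe, ye) >= bayes_acc - 0.05


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["a", "b", "a", "b"], dtype=object)
        rep = pc.evaluate(y, y)
        np.testing.assert_array_equal(rep.confusion, [[2, 0], [0, 2]])
        assert rep.average_accuracy == 1.0
        assert (rep.per_class["f1"] == 1.0).all()

    def test_degenerate_single_class_predictions(self):
        truth = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        pred = np.array(["a"] * 10, dtype=object)
        rep = pc.evaluate(pred, truth)
        assert rep.average_accuracy == 0.5
        assert rep.per_class.loc["a", "recall"] == 1.0
        assert rep.per_class.loc["b", "recall"] == 0.0
        assert rep.per_class.loc["b", "f1"] == 0.0

    def test_hand_computed_three_class_report(self):
        # confusion rows (true x predicted): (10,2,0), (1,8,1), (0,3,7)
        truth, pred = [], []
        for i, row in enumerate([(10, 2, 0), (1, 8, 1), (0, 3, 7)]):
            for j, count in enumerate(row):
                truth += ["abc"[i]] * count
                pred += ["abc"[j]] * count
        rep = pc.evaluate(np.array(pred, dtype=object), np.array(truth, dtype=object))
        assert rep.average_accuracy == pytest.approx(25 / 32)
        assert rep.per_class.loc["a", "precision"] == pytest.approx(10 / 11)
        assert rep.per_class.loc["a", "recall"] == pytest.approx(10 / 12)
        assert rep.per_class.loc["b", "precision"] == pytest.approx(8 / 13)
        assert rep.per_class.loc["b", "recall"] == pytest.approx(8 / 10)
        assert rep.per_class.loc["c", "f1"] == pytest.approx(
            2 * (7 / 8) * (7 / 10) / ((7 / 8) + (7 / 10))
        )

    def test_confusion_total_conserved(self, encoded_ga):
        tr, va, te = pc.split_dataset(encoded_ga, seed=0)
        model = pc.train_bayes_baseline(tr)
        pred, _ = pc.classify(model, te)
        rep = pc.evaluate(pred, [e.label for e in te])
        assert rep.confusion.sum() == len(te)
        np.testing.assert_array_equal(
            rep.confusion.sum(axis=1),
            [sum(e.label == c for e in te) for c in rep.classes],
        )

    def test_unseen_truth_label_rejected(self):
        with pytest.raises(ValidationError):
            pc.evaluate(np.array(["a"], dtype=object),
                        np.array(["z"], dtype=object), classes=["a", "b"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pc.evaluate(np.array(["a", "b"], dtype=object),
                        np.array(["a"], dtype=object))
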