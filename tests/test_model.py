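"""Fusion head, loss, training loop, persistence and prediction contracts."""

import numpy as np
import pytest
from sklearn.base import clone

from amhf.model import (
    FusionHead,
    MultiFunctionPeptideClassifier,
    branch_combination,
    fuse_forward,
    multilabel_loss,
    predict_records,
    tiny_classifier,
)


@pytest.fixture(scope="module")
def head():
    return FusionHead(12, (8,), 5, 0.2, np.random.default_rng(0))


class TestFusion:

    def test_probabilities_in_unit_interval(self, head):
        rng = np.random.default_rng(1)
        probs, labels = fuse_forward([rng.normal(size=(7, 12))], head)
        assert probs.shape == (7, 5)
        assert ((probs > 0) & (probs < 1)).all()
        assert set(np.unique(labels)) <= {0, 1}

    def test_threshold_tie_is_positive(self, head):
        probs = np.array([[0.5, 0.4999, 0.5001]])
        labels = (probs >= 0.5).astype(int)
        assert list(labels[0]) == [1, 0, 1]

    def test_all_branches_disabled(self, head):
        with pytest.raises(ValueError):
            fuse_forward([None, None, None], head)
        with pytest.raises(ValueError):
            FusionHead(0, (8,), 5, 0.2, np.random.default_rng(0))

    def test_ablation_names(self):
        assert branch_combination("2") == ("sequence",)
        assert branch_combination("23") == ("sequence", "hypergraph")
        assert branch_combination("123") == ("atomic", "sequence", "hypergraph")
        with pytest.raises(ValueError):
            branch_combination("4")


class TestLoss:
    def test_perfect_confident_predictions(self):
        y = np.array([[1, 0], [0, 1]])
        loss = multilabel_loss(y.astype(float), y)
        assert float(loss.data) <= 1e-6

    def test_uniform_half_is_ln2(self):
        y = np.array([[1, 0, 1]])
        loss = multilabel_loss(np.full((1, 3), 0.5), y)
        assert float(loss.data) == pytest.approx(np.log(2), abs=1e-6)

    def test_doubling_weight_doubles_class_term(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=(6, 3))
        p = rng.uniform(0.1, 0.9, size=(6, 3))
        w = np.ones(3)
        base = float(multilabel_loss(p, y, w).data)
        w2 = w.copy()
        w2[1] = 2.0
        boosted = float(multilabel_loss(p, y, w2).data)
        only1 = float(
            multilabel_loss(p[:, [1]], y[:, [1]], np.ones(1)).data
        )
        assert boosted == pytest.approx(base + only1 / 3, rel=1e-9)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            multilabel_loss(np.full((1, 2), 0.5), np.ones((1, 2)), np.array([1.0, 0.0]))


class TestTraining:
    def test_loss_decreases(self, tiny_model):
        clf, _, _ = tiny_model
        assert clf.history_[-1]["loss"] < clf.history_[0]["loss"]

    def test_sklearn_param_protocol(self):
        clf = tiny_classifier(random_state=1)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
        cloned.set_params(epochs=2)
        assert cloned.epochs == 2

    def test_rejects_bad_labels(self, small_dataset):
        clf = tiny_classifier(epochs=1)
        X = [r.sequence for r in small_dataset[:10]]
        with pytest.raises(ValueError):
            clf.fit(X, np.zeros((10, 4), dtype=int))  # empty label sets
        with pytest.raises(ValueError):
            clf.fit(X, np.full((10, 4), 2))

    def test_unknown_branch_rejected(self, small_dataset):
        clf = tiny_classifier(epochs=1, branches=("sequence", "tertiary"))
        y = np.stack([r.labels for r in small_dataset[:10]])
        with pytest.raises(ValueError):
            clf.fit(small_dataset[:10], y)


class TestPrediction:
    def test_deterministic_across_calls(self, tiny_model):
        clf, _, test = tiny_model
        a = clf.predict_proba(test)
        b = clf.predict_proba(test)
        assert np.array_equal(a, b)

    def test_batch_size_independence(self, tiny_model):
        clf, _, test = tiny_model
        full = clf.predict_proba(test)
        chunked = np.concatenate([clf.predict_proba(test[i : i + 3]) for i in range(0, len(test), 3)])
        assert np.abs(full - chunked).max() < 1e-6

    def test_threshold_consistency(self, tiny_model):
        clf, _, test = tiny_model
        probs = clf.predict_proba(test)
        labels = clf.predict(test)
        assert np.array_equal(labels, (probs >= clf.threshold).astype(labels.dtype))

    def test_short_sequences_become_error_entries(self, tiny_model):
        clf, _, test = tiny_model
        from amhf.io import PeptideRecord

        bad = PeptideRecord("tiny", "ACD", np.zeros(4, dtype=np.int8))
        results, errors = predict_records(clf, [test[0], bad, test[1]])
        assert len(results) == 2
        assert len(errors) == 1 and errors[0][0] == "tiny"

    def test_save_load_bit_identical(self, tiny_model, tmp_path):
        clf, _, test = tiny_model
        before = clf.predict_proba(test)
        path = tmp_path / "model.bin"
        clf.save(path)
        loaded = MultiFunctionPeptideClassifier.load(path)
        after = loaded.predict_proba(test)
        assert np.array_equal(before, after)
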