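"""Vectorization, CNN forward pass, metrics, CV protocol, corpus prediction."""

import dataclasses

import numpy as np
import pytest

from topicrisk import synthetic
from topicrisk.classifier import (
    ClassifierConfig, CNNParams, LabeledDataset, MetricsReport,
    cross_validate, evaluate, forward, predict_corpus, predict_proba,
    train_classifier, vectorize,
)
from topicrisk.embedding import TrainingConfig, train
from .conftest import comment, make_model


@pytest.fixture(scope="module")
def sep_model():
    """Embedding with two well-separated directions for pos/neg words."""
    vecs = {}
    rng = np.random.default_rng(0)
    for i in range(10):
        vecs[f"pos{i}"] = [1.0, 0.0] + list(0.05 * rng.normal(size=2))
        vecs[f"neg{i}"] = [0.0, 1.0] + list(0.05 * rng.normal(size=2))
    return make_model(vecs)


def make_separable(n=20, seed=0):
    rng = np.random.default_rng(seed)
    comments = []
    for i in range(n):
        label = i % 2
        stem = "pos" if label else "neg"
        toks = [f"{stem}{rng.integers(10)}" for _ in range(6)]
        comments.append(comment(toks, cid=f"s{i}", label=label))
    return LabeledDataset(comments)


class TestVectorize:
    def test_padding_rows_zero(self, sep_model):
        cfg = ClassifierConfig(max_len=5, kernel_sizes=(2,))
        c = comment(["pos0", "pos1", "pos2"])
        mat = vectorize(c, sep_model, cfg)
        assert mat.shape == (5, 4)
        assert np.all(mat[3:] == 0)
        assert np.any(mat[:3] != 0)

    def test_empty_tokens_all_zero(self, sep_model):
        cfg = ClassifierConfig(max_len=4, kernel_sizes=(2,))
        assert np.all(vectorize(comment([]), sep_model, cfg) == 0)

    def test_rows_equal_exported_vectors(self, sep_model):
        cfg = ClassifierConfig(max_len=6, kernel_sizes=(2,))
        toks = ["pos0", "neg3", "pos7", "neg1"]
        mat = vectorize(comment(toks), sep_model, cfg)
        for i, t in enumerate(toks):
            assert np.array_equal(mat[i], sep_model.vector(t))

    def test_truncation_at_tail(self, sep_model):
        cfg = ClassifierConfig(max_len=2, kernel_sizes=(2,))
        toks = ["pos0", "pos1", "pos2", "pos3"]
        mat = vectorize(comment(toks), sep_model, cfg)
        assert np.array_equal(mat[0], sep_model.vector("pos0"))
        assert np.array_equal(mat[1], sep_model.vector("pos1"))

    def test_oov_maps_to_zero_row(self, sep_model):
        cfg = ClassifierConfig(max_len=3, kernel_sizes=(2,))
        mat = vectorize(comment(["pos0", "zzz"]), sep_model, cfg)
        assert np.all(mat[1] == 0)


class TestForward:
    def test_zero_input_zero_affine_gives_half(self):
        cfg = ClassifierConfig(max_len=4, kernel_sizes=(2,),
                               filters_per_size=3)
        rng = np.random.default_rng(0)
        params = CNNParams.initialize(2, cfg, rng)
        params.w_affine[:] = 0.0
        params.b_affine[:] = 0.0
        assert forward(np.zeros((4, 2)), params) == pytest.approx(0.5)

    def test_probabilities_sum_to_one(self):
        cfg = ClassifierConfig(max_len=6, kernel_sizes=(2, 3),
                               filters_per_size=4)
        rng = np.random.default_rng(1)
        params = CNNParams.initialize(3, cfg, rng)
        from topicrisk.classifier import _forward_batch
        X = rng.normal(size=(5, 6, 3))
        probs, _ = _forward_batch(X, params)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_executed_convolution(self):
        # single kernel of size 1, single filter, 2x2 input, hand-set weights
        cfg = ClassifierConfig(max_len=2, kernel_sizes=(1,),
                               filters_per_size=1, dropout=0.0)
        rng = np.random.default_rng(0)
        params = CNNParams.initialize(2, cfg, rng)
        params.kernels[1] = np.array([[1.0], [2.0]])   # w = (1, 2)
        params.biases[1] = np.array([0.5])
        params.w_affine = np.array([[1.0, -1.0]])
        params.b_affine = np.array([0.0, 0.0])
        X = np.array([[1.0, 2.0], [3.0, -1.0]])
        # positions: 1*1+2*2+0.5 = 5.5 ; 1*3+2*(-1)+0.5 = 1.5 -> max 5.5
        # logits (5.5, -5.5); P(1) = e^-5.5/(e^5.5+e^-5.5)
        expected = np.exp(-5.5) / (np.exp(5.5) + np.exp(-5.5))
        assert forward(X, params) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_raises(self):
        cfg = ClassifierConfig(max_len=4, kernel_sizes=(2,))
        params = CNNParams.initialize(2, cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="rows"):
            forward(np.zeros((3, 2)), params)

    def test_invariant_to_extra_zero_padding(self, sep_model):
        # widening max_len only adds zero rows; pooled features unchanged
        c = comment(["pos0", "neg1", "pos2"])
        probs = []
        for max_len in (6, 10, 16):
            cfg = ClassifierConfig(max_len=max_len, kernel_sizes=(2, 3),
                                   filters_per_size=4, rng_seed=5)
            params = CNNParams.initialize(4, cfg, np.random.default_rng(5))
            probs.append(forward(vectorize(c, sep_model, cfg), params))
        assert probs[0] == pytest.approx(probs[1], abs=1e-12)
        assert probs[0] == pytest.approx(probs[2], abs=1e-12)


class TestMetrics:
    def test_hand_computed_report(self):
        r = MetricsReport(tp=8, fp=2, fn=1, tn=9)
        assert r.precision == pytest.approx(0.800, abs=5e-4)
        assert r.recall == pytest.approx(0.889, abs=5e-4)
        assert r.accuracy == pytest.approx(0.850, abs=5e-4)
        assert r.f1 == pytest.approx(0.842, abs=5e-4)

    def test_perfect_predictions(self):
        r = MetricsReport(tp=5, fp=0, fn=0, tn=5)
        assert (r.accuracy, r.precision, r.recall, r.f1) == (1, 1, 1, 1)

    def test_all_positive_predictor_on_balanced_data(self):
        r = MetricsReport(tp=10, fp=10, fn=0, tn=0)
        assert r.recall == 1.0 and r.precision == 0.5

    @pytest.mark.parametrize("tp,fp,fn,tn", [
        (3, 1, 2, 4), (0, 0, 5, 5), (7, 3, 0, 0), (1, 1, 1, 1)])
    def test_identities_hold_exactly(self, tp, fp, fn, tn):
        r = MetricsReport(tp, fp, fn, tn)
        n = tp + fp + fn + tn
        assert r.accuracy == (tp + tn) / n
        assert r.precision == (tp / (tp + fp) if tp + fp else 0.0)
        assert r.recall == (tp / (tp + fn) if tp + fn else 0.0)
        p, rc = r.precision, r.recall
        assert r.f1 == (2 * p * rc / (p + rc) if p + rc else 0.0)


class TestTraining:
    CFG = ClassifierConfig(max_len=8, kernel_sizes=(2,), filters_per_size=8,
                           dropout=0.0, epochs=50, batch_size=8, rng_seed=0)

    def test_overfits_separable_set(self, sep_model):
        ds = make_separable()
        params = train_classifier(ds, sep_model, self.CFG)
        rep = evaluate(params, ds, sep_model, self.CFG)
        assert rep.accuracy == 1.0

    def test_same_seed_identical_parameters(self, sep_model):
        ds = make_separable()
        cfg = dataclasses.replace(self.CFG, epochs=5)
        a = train_classifier(ds, sep_model, cfg)
        b = train_classifier(ds, sep_model, cfg)
        for pa, pb in zip(a.flat(), b.flat()):
            assert np.array_equal(pa, pb)

    def test_label_inversion_kills_recall(self, sep_model):
        ds = make_separable()
        flipped = LabeledDataset([
            dataclasses.replace(c, label=1 - c.label) for c in ds.comments])
        params = train_classifier(flipped, sep_model, self.CFG)
        rep = evaluate(params, ds, sep_model, self.CFG)
        assert rep.recall <= 0.1

    def test_single_class_raises(self, sep_model):
        ds = LabeledDataset([comment(["pos0"] * 4, cid=str(i), label=1)
                             for i in range(6)])
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(ds, sep_model, self.CFG)


class TestCrossValidate:
    def test_partition_properties(self, sep_model):
        ds = make_separable(n=100)
        cfg = dataclasses.replace(TestTraining.CFG, epochs=2)
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=10, shuffle=True,
                              random_state=cfg.rng_seed)
        y = ds.labels
        seen = []
        for tr, va in skf.split(np.zeros(len(y)), y):
            assert len(va) == 10
            assert set(tr) | set(va) == set(range(100))
            assert not set(tr) & set(va)
            # stratification within one item of the global ratio
            assert abs(y[va].sum() - 5) <= 1
            seen.extend(va)
        assert sorted(seen) == list(range(100))

    def test_mean_equals_arithmetic_mean_of_folds(self, sep_model):
        ds = make_separable(n=60)
        cfg = dataclasses.replace(TestTraining.CFG, epochs=3)
        reports, mean = cross_validate(ds, sep_model, cfg, folds=3)
        assert len(reports) == 3
        assert mean["accuracy"] == pytest.approx(
            np.mean([r.accuracy for r in reports]))
        assert mean["recall"] == pytest.approx(
            np.mean([r.recall for r in reports]))

    def test_degenerate_folds_raise(self, sep_model):
        ds = make_separable(n=20)
        with pytest.raises(ValueError):
            cross_validate(ds, sep_model, TestTraining.CFG, folds=1)

    def test_too_few_items_raise(self, sep_model):
        ds = make_separable(n=10)
        with pytest.raises(ValueError, match="fewer than"):
            cross_validate(ds, sep_model, TestTraining.CFG, folds=10)


class TestPredictCorpus:
    def test_threshold_zero_flags_all(self, sep_model):
        ds = make_separable()
        cfg = dataclasses.replace(TestTraining.CFG, epochs=2,
                                  decision_threshold=0.0)
        params = train_classifier(ds, sep_model, cfg)
        flagged = predict_corpus(params, ds.comments, sep_model, cfg)
        assert len(flagged) == len(ds)

    def test_threshold_one_flags_only_certainty(self, sep_model):
        ds = make_separable()
        cfg = dataclasses.replace(TestTraining.CFG, epochs=2,
                                  decision_threshold=1.0)
        params = train_classifier(ds, sep_model, cfg)
        flagged = predict_corpus(params, ds.comments, sep_model, cfg)
        probs = predict_proba(params, ds.comments, sep_model, cfg)
        assert len(flagged) == int((probs >= 1.0).sum())

    def test_flagged_fraction_tracks_positive_rate(self):
        gen = synthetic.GeneratorConfig(
            n_comments=300, risk_fraction=0.3, ultrashort_fraction=0.0,
            words_per_topic=20, background_vocab_size=80, rng_seed=7)
        comments, truth, tdict = synthetic.generate_corpus(gen)
        model = train(comments, tdict,
                      TrainingConfig(dimension=16, epochs=3, rng_seed=7))
        ds = LabeledDataset(comments)
        cfg = ClassifierConfig(max_len=16, kernel_sizes=(2, 3),
                               filters_per_size=16, rng_seed=7)
        params = train_classifier(ds, model, cfg)
        flagged = predict_corpus(params, comments, model, cfg)
        frac = len(flagged) / len(comments)
        assert abs(frac - 0.3) <= 0.1
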