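"""Classifier head, metrics, training loop and cross-validation."""
import numpy as np
import pytest

from kgrex import (
    ClassifierParams,
    CorpusSpec,
    EvalReport,
    LabelScheme,
    TrainConfig,
    concat_features,
    cross_entropy,
    cross_validate,
    evaluate,
    generate_corpus,
    predict,
    train_model,
)
from kgrex.errors import ValidationError
from kgrex.model import build_model
from kgrex.encoder import build_tables

SMALL = dict(word_dim=16, pos_dim=4, hidden=8, kg_dim=4, max_distance=32, heads=2)

# multi-class confusion matrix reported for the attention-only model on one
# evaluation fold (gold rows x predicted columns)
ONE_FOLD_CONFUSION = np.array(
    [
        [721, 7, 10, 16, 32],
        [74, 168, 0, 4, 2],
        [22, 0, 57, 0, 13],
        [16, 0, 0, 55, 0],
        [49, 1, 0, 0, 302],
    ]
)


class TestConcatFeatures:
    def test_default_dimension_is_500(self, rng):
        B = rng.normal(size=400)
        z = concat_features(B, rng.normal(size=50), rng.normal(size=50), k=50)
        assert z.shape == (500,)

    def test_absent_slots_zero_filled(self, rng):
        B = rng.normal(size=6)
        z = concat_features(B, None, None, k=3)
        assert np.array_equal(z[6:], np.zeros(6))

    def test_order_is_positional(self, rng):
        B = rng.normal(size=4)
        dg, dm = rng.normal(size=2), rng.normal(size=2)
        a = concat_features(B, dg, dm, k=2)
        b = concat_features(B, dm, dg, k=2)
        assert not np.array_equal(a, b)
        assert np.array_equal(a[4:6], dg) and np.array_equal(a[6:], dm)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValidationError):
            concat_features(rng.normal(size=4), np.zeros(3), None, k=2)


class TestPredict:
    def test_zero_weights_give_uniform(self):
        clf = ClassifierParams(W=np.zeros((5, 7)), b=np.zeros(5))
        assert np.allclose(predict(np.ones(7), clf), 0.2)

    def test_closed_form_two_class(self):
        # logits (ln 2, 0) -> (2/3, 1/3)
        clf = ClassifierParams(W=np.zeros((2, 1)), b=np.array([np.log(2), 0.0]))
        assert np.allclose(predict(np.zeros(1), clf), [2 / 3, 1 / 3])

    def test_logit_shift_invariance(self, rng):
        W = rng.normal(size=(3, 4))
        z = rng.normal(size=4)
        a = predict(z, ClassifierParams(W=W, b=np.zeros(3)))
        b = predict(z, ClassifierParams(W=W, b=np.full(3, 7.5)))
        assert np.allclose(a, b, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        clf = ClassifierParams(W=rng.normal(size=(5, 6)) * 10, b=rng.normal(size=5))
        p = predict(rng.normal(size=6), clf)
        assert p.sum() == pytest.approx(1.0, abs=1e-9) and (p > 0).all()

    def test_shape_mismatch(self):
        clf = ClassifierParams(W=np.zeros((2, 3)), b=np.zeros(2))
        with pytest.raises(ValidationError):
            predict(np.zeros(4), clf)


class TestCrossEntropy:
    def test_certain_prediction_is_zero(self):
        assert cross_entropy(np.array([1.0, 0.0]), 0) == 0.0

    def test_uniform_five_class(self):
        assert cross_entropy(np.full(5, 0.2), 3) == pytest.approx(np.log(5))

    def test_batch_mean(self):
        probs = np.array([[1.0, 0.0, 0.0, 0.0, 0.0], [0.2, 0.2, 0.2, 0.2, 0.2]])
        assert cross_entropy(probs, [0, 1]) == pytest.approx(np.log(5) / 2)


class TestEvalReport:
    def test_perfect_predictions(self):
        rep = EvalReport.from_predictions([0, 1, 2], [0, 1, 2], [10, 50, 80], "abc")
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0
        assert np.array_equal(rep.confusion, np.eye(3, dtype=int))
        assert rep.bucket_accuracy == {"0-45": 1.0, "45-75": 1.0, "75-": 1.0}

    def test_all_one_class_on_balanced_binary(self):
        # accuracy 1/2; F1 = (2*0.5*1/(1.5) + 0)/2 = 1/3
        rep = EvalReport.from_predictions([0, 0, 1, 1], [0, 0, 0, 0], [1] * 4, "ab")
        assert rep.accuracy == 0.5
        assert rep.macro_f1 == pytest.approx(1 / 3)

    def test_one_fold_confusion_arithmetic(self):
        rep = EvalReport.from_confusion(ONE_FOLD_CONFUSION, list("abcde"))
        # independent hand-sum oracle
        assert ONE_FOLD_CONFUSION.sum() == 1549
        assert np.trace(ONE_FOLD_CONFUSION) == 1303
        assert rep.accuracy == pytest.approx(1303 / 1549)

    def test_macro_f1_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score

        gold = rng.integers(0, 4, 200)
        pred = rng.integers(0, 3, 200)  # class 3 never predicted
        rep = EvalReport.from_predictions(gold, pred, np.full(200, 10), "abcd")
        expect = f1_score(gold, pred, labels=range(4), average="macro", zero_division=0)
        assert rep.macro_f1 == pytest.approx(expect)

    def test_confusion_totals_conserved(self, rng):
        gold = rng.integers(0, 5, 300)
        pred = rng.integers(0, 5, 300)
        rep = EvalReport.from_predictions(gold, pred, rng.integers(1, 100, 300), "abcde")
        assert rep.confusion.sum() == 300
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / 300)
        assert sum(rep.bucket_counts.values()) == 300


class TestTrainConfig:
    def test_defaults_mirror_reference_design(self):
        cfg = TrainConfig()
        assert (cfg.batch_size, cfg.learning_rate, cfg.epochs, cfg.heads) == (6, 0.001, 10, 4)
        assert (cfg.word_dim, cfg.pos_dim, cfg.hidden, cfg.kg_dim) == (200, 50, 200, 50)
        assert cfg.model_dim == 400
        assert cfg.recurrent_dropout == cfg.output_dropout == 0.5

    def test_unknown_config_key_rejected(self, tmp_path):
        f = tmp_path / "cfg.yaml"
        f.write_text("epochs: 2\nbogus_key: 1\n")
        with pytest.raises(ValidationError, match="bogus_key"):
            TrainConfig.from_file(f)

    def test_file_round_trip(self, tmp_path):
        f = tmp_path / "cfg.yaml"
        f.write_text("epochs: 3\nhidden: 16\npooling: mean\n")
        cfg = TrainConfig.from_file(f)
        assert (cfg.epochs, cfg.hidden, cfg.pooling) == (3, 16, "mean")

    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(epochs=0)
        with pytest.raises(ValidationError):
            TrainConfig(recurrent_dropout=1.0)


@pytest.fixture(scope="module")
def trained_toy():
    """One small trained model shared across training-behavior tests."""
    spec = CorpusSpec(n_instances=60, vocab_size=60, scheme=LabelScheme.binary(),
                      signal_strength=1.0, rng_seed=5)
    data = generate_corpus(spec)
    cfg = TrainConfig(**SMALL, epochs=3, rng_seed=3)
    train, test = data.subset(range(45)), data.subset(range(45, 60))
    model = train_model(train, None, None, None, cfg)
    return model, train, test


class TestTraining:
    def test_empty_train_rejected(self, tiny_corpus):
        with pytest.raises(ValidationError):
            train_model(tiny_corpus.subset([]), None, None, None, TrainConfig(**SMALL))

    def test_deterministic_given_seed(self, trained_toy):
        model, train, test = trained_toy
        cfg = TrainConfig(**SMALL, epochs=3, rng_seed=3)
        again = train_model(train, None, None, None, cfg)
        for a, b in zip(model.parameters().values(), again.parameters().values()):
            assert np.array_equal(a, b)

    def test_evaluation_scheme_mismatch(self, trained_toy, tiny_corpus):
        model, _, _ = trained_toy
        with pytest.raises(ValidationError, match="scheme"):
            evaluate(model, tiny_corpus)  # multiclass data, binary model

    def test_probabilities_valid(self, trained_toy):
        model, _, test = trained_toy
        for inst in test.instances[:5]:
            p = model.predict_proba(inst)
            assert p.sum() == pytest.approx(1.0, abs=1e-9) and (p >= 0).all()

    def test_zeroed_kg_columns_reproduce_no_kg_logits(self, trained_toy):
        model, _, test = trained_toy
        inst = test.instances[0]
        d = model.config.model_dim
        model.clf.W[:, d:] = 0.0  # silence the KG feature coordinates
        base = model.predict_proba(inst)
        # attach KG side information; zero classifier weight makes it inert
        from kgrex import KGSpec, generate_kg, train_embeddings

        kg, _ = generate_kg(KGSpec(n_drugs=5, n_relations=2, triples_per_relation=3,
                                   k_true=4, rng_seed=0))
        model.kg_params = train_embeddings(kg, "transE", k=4, epochs=2, rng_seed=0)
        model.config.kg_for_binary = True
        assert np.allclose(model.predict_proba(inst), base, atol=1e-12)
        model.kg_params = None
        model.config.kg_for_binary = False


class TestCrossValidate:
    def test_mean_is_mean_of_fold_accuracies(self):
        spec = CorpusSpec(n_instances=40, vocab_size=60, scheme=LabelScheme.binary(),
                          signal_strength=1.0, rng_seed=8)
        data = generate_corpus(spec)
        cfg = TrainConfig(**SMALL, epochs=1, rng_seed=1)
        res = cross_validate(data, None, None, cfg, k=2, validation_size=0)
        accs = [r.accuracy for r in res["reports"]]
        assert len(accs) == 2
        assert res["mean_accuracy"] == pytest.approx(np.mean(accs))
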