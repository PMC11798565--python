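"""MLP initialisation/forward/training, evaluation harness, oracle classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prevadjust as pa
from prevadjust.classifier import (
    FeatureEncoder,
    init_model,
    stratified_fold_indices,
)


def brute_force_auc(scores, truth):
    """All-pairs Mann-Whitney AUC oracle: P(pos > neg) + 0.5 P(tie)."""
    s = np.asarray(scores, float)
    y = np.asarray(truth, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def make_model(weights, biases, threshold=0.5):
    spec = pa.MlpSpec(tuple(w.shape[1] for w in weights[:-1]))
    return pa.TrainedModel(spec=spec, weights=[np.asarray(w, float) for w in weights],
                           biases=[np.asarray(b, float) for b in biases],
                           threshold=threshold)


class TestInit:
    def test_weight_shapes_match_architecture(self):
        model = init_model(pa.MlpSpec(), input_width=100, seed=0)
        shapes = [w.shape for w in model.weights]
        assert shapes == [(100, 128), (128, 64), (64, 32), (32, 16), (16, 8), (8, 1)]
        assert all((b == 0).all() for b in model.biases)

    def test_he_variance(self):
        model = init_model(pa.MlpSpec(), input_width=100, seed=1)
        v = model.weights[0].var()
        assert abs(v - 2 / 100) < 0.2 * (2 / 100)
        v2 = model.weights[1].var()  # fan_in 128
        assert abs(v2 - 2 / 128) < 0.2 * (2 / 128)

    def test_seed_determinism(self):
        a = init_model(pa.MlpSpec(), 30, seed=5)
        b = init_model(pa.MlpSpec(), 30, seed=5)
        assert all((x == y).all() for x, y in zip(a.weights, b.weights))

    def test_bad_layer_size_rejected(self):
        with pytest.raises(pa.ValidationError):
            pa.MlpSpec((128, 0, 8))
        with pytest.raises(pa.ValidationError):
            init_model(pa.MlpSpec(), 0, seed=0)


class TestForward:
    def test_zero_network_outputs_half(self):
        m = make_model([np.zeros((3, 4)), np.zeros((4, 1))], [np.zeros(4), np.zeros(1)])
        out = pa.forward(m, np.zeros((5, 3)))
        assert np.allclose(out, 0.5)

    def test_hand_network_closed_form(self):
        # single hidden unit, unit weights, zero biases: sigmoid(relu(x))
        m = make_model([np.ones((1, 1)), np.ones((1, 1))], [np.zeros(1), np.zeros(1)])
        assert pa.forward(m, np.array([[0.0]]))[0] == pytest.approx(0.5)
        assert pa.forward(m, np.array([[2.0]]))[0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)
        assert pa.forward(m, np.array([[2.0]]))[0] == pytest.approx(0.8808, abs=1e-4)

    def test_width_mismatch_rejected(self):
        m = make_model([np.zeros((3, 2)), np.zeros((2, 1))], [np.zeros(2), np.zeros(1)])
        with pytest.raises(pa.ValidationError, match="width"):
            pa.forward(m, np.zeros((2, 4)))

    def test_outputs_strictly_inside_unit_interval(self):
        model = init_model(pa.MlpSpec((8, 4)), 6, seed=2)
        out = pa.forward(model, np.random.default_rng(0).normal(size=(50, 6)) * 100)
        assert ((out > 0) & (out < 1)).all()

    def test_nonnegative_weights_monotone_in_inputs(self):
        """With all-nonnegative weights, raising any input coordinate cannot
        lower the output probability (ReLU and sigmoid are monotone)."""
        rng = np.random.default_rng(3)
        weights = [np.abs(rng.normal(size=s)) for s in [(4, 8), (8, 4), (4, 1)]]
        biases = [rng.normal(size=s[1]) for s in [(4, 8), (8, 4), (4, 1)]]
        m = make_model(weights, biases)
        x = rng.normal(size=(20, 4))
        base = pa.forward(m, x)
        for j in range(4):
            bumped = x.copy()
            bumped[:, j] += 0.7
            assert (pa.forward(m, bumped) >= base - 1e-12).all()


class TestTraining:
    def test_linearly_separable_toy_set_fits_perfectly(self):
        # 20 rows separable on a single feature with a wide margin
        x = np.concatenate([np.linspace(-3, -1, 10), np.linspace(1, 3, 10)])
        table = pd.DataFrame({"x": x})
        y = np.array([0] * 10 + [1] * 10)
        model = pa.train(pa.MlpSpec((8,)), table, y, seed=0,
                         hyperparams=pa.Hyperparams(max_epochs=300, patience=300,
                                                    val_fraction=0.2, batch_size=4))
        assert (pa.classify(model, table) == y).mean() == 1.0

    def test_development_set_shape_reaches_auc(self, dev_set):
        """223 cases / 1776 controls: held-out AUC of the trained MLP >= 0.8."""
        names = pa.default_schema().names
        y = (dev_set["latent_class"] == "sz").astype(int)
        model = pa.train(pa.MlpSpec(), dev_set[names], y, seed=0,
                         hyperparams=pa.Hyperparams(max_epochs=60))
        test = pd.DataFrame({"id": np.arange(2000),
                             "latent_class": np.array(["sz"] * 400 + ["healthy"] * 1600,
                                                      dtype=object)})
        test = pa.generate_features(test, pa.default_schema(), seed=77)
        m = pa.evaluate(pa.forward(model, test[names]),
                        (test["latent_class"] == "sz").astype(int))
        assert m.auc >= 0.8

    def test_no_signal_features_give_chance_auc(self):
        classes = np.array(["sz"] * 300 + ["healthy"] * 1700, dtype=object)
        df = pd.DataFrame({"id": np.arange(2000), "latent_class": classes})
        df = pa.generate_features(df, pa.null_schema(), seed=5)
        names = pa.null_schema().names
        y = (df["latent_class"] == "sz").astype(int)
        model = pa.train(pa.MlpSpec((16, 8)), df[names], y, seed=1,
                         hyperparams=pa.Hyperparams(max_epochs=20))
        test = pd.DataFrame({"id": np.arange(2000), "latent_class": classes})
        test = pa.generate_features(test, pa.null_schema(), seed=6)
        m = pa.evaluate(pa.forward(model, test[names]),
                        (test["latent_class"] == "sz").astype(int))
        assert 0.4 <= m.auc <= 0.6

    def test_training_loss_decreases(self, dev_set):
        names = pa.default_schema().names
        y = (dev_set["latent_class"] == "sz").astype(int)
        model = pa.train(pa.MlpSpec((16,)), dev_set[names], y, seed=0,
                         hyperparams=pa.Hyperparams(max_epochs=15, patience=15))
        assert model.loss_history[-1] < model.loss_history[0]

    def test_seeded_reproducibility(self, dev_set):
        names = pa.default_schema().names
        y = (dev_set["latent_class"] == "sz").astype(int)
        hp = pa.Hyperparams(max_epochs=3, patience=3)
        a = pa.train(pa.MlpSpec((8,)), dev_set[names], y, hyperparams=hp, seed=4)
        b = pa.train(pa.MlpSpec((8,)), dev_set[names], y, hyperparams=hp, seed=4)
        assert all((x == y_).all() for x, y_ in zip(a.weights, b.weights))

    def test_single_class_labels_rejected(self, dev_set):
        names = pa.default_schema().names
        with pytest.raises(pa.ValidationError, match="single class"):
            pa.train(pa.MlpSpec((4,)), dev_set[names], np.zeros(len(dev_set)), seed=0)


class TestClassify:
    def test_threshold_boundary_is_inclusive(self):
        # identity network: hidden units relu(x) and relu(-x), recombined
        # to x, so the output is sigmoid(x) for either sign of x
        m = make_model([np.array([[1.0, -1.0]]), np.array([[1.0], [-1.0]])],
                       [np.zeros(2), np.zeros(1)])
        logit = lambda p: np.log(p / (1 - p))
        x = np.array([[logit(0.49)], [logit(0.5)], [logit(0.51)]])
        assert pa.classify(m, x).tolist() == [0, 1, 1]

    def test_zero_model_all_positive_at_default_threshold(self):
        m = make_model([np.zeros((2, 2)), np.zeros((2, 1))], [np.zeros(2), np.zeros(1)])
        assert pa.classify(m, np.zeros((4, 2))).tolist() == [1, 1, 1, 1]

    def test_threshold_one_labels_nothing(self):
        m = make_model([np.zeros((2, 2)), np.zeros((2, 1))], [np.zeros(2), np.zeros(1)],
                       threshold=1.0)
        assert pa.classify(m, np.zeros((4, 2))).sum() == 0


class TestEvaluate:
    def test_perfect_separation(self):
        m = pa.evaluate(np.array([0.9, 0.8, 0.2, 0.1]), [1, 1, 0, 0])
        assert m.auc == 1.0 and m.accuracy == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_six_pair_example(self):
        # positives {0.9, 0.8}, negatives {0.7, 0.1}: AUC 1
        assert pa.evaluate([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]).auc == 1.0
        # adding a negative at 0.85 loses one of six pairs: AUC 5/6
        m = pa.evaluate([0.9, 0.8, 0.85, 0.7, 0.1], [1, 1, 0, 0, 0])
        assert m.auc == pytest.approx(5 / 6)

    def test_constant_scores_give_half(self):
        assert pa.evaluate([0.3] * 6, [1, 0, 1, 0, 0, 1]).auc == 0.5

    def test_single_class_truth_rejected(self):
        with pytest.raises(pa.ValidationError):
            pa.evaluate([0.1, 0.9], [1, 1])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 200)
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # forces ties
        truth = rng.integers(0, 2, size=n)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        assert pa.evaluate(scores, truth).auc == pytest.approx(
            brute_force_auc(scores, truth), abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        truth = rng.integers(0, 2, size=60)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        a = pa.evaluate(scores, truth).auc
        b = pa.evaluate(np.exp(3 * scores) + 5, truth).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestCrossValidation:
    def test_fold_sizes_partition_the_data(self):
        y = np.array([1] * 223 + [0] * 1777)
        folds = stratified_fold_indices(y, k=10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sum(sizes) == 2000
        assert all(s == 200 for s in sizes)
        assert len(np.unique(np.concatenate(folds))) == 2000

    def test_mean_fold_auc_close_to_single_split(self, dev_set):
        """CV mean AUC within 0.05 of a fixed held-out split AUC."""
        names = pa.default_schema().names
        y = (dev_set["latent_class"] == "sz").astype(int).to_numpy()
        hp = pa.Hyperparams(max_epochs=25)
        cv = pa.cross_validate(pa.MlpSpec((32, 16)), dev_set[names], y, k=5, seed=0,
                               hyperparams=hp)
        assert len(cv.fold_aucs) == 5
        model = pa.train(pa.MlpSpec((32, 16)), dev_set[names], y, hyperparams=hp, seed=0)
        test = pd.DataFrame({"id": np.arange(2000),
                             "latent_class": np.array(["sz"] * 250 + ["healthy"] * 1750,
                                                      dtype=object)})
        test = pa.generate_features(test, pa.default_schema(), seed=33)
        single = pa.evaluate(pa.forward(model, test[names]),
                             (test["latent_class"] == "sz").astype(int)).auc
        assert abs(np.mean(cv.fold_aucs) - single) < 0.05


class TestOracle:
    def test_all_zero_rates(self):
        df = pd.DataFrame({"latent_class": ["sz", "healthy", "mdd"] * 5})
        labels = pa.oracle_classify(df, {c: 0.0 for c in pa.LATENT_CLASSES}, seed=0)
        assert labels.sum() == 0

    def test_indicator_rates(self):
        df = pd.DataFrame({"latent_class": ["sz", "healthy", "bd", "sz"] * 10})
        rates = {c: 0.0 for c in pa.LATENT_CLASSES} | {"sz": 1.0}
        labels = pa.oracle_classify(df, rates, seed=0)
        assert (labels == (df["latent_class"] == "sz").astype(int)).all()

    def test_external_validation_shape(self):
        """61 sz / 56 mdd / 32 bd / 1 other at the published rates: the
        expected schizophrenia positives are 61 * 46/61 = 46, and the
        observed count over many seeds stays within binomial error."""
        df = pd.DataFrame({"latent_class": ["sz"] * 61 + ["mdd"] * 56 + ["bd"] * 32 + ["other"]})
        counts = [pa.oracle_classify(df, seed=s)[:61].sum() for s in range(50)]
        sd = np.sqrt(61 * (46 / 61) * (15 / 61))
        assert abs(np.mean(counts) - 46) < 4 * sd / np.sqrt(50)

    def test_per_class_rates_converge(self):
        n = 10_000
        df = pd.DataFrame({"latent_class": np.repeat(pa.LATENT_CLASSES, n)})
        labels = pa.oracle_classify(df, seed=12)
        for i, cls in enumerate(pa.LATENT_CLASSES):
            r = pa.EXTERNAL_VALIDATION_RATES[cls]
            got = labels[i * n:(i + 1) * n].mean()
            sd = np.sqrt(r * (1 - r) / n)
            assert abs(got - r) <= 4 * sd + 1e-12, cls

    def test_missing_class_rate_rejected(self):
        df = pd.DataFrame({"latent_class": ["sz", "other"]})
        with pytest.raises(pa.ValidationError, match="other"):
            pa.oracle_classify(df, {"sz": 0.5}, seed=0)


class TestModelArchive:
    def test_save_load_round_trip(self, dev_set, tmp_path):
        names = pa.default_schema().names
        y = (dev_set["latent_class"] == "sz").astype(int)
        model = pa.train(pa.MlpSpec((8,)), dev_set[names], y, seed=0,
                         hyperparams=pa.Hyperparams(max_epochs=2, patience=2))
        path = tmp_path / "model.json"
        pa.save_model(model, path)
        back = pa.load_model(path)
        x = dev_set[names].head(20)
        assert np.allclose(pa.forward(model, x), pa.forward(back, x))
        assert back.threshold == model.threshold
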