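"""Grammar construction, node rules, undersampling and training contracts."""

import numpy as np
import pytest

from pentail.errors import BalanceError, ConfigurationError
from pentail.models import (
    ModelSpec,
    balance_undersample,
    build_model,
    node_count,
    parameter_count,
    predict_proba,
    train,
    units_per_layer,
)
from pentail.sequences import SequenceSet


class TestNodeCount:
    @pytest.mark.parametrize(
        "rule,width,expected",
        [
            ("sum", 64, 66),
            ("mean", 256, 129),
            ("half_mean", 4, 2),     # round(1.5) = 2 under round-half-to-even
            ("mean", 4, 3),
            ("half_mean", 512, 128), # round(128.5) = 128
            ("sum", 3485, 3487),
        ],
    )
    def test_rule_arithmetic(self, rule, width, expected):
        assert node_count(rule, width) == expected

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            node_count("median", 8)

    def test_minimum_one_node(self):
        assert node_count("half_mean", 1) >= 1

    @pytest.mark.parametrize("total,layers,expected", [(66, 3, 22), (5, 3, 2), (1, 3, 1)])
    def test_equal_split_over_layers(self, total, layers, expected):
        assert units_per_layer(total, layers) == expected


class TestSpecValidation:
    def test_family_fields_are_exclusive(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(family="lstm", n_obs=10, n_pc=8, n_layers=1, first_filters=8)
        with pytest.raises(ConfigurationError):
            ModelSpec(family="cnn", n_obs=10, n_pc=8, n_layers=1, node_rule="sum")

    def test_domain_checks(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(family="lstm", n_obs=10, n_pc=8, n_layers=4, node_rule="sum")
        with pytest.raises(ConfigurationError):
            ModelSpec(family="cnn", n_obs=10, n_pc=8, n_layers=1, first_filters=7)


class TestBuildModel:
    def test_lstm_single_layer_parameter_count_closed_form(self):
        spec = ModelSpec(family="lstm", n_obs=10, n_pc=64, n_layers=1, node_rule="sum")
        model = build_model(spec, seed=0)
        u, d = 66, 64
        expected = 4 * u * (d + u + 1) + 2 * u + (u + 1) * 2
        assert model.n_params == expected == parameter_count(spec)

    def test_cnn_filter_doubling(self):
        spec = ModelSpec(family="cnn", n_obs=10, n_pc=8, n_layers=3, first_filters=8)
        model = build_model(spec, seed=0)
        conv_filters = [layer.params["b"].size for layer in model.layers
                        if type(layer).__name__ == "Conv2D"]
        assert conv_filters == [8, 16, 32]

    def test_seeded_builds_are_identical(self):
        spec = ModelSpec(family="lstm", n_obs=10, n_pc=8, n_layers=2, node_rule="mean")
        m1 = build_model(spec, seed=5)
        m2 = build_model(spec, seed=5)
        for l1, l2 in zip(m1.layers, m2.layers):
            for k in l1.params:
                np.testing.assert_array_equal(l1.params[k], l2.params[k])

    def test_no_pca_requires_input_dim(self):
        spec = ModelSpec(family="lstm", n_obs=10, n_pc=None, n_layers=1, node_rule="sum")
        with pytest.raises(ConfigurationError, match="input_dim"):
            build_model(spec)

    @pytest.mark.parametrize("family,kw", [
        ("lstm", {"node_rule": "half_mean"}),
        ("cnn", {"first_filters": 16}),
    ])
    @pytest.mark.parametrize("n_layers", [1, 2, 3])
    def test_built_count_matches_closed_form(self, family, kw, n_layers):
        spec = ModelSpec(family=family, n_obs=20, n_pc=16, n_layers=n_layers, **kw)
        assert build_model(spec, seed=1).n_params == parameter_count(spec)


def _dummy_set(n_pos, n_neg, n_obs=4, d=3, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.array([1] * n_pos + [0] * n_neg, dtype=np.int8)
    return SequenceSet(
        x=rng.random((n, n_obs, d)).astype(np.float32),
        labels=labels,
        categories=np.where(labels == 1, "tail_biting", "no_event").astype(object),
        pen_ids=np.array(["A"] * n, dtype=object),
        window_start=np.arange(n, dtype=np.int64),
    )


class TestBalanceUndersample:
    def test_published_sized_example(self):
        balanced = balance_undersample(_dummy_set(74, 2036), seed=0)
        assert len(balanced) == 148
        assert balanced.n_positive == 74

    def test_already_balanced_unchanged(self):
        s = _dummy_set(10, 10)
        balanced = balance_undersample(s, seed=1)
        np.testing.assert_array_equal(np.sort(balanced.window_start),
                                      np.sort(s.window_start))

    def test_seed_contract(self):
        s = _dummy_set(20, 200)
        b1 = balance_undersample(s, seed=7)
        b2 = balance_undersample(s, seed=7)
        b3 = balance_undersample(s, seed=8)
        np.testing.assert_array_equal(b1.window_start, b2.window_start)
        assert len(b3) == len(b1)
        assert not np.array_equal(b1.window_start, b3.window_start)

    def test_no_positives_is_balance_error(self):
        with pytest.raises(BalanceError):
            balance_undersample(_dummy_set(0, 10), seed=0)


@pytest.fixture(scope="module")
def separable_sets():
    rng = np.random.default_rng(11)

    def make(n, pen):
        labels = rng.integers(0, 2, n).astype(np.int8)
        x = rng.standard_normal((n, 6, 4)).astype(np.float32)
        x[labels == 1, :, 0] += 3.0  # linearly separable channel
        return SequenceSet(
            x=x, labels=labels,
            categories=np.where(labels == 1, "tail_biting", "no_event").astype(object),
            pen_ids=np.array([pen] * n, dtype=object),
            window_start=np.arange(n, dtype=np.int64),
        )

    return make(80, "A"), make(40, "B")


class TestTraining:
    def test_separable_data_reaches_high_training_accuracy(self, separable_sets):
        train_set, val_set = separable_sets
        spec = ModelSpec(family="lstm", n_obs=6, n_pc=4, n_layers=1, node_rule="sum")
        model = build_model(spec, seed=2)
        model, log = train(model, train_set, val_set, spec, seed=2, max_epochs=50)
        assert max(log.train_acc) >= 0.95

    def test_predict_proba_contract(self, separable_sets):
        train_set, val_set = separable_sets
        spec = ModelSpec(family="lstm", n_obs=6, n_pc=4, n_layers=1, node_rule="sum")
        model = build_model(spec, seed=2)
        model, _ = train(model, train_set, val_set, spec, seed=2, max_epochs=15)
        p1 = predict_proba(model, val_set, "lstm")
        p2 = predict_proba(model, val_set, "lstm")
        assert p1.shape == (len(val_set),)
        assert np.all((p1 >= 0) & (p1 <= 1))
        np.testing.assert_array_equal(p1, p2)

    def test_pen_overlap_between_train_and_val_rejected(self, separable_sets):
        train_set, _ = separable_sets
        spec = ModelSpec(family="lstm", n_obs=6, n_pc=4, n_layers=1, node_rule="sum")
        model = build_model(spec, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            train(model, train_set, train_set, spec, seed=0)
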