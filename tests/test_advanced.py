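"""CNN+BLSTM extractor construction, CV training and the 8-D matrix."""

import numpy as np
import pytest

from mc4deep import (
    GeneratorConfig,
    NetworkConfig,
    Scheme,
    build_network,
    encode_dataset,
    extract_advanced,
    generate,
    stratified_folds,
    train_extractor,
)
from mc4deep.advanced import (
    AdvancedFeatureBundle,
    AdvancedFeatureMatrix,
    load_bundle,
    min_input_length,
    save_bundle,
)
from mc4deep.metrics import auc_score


def small_config(**overrides):
    base = dict(n_conv_layers=3, nb_filter=(4, 8, 16), filter_length=(5, 5, 5),
                pool_size=2, lstm_units=8, dense_units=8, dropout=0.1,
                epochs=5, batch_size=16, seed=0)
    base.update(overrides)
    return NetworkConfig(**base)


class TestBuildNetwork:
    def test_default_config_final_conv_has_64_channels(self):
        net = build_network(NetworkConfig(), input_length=500)
        assert net.conv_shapes[-1][1] == 64
        assert [c for _, c in net.conv_shapes] == [16, 32, 64]

    def test_mismatched_filter_list_rejected(self):
        with pytest.raises(ValueError, match="conv layers"):
            NetworkConfig(n_conv_layers=4)  # default lists have 3 entries

    def test_all_zero_input_gives_probability(self):
        net = build_network(small_config(), input_length=64)
        prob = net.predict_proba(np.zeros((1, 64, 1)))
        assert 0.0 <= prob[0] <= 1.0

    def test_short_input_errors_with_minimum_length(self):
        cfg = NetworkConfig()
        with pytest.raises(ValueError, match=str(min_input_length(cfg))):
            build_network(cfg, input_length=10)

    def test_adaptive_build_handles_short_inputs(self):
        net = build_network(NetworkConfig(), input_length=10, adapt=True)
        prob = net.predict_proba(np.zeros((2, 10, 1)))
        assert prob.shape == (2,)
        assert len(net.conv_shapes) == 3  # still a three-block stack

    def test_minimum_length_is_tight(self):
        cfg = NetworkConfig()
        m = min_input_length(cfg)
        build_network(cfg, input_length=m)  # exactly the minimum works
        with pytest.raises(ValueError):
            build_network(cfg, input_length=m - 1)


class TestTrainExtractor:
    def test_separable_motif_reaches_high_oof_auc(self):
        samples = generate(GeneratorConfig(n_pos=120, n_neg=120, effect=1.0,
                                           seed=21))
        folds = stratified_folds(samples, k=3, seed=21)
        labels = [s.label for s in samples]
        enc = encode_dataset(samples, Scheme.BKF)
        cv = train_extractor(enc, labels, folds, small_config(seed=21))
        assert auc_score(labels, cv.oof_probs) > 0.9

    def test_shuffled_labels_give_chance_level_auc(self):
        samples = generate(GeneratorConfig(n_pos=60, n_neg=60, effect=1.0,
                                           seed=22))
        rng = np.random.default_rng(22)
        labels = rng.permutation([s.label for s in samples])
        folds = stratified_folds(np.asarray(labels), k=3, seed=22)
        enc = encode_dataset(samples, Scheme.BKF)
        cv = train_extractor(enc, labels, folds, small_config(seed=22))
        assert 0.3 < auc_score(labels, cv.oof_probs) < 0.7

    def test_deterministic_for_fixed_seed(self, tiny_samples, tiny_folds):
        labels = [s.label for s in tiny_samples]
        enc = encode_dataset(tiny_samples, Scheme.PSEEIIP)
        cfg = small_config(epochs=2)
        a = train_extractor(enc, labels, tiny_folds, cfg)
        b = train_extractor(enc, labels, tiny_folds, cfg)
        np.testing.assert_array_equal(a.oof_probs, b.oof_probs)
        assert [len(h["loss"]) for h in a.histories] == [2, 2, 2]

    def test_single_class_split_rejected(self, tiny_samples, tiny_folds):
        enc = encode_dataset(tiny_samples, Scheme.PSEEIIP)
        with pytest.raises(ValueError, match="single class"):
            train_extractor(enc, [1] * len(tiny_samples), tiny_folds,
                            small_config(epochs=1))

    def test_out_of_fold_provenance(self, tiny_samples, tiny_folds):
        labels = [s.label for s in tiny_samples]
        enc = encode_dataset(tiny_samples, Scheme.PSEEIIP)
        cv = train_extractor(enc, labels, tiny_folds, small_config(epochs=1))
        assert np.isfinite(cv.oof_probs).all()
        for i in range(len(tiny_samples)):
            producing = cv.producer_fold[i]
            trained = cv.trained_rows[producing]
            assert i not in trained  # the model for row i never saw row i
            own_fold_rows = tiny_folds.rows_in_fold(tiny_folds.assignments[i])
            assert not np.isin(own_fold_rows, trained).any()


@pytest.fixture(scope="module")
def fitted():
    samples = generate(GeneratorConfig(n_pos=24, n_neg=24, effect=0.9,
                                       seed=30))
    folds = stratified_folds(samples, k=3, seed=30)
    bundle = AdvancedFeatureBundle(small_config(epochs=1, batch_size=16))
    return samples, bundle.fit(samples, folds)


class TestBundle:
    def test_oof_matrix_is_n_by_8_in_unit_interval(self, fitted):
        samples, bundle = fitted
        assert bundle.oof.matrix.shape == (len(samples), 8)
        assert (bundle.oof.matrix >= 0).all() and (bundle.oof.matrix <= 1).all()
        assert bundle.oof.schemes == tuple(Scheme)

    def test_transform_new_windows(self, fitted, tiny_samples):
        _, bundle = fitted
        adv = extract_advanced(tiny_samples[:5], bundle)
        assert adv.matrix.shape == (5, 8)
        empty = extract_advanced([], bundle)
        assert empty.matrix.shape == (0, 8)

    def test_duplicated_rows_get_identical_features(self, fitted, tiny_samples):
        _, bundle = fitted
        adv = extract_advanced([tiny_samples[0], tiny_samples[0]], bundle)
        np.testing.assert_array_equal(adv.matrix[0], adv.matrix[1])

    def test_missing_scheme_named_in_error(self, fitted, tiny_samples):
        _, bundle = fitted
        broken = AdvancedFeatureBundle(bundle.config)
        broken.extractors = {k: v for k, v in bundle.extractors.items()
                             if k is not Scheme.MMI}
        broken.knn_references = bundle.knn_references
        with pytest.raises(ValueError, match="mmi"):
            broken.transform(tiny_samples[:2])

    def test_save_load_roundtrip(self, fitted, tiny_samples, tmp_path):
        _, bundle = fitted
        save_bundle(bundle, tmp_path / "bundle")
        reloaded = load_bundle(tmp_path / "bundle")
        a = bundle.transform(tiny_samples[:4]).matrix
        b = reloaded.transform(tiny_samples[:4]).matrix
        np.testing.assert_allclose(a, b)

    def test_training_loss_mostly_decreasing(self):
        samples = generate(GeneratorConfig(n_pos=60, n_neg=60, effect=1.0,
                                           seed=31))
        folds = stratified_folds(samples, k=3, seed=31)
        enc = encode_dataset(samples, Scheme.BKF)
        cv = train_extractor(enc, [s.label for s in samples], folds,
                             small_config(epochs=5, seed=31))
        for history in cv.histories:
            losses = history["loss"]
            drops = sum(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))
            assert drops >= 3  # loose monotonicity across 5 epochs


def test_matrix_type_enforces_unit_interval():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        AdvancedFeatureMatrix(("a",), np.full((1, 8), 1.5))
    with pytest.raises(ValueError, match="columns"):
        AdvancedFeatureMatrix(("a",), np.zeros((1, 7)))
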