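"""Sequence classifier: contracts, training behaviour, persistence."""

import numpy as np
import pytest

from mhtcnn import ModelConfig, Preprocessing, build_model
from mhtcnn.classifier import (DEFAULT_LAYERS, load_model, save_model)
from mhtcnn.nn import LayerSpec


def step_sequence(rng, m, boundary, lo=0.05, hi=0.6):
    """Synthetic W-like sequence: exponential spacings whose level jumps."""
    scale = np.where(np.arange(m) < boundary, lo, hi)
    seq = rng.exponential(scale)
    labels = (np.arange(m) >= boundary).astype(float)
    return seq, labels


@pytest.fixture(scope="module")
def step_model():
    """Classifier trained on a synthetic level-shift sequence (fast)."""
    rng = np.random.default_rng(17)
    seq, labels = step_sequence(rng, 3000, 2400)
    config = ModelConfig(epochs=20, crop_length=512, crops_per_epoch=32,
                         batch_size=8, seed=3)
    return build_model(config).fit_sequence(seq, labels), seq, labels


class TestConfig:
    def test_invariants(self):
        assert DEFAULT_LAYERS[0].filters == 64
        with pytest.raises(ValueError, match="final layer"):
            ModelConfig(layers=(LayerSpec(4, 3), LayerSpec(2, 1, activation="linear")))
        with pytest.raises(ValueError, match="kernel_size"):
            ModelConfig(layers=(LayerSpec(4, 1), LayerSpec(1, 1, activation="linear")))
        with pytest.raises(ValueError, match="input_kind"):
            ModelConfig(input_kind="images")

    def test_round_trip_dict(self):
        cfg = ModelConfig.for_pvalues(epochs=5, seed=9)
        again = ModelConfig.from_dict(cfg.to_dict())
        assert again == cfg
        assert again.preprocessing.kind == "raw"


class TestPreprocessing:
    def test_clipping_tames_the_spike(self):
        rng = np.random.default_rng(0)
        w = rng.exponential(0.01, 10_000)
        w[7000] = 1e6
        out = Preprocessing(clip_quantile=0.999).apply(w)
        assert out.max() < 20.0
        assert np.isfinite(out).all()

    def test_raw_passthrough_and_validation(self):
        seq = np.linspace(0, 1, 10)
        np.testing.assert_array_equal(Preprocessing(kind="raw").apply(seq), seq)
        with pytest.raises(ValueError, match="non-finite"):
            Preprocessing().apply(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            Preprocessing(kind="weird")


class TestShapeContracts:
    @pytest.mark.parametrize("length", [3, 137, 13_930])
    def test_output_matches_input_length(self, length):
        model = build_model(ModelConfig())
        model.trained = True  # shape contract only; weights untrained
        p = model.predict_proba(np.random.default_rng(0).exponential(size=length))
        assert p.shape == (length,)
        assert np.all((p > 0) & (p < 1))

    def test_untrained_predict_raises(self):
        with pytest.raises(RuntimeError, match="untrained"):
            build_model().predict_proba(np.ones(10))

    def test_zero_weight_hook_gives_half(self):
        model = build_model()
        model.net.zero_weights()
        model.trained = True
        np.testing.assert_allclose(model.predict_proba(np.ones(50)), 0.5)

    def test_feature_map_shape(self):
        model = build_model()
        fm = model.feature_map(np.random.default_rng(1).exponential(size=200))
        assert fm.shape == (64, 200)


class TestTraining:
    def test_learns_level_shift_and_records_history(self, step_model):
        model, seq, labels = step_model
        assert model.trained
        hist = model.training_history
        assert list(hist.columns) == ["epoch", "loss", "accuracy"]
        assert len(hist) == 20
        assert hist["accuracy"].iloc[-1] > 0.9
        p = model.predict_proba(seq)
        assert p[labels == 1].mean() > 0.5 > p[labels == 0].mean()

    def test_translation_of_boundary_moves_crossing(self, step_model):
        model, _, _ = step_model
        from mhtcnn.evaluate import main_crossing
        rng = np.random.default_rng(99)
        boundaries = (2100, 2300, 2500, 2700)
        mains = []
        for boundary in boundaries:
            seq, _ = step_sequence(rng, 3000, boundary)
            mains.append(main_crossing(model.predict_proba(seq))["main"])
        # convolutional features track the boundary, not its training
        # position, to within roughly half the receptive field
        for boundary, main in zip(boundaries, mains):
            assert abs(main - boundary) < 250
        assert list(mains) == sorted(mains)

    def test_all_null_labels_trivially_learned(self):
        rng = np.random.default_rng(5)
        seq = rng.exponential(0.1, 400)
        cfg = ModelConfig(epochs=8, crop_length=128, crops_per_epoch=16,
                          batch_size=4, seed=1)
        model = build_model(cfg).fit_sequence(seq, np.zeros(400))
        assert model.training_history["accuracy"].iloc[-1] == 1.0

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(2)
        seq, labels = step_sequence(rng, 600, 480)
        cfg = ModelConfig(epochs=3, crop_length=128, crops_per_epoch=8,
                          batch_size=4, seed=42)
        h1 = build_model(cfg).fit_sequence(seq, labels).training_history
        h2 = build_model(cfg).fit_sequence(seq, labels).training_history
        assert h1.equals(h2)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            build_model().fit_sequence(np.ones(10), np.zeros(9))


class TestPersistence:
    def test_save_load_bitwise_predictions(self, step_model, tmp_path):
        model, seq, _ = step_model
        save_model(model, tmp_path / "artifact")
        loaded = load_model(tmp_path / "artifact")
        assert loaded.fingerprint == model.fingerprint
        np.testing.assert_array_equal(loaded.predict_proba(seq),
                                      model.predict_proba(seq))
        assert loaded.training_history.equals(model.training_history)

    def test_fingerprint_tracks_weights(self):
        a = build_model()
        fp = a.fingerprint
        a.net.weights[0][0, 0] += 1.0
        assert a.fingerprint != fp
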