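"""Shape, connectivity, and training contracts of the configurable CNN."""

import numpy as np
import pytest

from neoseg import (
    ConvLayerAction,
    TrainingSettings,
    assemble_configuration,
    build_model,
    encode_conv_action,
    predict_segmentation,
    train_candidate,
)
from neoseg.network import DataError, ShapeError


def _idx(n, l, w):
    return encode_conv_action(ConvLayerAction(n, l, w))


class TestBuildModel:
    def test_output_shape_and_normalisation(self, minimal_config, rng):
        model = build_model(minimal_config, n_modalities=2, n_classes=4, spatial_rank=3)
        x = rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32)
        probs = model.forward(x)
        assert probs.shape == (1, 4, 8, 8, 8)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_output_extent_preserved_2d_mixed_kernels(self, rng):
        cfg = assemble_configuration(
            [_idx(32, l, w) for l, w in [(9, 1), (1, 9), (5, 7)] * 6 + [(3, 5)]], [1, 0]
        )
        model = build_model(cfg, n_modalities=3, n_classes=2, spatial_rank=2)
        x = rng.normal(size=(2, 3, 12, 20)).astype(np.float32)
        assert model.forward(x).shape == (2, 2, 12, 20)

    def test_indivisible_extent_rejected(self, minimal_config, rng):
        model = build_model(minimal_config, n_modalities=2, spatial_rank=2)
        with pytest.raises(ShapeError, match="downsampling"):
            model.forward(rng.normal(size=(1, 2, 10, 8)).astype(np.float32))

    def test_modality_mismatch_rejected(self, minimal_config, rng):
        model = build_model(minimal_config, n_modalities=2, spatial_rank=2)
        with pytest.raises(ShapeError, match="modalities"):
            model.forward(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))

    def test_parameter_count_monotone_in_filter_count(self):
        base = [_idx(32, 3, 3)] * 19
        wider = list(base)
        wider[7] = _idx(48, 3, 3)
        m0 = build_model(assemble_configuration(base, [0, 0]), 2, spatial_rank=2)
        m1 = build_model(assemble_configuration(wider, [0, 0]), 2, spatial_rank=2)
        assert m1.n_parameters() > m0.n_parameters()

    def test_dense_connectivity_channel_counts(self):
        # third layer of a block sees block input + N1 + N2 channels
        idx = [_idx(64, 3, 3), _idx(32, 3, 3), _idx(48, 3, 3)] + [_idx(32, 1, 1)] * 16
        cfg = assemble_configuration(idx, [0, 0])
        model = build_model(cfg, n_modalities=2, spatial_rank=2)
        assert model.enc1.layer_in_channels == [2, 2 + 64, 2 + 64 + 32]

    def test_pointwise_model_constant_input_gives_constant_output(self, minimal_config):
        model = build_model(minimal_config, n_modalities=2, spatial_rank=2, seed=7)
        x = np.ones((1, 2, 8, 8), dtype=np.float32)
        probs = model.forward(x)
        flat = probs.reshape(4, -1)
        assert np.allclose(flat, flat[:, :1], atol=1e-5)


class TestTraining:
    def test_loss_decreases_on_learnable_phantom(self, small_config, small_phantom_dataset):
        model = build_model(small_config, n_modalities=2, spatial_rank=2, seed=0)
        settings = TrainingSettings(max_epochs=5, patience_epochs=5, batch_size=4,
                                    patch_shape=(16, 16), seed=0)
        model, hist = train_candidate(model, small_phantom_dataset[:6], settings,
                                      rng=np.random.default_rng(0))
        assert len(hist.epochs) <= 5
        assert hist.losses[-1] < hist.losses[0]
        assert not hist.diverged

    def test_early_stopping_patience(self, minimal_config, small_phantom_dataset,
                                     monkeypatch):
        # a monitored metric that never improves stops after exactly 2 epochs
        import neoseg.network as net

        calls = {"n": 0}
        real = net.ce_dice_loss_and_grad

        def flat_loss(logits, target, dice_eps=1.0):
            _, grad = real(logits, target, dice_eps)
            calls["n"] += 1
            return 1.0, grad  # constant loss -> metric never improves

        monkeypatch.setattr(net, "ce_dice_loss_and_grad", flat_loss)
        model = build_model(minimal_config, n_modalities=2, spatial_rank=2)
        settings = TrainingSettings(max_epochs=50, patience_epochs=1, batch_size=8,
                                    patch_shape=(16, 16), seed=0)
        _, hist = train_candidate(model, small_phantom_dataset[:4], settings,
                                  rng=np.random.default_rng(0))
        assert hist.epochs == [1, 2]

    def test_training_is_deterministic_given_seed(self, minimal_config,
                                                  small_phantom_dataset):
        results = []
        for _ in range(2):
            model = build_model(minimal_config, n_modalities=2, spatial_rank=2, seed=3)
            settings = TrainingSettings(max_epochs=2, patience_epochs=2, batch_size=4,
                                        patch_shape=(16, 16), seed=3)
            _, hist = train_candidate(model, small_phantom_dataset[:4], settings,
                                      rng=np.random.default_rng(3))
            results.append(hist.metrics[-1])
        assert results[0] == results[1]

    def test_empty_dataset_rejected(self, minimal_config):
        model = build_model(minimal_config, n_modalities=2, spatial_rank=2)
        with pytest.raises(DataError):
            train_candidate(model, [], TrainingSettings(max_epochs=1, patience_epochs=1))

    def test_divergence_flagged_not_raised(self, minimal_config, small_phantom_dataset):
        model = build_model(minimal_config, n_modalities=2, spatial_rank=2)
        img, lab = small_phantom_dataset[0]
        poisoned = [(np.full_like(img, np.nan), lab)]
        settings = TrainingSettings(max_epochs=5, patience_epochs=5, batch_size=1,
                                    patch_shape=(16, 16), seed=0)
        _, hist = train_candidate(model, poisoned, settings,
                                  rng=np.random.default_rng(0))
        assert hist.diverged

    def test_history_csv_export(self, tmp_path, minimal_config, small_phantom_dataset):
        model = build_model(minimal_config, n_modalities=2, spatial_rank=2)
        settings = TrainingSettings(max_epochs=2, patience_epochs=2, batch_size=4,
                                    patch_shape=(16, 16), seed=0)
        _, hist = train_candidate(model, small_phantom_dataset[:4], settings,
                                  rng=np.random.default_rng(0))
        out = tmp_path / "history.csv"
        hist.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "epoch,loss,monitored_metric"
        assert len(lines) == len(hist.epochs) + 1


class TestPrediction:
    def test_labels_within_class_range(self, minimal_config, rng):
        model = build_model(minimal_config, n_modalities=2, n_classes=4, spatial_rank=2)
        vol = rng.normal(size=(2, 8, 8)).astype(np.float32)
        pred = predict_segmentation(model, vol)
        assert pred.labels.shape == (8, 8)
        assert set(np.unique(pred.labels)) <= {0, 1, 2, 3}

    def test_prediction_deterministic(self, minimal_config, rng):
        model = build_model(minimal_config, n_modalities=2, spatial_rank=2, seed=11)
        vol = rng.normal(size=(2, 8, 8)).astype(np.float32)
        a = predict_segmentation(model, vol)
        b = predict_segmentation(model, vol)
        assert np.array_equal(a.labels, b.labels)

    def test_wrong_rank_rejected(self, minimal_config, rng):
        model = build_model(minimal_config, n_modalities=2, spatial_rank=2)
        with pytest.raises(ShapeError):
            predict_segmentation(model, rng.normal(size=(2, 8, 8, 8)).astype(np.float32))
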