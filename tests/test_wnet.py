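"""W-net contracts: architecture, losses, training-step semantics, mapping."""

import numpy as np
import pytest

from gaseg.wnet import (WNet, WNetConfig, argmax_segment, auto_map_classes,
                        map_classes_to_lesion, reconstruction_loss)

MINI = WNetConfig(n_classes=3, depth=2, base_features=4, epochs=1,
                  batch_size=2, seed=0)


class TestReconstructionLoss:
    def test_identical_images_zero(self, rng):
        img = rng.random((8, 8))
        assert reconstruction_loss(img, img) == 0.0

    def test_uniform_offset_closed_form(self, rng):
        img = rng.random((8, 8)) * 0.5
        assert reconstruction_loss(img, img + 0.1) == pytest.approx(0.01)

    def test_matches_direct_formula(self, rng):
        a = rng.random((6, 7))
        b = rng.random((6, 7))
        assert reconstruction_loss(a, b) == pytest.approx(
            float(((a - b) ** 2).sum() / a.size))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            reconstruction_loss(rng.random((4, 4)), rng.random((5, 5)))


class TestArgmaxAndMapping:
    def test_argmax_basic(self):
        p = np.array([0.2, 0.7, 0.1])[:, None, None]
        assert argmax_segment(p)[0, 0] == 1

    def test_tie_breaks_to_lowest_index(self):
        p = np.array([0.5, 0.5])[:, None, None]
        assert argmax_segment(p)[0, 0] == 0
        uniform = np.full((3, 2, 2), 1 / 3)
        assert np.all(argmax_segment(uniform) == 0)

    @pytest.mark.parametrize("classes,expected_sum", [
        (set(), 0), ({1}, 2), ({0, 1, 2}, 4)])
    def test_map_classes_to_lesion(self, classes, expected_sum):
        mask = np.array([[0, 1], [2, 1]])
        out = map_classes_to_lesion(mask, classes)
        assert out.sum() == expected_sum
        assert set(np.unique(out)) <= {0, 1}


class TestAutoMapClasses:
    def test_brightest_class_chosen_without_references(self):
        img = np.array([[0.1, 0.1], [0.9, 0.9]])
        labels = np.array([[0, 0], [2, 2]])
        assert auto_map_classes([labels], [img], n_classes=3) == {2}

    def test_two_class_case_returns_brighter(self):
        img = np.array([[0.2, 0.8]])
        labels = np.array([[0, 1]])
        assert auto_map_classes([labels], [img], n_classes=2) == {1}

    def test_reference_guided_maximizes_f1(self, rng):
        img = rng.random((8, 8))
        labels = rng.integers(0, 3, size=(8, 8))
        truth = (labels == 1).astype(np.uint8)  # class 1 is exactly the lesion
        best = auto_map_classes([labels], [img], 3, reference_masks=[truth])
        assert best == {1}


class TestBuildAndPredict:
    def test_full_scale_default_bottleneck(self):
        assert WNetConfig().bottleneck_features == 1024
        assert WNetConfig().n_classes == 3
        assert WNetConfig().kernel_size == 3
        assert WNetConfig().epochs == 250

    def test_forward_shape_contract(self, rng):
        model = WNet(MINI)
        img = rng.random((16, 16))
        p = model.predict(img)
        assert p.shape == (3, 16, 16)
        recon = model.reconstruct(img)
        assert recon.shape == (16, 16)

    def test_probabilities_sum_to_one(self, rng):
        p = WNet(MINI).predict(rng.random((16, 16)))
        assert np.abs(p.sum(axis=0) - 1).max() < 1e-5

    def test_same_seed_identical_parameters(self):
        a, b = WNet(MINI), WNet(MINI)
        for pa, pb in zip(a.encoder.params, b.encoder.params):
            assert np.array_equal(pa, pb)

    def test_inference_deterministic(self, rng):
        model = WNet(MINI)
        img = rng.random((16, 16))
        assert np.array_equal(model.predict(img), model.predict(img))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            WNetConfig(n_classes=1)
        with pytest.raises(ValueError):
            WNetConfig(kernel_size=4)
        with pytest.raises(ValueError):
            WNetConfig(pool_factor=0)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = WNet(MINI)
        img = rng.random((16, 16))
        path = tmp_path / "wnet.npz"
        model.save(path)
        clone = WNet.load(path)
        assert clone.config == model.config
        np.testing.assert_allclose(clone.predict(img), model.predict(img))


class TestTrainingSemantics:
    def test_one_epoch_one_image_two_optimizer_steps(self, rng):
        model = WNet(MINI)
        res = model.fit([rng.random((16, 16))])
        assert res.n_mse_steps == 1
        assert res.n_ncut_steps == 1
        assert list(res.history.columns) == ["epoch", "mse", "soft_ncut"]

    def test_masks_rejected_as_training_input(self, rng):
        model = WNet(MINI)
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        with pytest.raises(TypeError, match="masks are not accepted"):
            model.fit([mask])

    def test_empty_image_list_rejected(self):
        with pytest.raises(ValueError):
            WNet(MINI).fit([])

    def test_mixed_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            WNet(MINI).fit([rng.random((16, 16)), rng.random((32, 32))])

    def test_predict_size_must_match_training_side(self, rng):
        model = WNet(MINI)
        model.fit([rng.random((16, 16))])
        with pytest.raises(ValueError, match="training side"):
            model.predict(rng.random((32, 32)))

    def test_ncut_step_leaves_decoder_untouched(self, rng):
        """The partition step updates the encoder only; the reconstruction
        step updates both halves."""
        from gaseg import nn as gnn
        from gaseg.ncut import average_pool, pixel_weights

        model = WNet(MINI)
        img = rng.random((16, 16)).astype(np.float32)
        x = img[None, None]
        weights = pixel_weights(average_pool(img.astype(np.float64), 2),
                                MINI.affinity)
        enc0 = [p.copy() for p in model.encoder.params]
        dec0 = [p.copy() for p in model.decoder.params]

        # soft-N-cut step only
        opt_n = gnn.Adam(model.encoder.params, model.encoder.grads, lr=1e-3)
        p = model.encoder.forward(x)
        _, dj = model._ncut_grad_batch(p, [weights])
        model.encoder.backward(dj)
        opt_n.step()
        assert all(np.array_equal(a, b)
                   for a, b in zip(model.decoder.params, dec0))
        assert any(not np.array_equal(a, b)
                   for a, b in zip(model.encoder.params, enc0))

        # reconstruction step changes both halves
        enc1 = [p.copy() for p in model.encoder.params]
        params = model.encoder.params + model.decoder.params
        grads = model.encoder.grads + model.decoder.grads
        opt_r = gnn.Adam(params, grads, lr=1e-3)
        p = model.encoder.forward(x)
        recon = model.decoder.forward(p)
        diff = recon - x
        dp = model.decoder.backward((2 * diff / diff.size).astype(np.float32))
        model.encoder.backward(dp)
        opt_r.step()
        assert any(not np.array_equal(a, b)
                   for a, b in zip(model.decoder.params, dec0))
        assert any(not np.array_equal(a, b)
                   for a, b in zip(model.encoder.params, enc1))

    def test_restart_selection_keeps_lowest_ncut_model(self, rng):
        """fit_restarts picks the candidate with the lowest final J, and the
        winner matches a direct fit with the winning seed."""
        cfg = WNetConfig(n_classes=2, depth=2, base_features=4, epochs=3,
                         batch_size=2, seed=5)
        imgs = [rng.random((16, 16)) * 0.8 for _ in range(2)]
        best = WNet.fit_restarts(imgs, cfg, n_init=2)
        js = []
        for i in range(2):
            from dataclasses import replace
            res = WNet(replace(cfg, seed=cfg.seed + i)).fit(imgs)
            js.append(float(res.history["soft_ncut"].iloc[-1]))
        assert float(best.history["soft_ncut"].iloc[-1]) == pytest.approx(min(js))
        with pytest.raises(ValueError):
            WNet.fit_restarts(imgs, cfg, n_init=0)

    def test_short_training_reduces_reconstruction_error(self, rng):
        cfg = WNetConfig(n_classes=2, depth=2, base_features=4, epochs=8,
                         batch_size=2, seed=1)
        imgs = [rng.random((16, 16)) * 0.8 for _ in range(2)]
        res = WNet(cfg).fit(imgs)
        assert res.history["mse"].iloc[-1] < res.history["mse"].iloc[0]
        assert res.n_mse_steps == res.n_ncut_steps == 8
        assert "soft-N-cut" in res.summary()
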