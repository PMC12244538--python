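"""CDL network: structure, focal loss, layers' gradients, training loop."""

import numpy as np
import pytest

from mitodet import nn
from mitodet.cdl import (
    CDLConfig, EarlyStopper, augment, build_cdl, detection_f1, focal_loss,
    load_checkpoint, match_detections, postprocess_detections,
    predict_segmentation, save_checkpoint, train, transfer_weights,
    _focal_loss_and_grad,
)
from mitodet.synthetic import TileGenParams, gen_he_tile


def micro_config(**overrides):
    defaults = dict(input_side=32, width_scale=0.05, seed=3, dropout=0.0,
                    pretrained_source="none", batch_size=4, max_epochs=2,
                    patience=2)
    defaults.update(overrides)
    return CDLConfig(**defaults)


class TestArchitecture:
    def test_thirteen_convs_three_fc_three_skips(self):
        net = build_cdl(micro_config())
        desc = net.describe()
        assert desc["n_conv_layers"] == 13
        assert desc["n_fc_equivalent"] == 3
        assert len(desc["skips"]) == 3
        assert all(s["kernel"] == [1, 1] for s in desc["skips"])

    @pytest.mark.parametrize("side", [32, 96, 227])
    def test_output_matches_input_spatial_shape(self, side):
        net = build_cdl(micro_config(input_side=side))
        x = np.random.default_rng(0).uniform(size=(1, 3, side, side))
        out = net.forward(x.astype(np.float32))
        assert out.shape == (1, 1, side, side)

    def test_invalid_input_side_names_nearest_valid(self):
        with pytest.raises(ValueError, match="nearest valid side"):
            build_cdl(micro_config(input_side=16))

    def test_width_scale_never_changes_structure(self):
        for ws in (0.05, 0.25, 1.0):
            desc = build_cdl(micro_config(width_scale=ws)).describe()
            assert desc["n_conv_layers"] == 13


class TestFocalLoss:
    def test_reduces_to_cross_entropy_at_gamma_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=1000)
        t = rng.integers(0, 2, size=1000)
        fl = focal_loss(p, t, alpha=1.0, gamma=0.0)
        ce = -np.mean(t * np.log(p) + (1 - t) * np.log(1 - p))
        assert fl == pytest.approx(ce, rel=1e-12)

    def test_perfect_predictions_give_near_zero_loss(self):
        t = np.array([1.0, 0.0, 1.0])
        p = np.array([1.0, 0.0, 1.0])
        assert focal_loss(p, t) < 1e-5

    def test_single_pixel_worked_value(self):
        # alpha 0.25, gamma 2, p_t = 0.9: 0.25 * 0.01 * (-ln 0.9)
        expected = 0.25 * 0.1 ** 2 * -np.log(0.9)
        assert focal_loss(np.array([0.9]), np.array([1])) == pytest.approx(
            expected, rel=1e-6
        )
        assert expected == pytest.approx(2.634e-4, rel=1e-3)

    def test_monotone_non_increasing_in_p_t(self):
        p = np.linspace(0.02, 0.98, 50)
        losses = [focal_loss(np.array([v]), np.array([1])) for v in p]
        assert all(b <= a for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            focal_loss(np.zeros((2, 2)), np.zeros(3))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=12)
        t = rng.integers(0, 2, size=12).astype(float)
        for gamma in (0.0, 2.0):
            _, g = _focal_loss_and_grad(z, t, 0.25, gamma)
            for i in range(4):
                eps = 1e-6
                zp, zm = z.copy(), z.copy()
                zp[i] += eps
                zm[i] -= eps
                lp, _ = _focal_loss_and_grad(zp, t, 0.25, gamma)
                lm, _ = _focal_loss_and_grad(zm, t, 0.25, gamma)
                assert g[i] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestLayerGradients:
    """Each layer's backward pass against float64 finite differences."""

    @pytest.mark.parametrize("make", [
        lambda rng: nn.Conv2d(3, 4, 3, rng),
        lambda rng: nn.Conv1x1(3, 4, rng),
        lambda rng: nn.ConvTransposeBlock(3, 2, 2, rng),
        lambda rng: nn.ConvTransposeBlock(3, 2, 4, rng),
    ])
    def test_param_and_input_gradients(self, make):
        rng = np.random.default_rng(0)
        layer = make(rng)
        for k in layer.params:
            layer.params[k] = layer.params[k].astype(np.float64)
        x = rng.normal(size=(2, 3, 8, 8))
        proj = None

        def loss():
            nonlocal proj
            y = layer.forward(x, train=True)
            if proj is None:
                proj = rng.normal(size=y.shape)
            return float((y * proj).sum())

        base = loss()
        gx = layer.backward(proj)
        eps = 1e-6
        for k, p in layer.params.items():
            an = layer.grads[k]
            idx = tuple(rng.integers(s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            assert an[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5,
                                            abs=1e-8)
        idx = tuple(rng.integers(s) for s in x.shape)
        orig = x[idx]
        x[idx] = orig + eps
        lp = loss()
        x[idx] = orig - eps
        lm = loss()
        x[idx] = orig
        assert gx[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5,
                                        abs=1e-8)

    def test_maxpool_routes_gradient_to_argmax(self):
        x = np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4)
        pool = nn.MaxPool2()
        y = pool.forward(x, train=True)
        g = pool.backward(np.ones_like(y))
        assert g.sum() == y.size
        assert g[0, 0, 1, 1] == 1.0 and g[0, 0, 0, 0] == 0.0


class TestTransferWeights:
    def test_none_source_is_deterministic(self):
        cfg = micro_config(seed=17)
        a, b = build_cdl(cfg), build_cdl(cfg)
        for la, lb in zip(a.param_layers(), b.param_layers()):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k])

    def test_missing_weight_file_names_expected_path(self, tmp_path):
        net = build_cdl(micro_config())
        with pytest.raises(FileNotFoundError, match="vgg_conv.npz"):
            transfer_weights(net, "vgg",
                             weights_path=tmp_path / "vgg_conv.npz")

    def test_transfer_truncates_channels_and_tags_layers(self, tmp_path):
        net = build_cdl(micro_config(width_scale=0.05))
        rng = np.random.default_rng(0)
        path = tmp_path / "vgg_conv.npz"
        np.savez(path,
                 conv1_W=rng.normal(size=(64, 3, 3, 3)),
                 conv1_b=rng.normal(size=64),
                 conv2_W=rng.normal(size=(64, 64, 3, 3)),
                 conv2_b=rng.normal(size=64))
        transfer_weights(net, "vgg", weights_path=path)
        tagged = [l for l in net.conv_layers if l.lr_group == "pretrained"]
        assert len(tagged) == 2
        f, c, _, _ = net.conv_layers[0].params["W"].shape
        expected = np.load(path)["conv1_W"][:f, :c].astype(np.float32)
        assert np.array_equal(net.conv_layers[0].params["W"], expected)


class TestAugment:
    @pytest.fixture
    def tile(self):
        return gen_he_tile(TileGenParams(side=64, n_nuclei=8, n_mitotic=2,
                                         seed=2))

    def test_mask_flips_with_image(self, tile):
        out = augment(tile, np.random.default_rng(0))
        assert out.mask.sum() == tile.mask.sum()
        assert out.pixels.shape == tile.pixels.shape

    def test_noop_draws_reproduce_input(self, tile, stub_rng):
        # no flips; brightness offset 0 (u=0.5); contrast gain 1 (u=0.5)
        rng = stub_rng(uniforms=[0.9, 0.9, 0.5, 0.5])
        out = augment(tile, rng)
        assert np.array_equal(out.pixels, tile.pixels)

    def test_double_horizontal_flip_is_identity(self, tile, stub_rng):
        flip = lambda: stub_rng(uniforms=[0.0, 0.9, 0.5, 0.5])
        once = augment(tile, flip())
        twice = augment(once, flip())
        assert np.array_equal(twice.pixels, tile.pixels)
        assert np.array_equal(twice.mask, tile.mask)


class TestEarlyStopping:
    def test_flat_validation_stops_after_patience(self):
        stopper = EarlyStopper(patience=5)
        stops = [stopper.update(1.0) for _ in range(6)]
        # epoch 1 improves from inf; epochs 2-6 flat -> stop at epoch 6
        assert stops == [False, False, False, False, False, True]

    def test_improvement_resets_counter(self):
        stopper = EarlyStopper(patience=2)
        assert not stopper.update(1.0)
        assert not stopper.update(1.0)
        assert not stopper.update(0.5)
        assert not stopper.update(0.5)
        assert stopper.update(0.5)


@pytest.fixture(scope="module")
def tiny_tiles():
    tiles = [gen_he_tile(TileGenParams(side=32, n_nuclei=3, n_mitotic=1,
                                       seed=100 + i)) for i in range(6)]
    return tiles[:4], tiles[4:]


class TestTrainingLoop:
    def test_loss_decreases_on_tiny_problem(self, tiny_tiles):
        train_t, val_t = tiny_tiles
        cfg = micro_config(width_scale=0.1, max_epochs=6, batch_size=2)
        net = build_cdl(cfg)
        state = train(net, train_t, val_t, cfg, augment_train=False)
        assert state.history[-1]["train_loss"] < state.history[0]["train_loss"]
        assert state.epoch <= cfg.max_epochs

    def test_training_is_deterministic(self, tiny_tiles):
        train_t, val_t = tiny_tiles
        cfg = micro_config(width_scale=0.05, max_epochs=2, batch_size=2)
        s1 = train(build_cdl(cfg), train_t, val_t, cfg)
        s2 = train(build_cdl(cfg), train_t, val_t, cfg)
        assert s1.history == s2.history

    def test_prediction_contract(self, tiny_tiles):
        train_t, _ = tiny_tiles
        net = build_cdl(micro_config())
        with pytest.warns(UserWarning, match="untrained"):
            prob = predict_segmentation(net, train_t[0])
        assert prob.shape == train_t[0].pixels.shape[:2]
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_checkpoint_round_trip(self, tiny_tiles, tmp_path):
        train_t, val_t = tiny_tiles
        cfg = micro_config(width_scale=0.05, max_epochs=1, batch_size=2)
        net = build_cdl(cfg)
        train(net, train_t, val_t, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        restored = load_checkpoint(path)
        p1 = predict_segmentation(net, train_t[0])
        p2 = predict_segmentation(restored, train_t[0])
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestPostprocessing:
    def test_empty_map_gives_no_detections(self):
        assert postprocess_detections(np.zeros((32, 32))) == []

    def test_single_disk_detection(self):
        yy, xx = np.mgrid[0:64, 0:64]
        prob = np.where((yy - 30) ** 2 + (xx - 20) ** 2 <= 16, 0.9, 0.0)
        dets = postprocess_detections(prob, threshold=0.5, min_area=10)
        assert len(dets) == 1
        assert dets[0]["score"] == pytest.approx(0.9)
        r, c = dets[0]["centroid"]
        assert abs(r - 30) < 1 and abs(c - 20) < 1

    def test_min_area_filters_small_blobs(self):
        prob = np.zeros((32, 32))
        prob[2:4, 2:4] = 0.9            # area 4 < 10 -> dropped
        prob[10:20, 10:15] = 0.8        # area 50 -> kept
        dets = postprocess_detections(prob, min_area=10)
        assert len(dets) == 1
        assert dets[0]["area"] == 50

    def test_centroid_matching_counts(self):
        truth = np.zeros((32, 32), np.uint8)
        truth[5:10, 5:10] = 1
        hit = {"centroid": (7.0, 7.0), "area": 20, "score": 0.9}
        miss = {"centroid": (25.0, 25.0), "area": 20, "score": 0.8}
        assert match_detections([hit], truth) == (1, 0, 0)
        assert match_detections([miss], truth) == (0, 1, 1)
        assert match_detections([hit, hit], truth) == (1, 1, 0)
        assert detection_f1([([hit], truth)]) == 1.0
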