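"""Architecture fidelity, forward/backward correctness, inference."""

import numpy as np
import pytest

from hsitissue.io import AnnotationMask, Hypercube, ShapeError
from hsitissue.model import (
    ModelSpec,
    ModelSpecError,
    build_model,
    count_parameters,
    default_model_spec,
    load_checkpoint,
    predict_map,
    save_checkpoint,
    softmax,
)

EXPECTED_COUNTS = [("Conv1", 560), ("Pool1", 1220), ("Conv2", 18935),
                   ("Pool2", 3710), ("Conv3", 3710), ("Pool3", 2485),
                   ("FC", 912)]


def naive_forward(model, patches):
    """Direct-summation oracle for the layer stack, float64 loops."""
    x = np.asarray(patches, dtype=np.float64)
    n = x.shape[0]
    a = x.transpose(0, 3, 1, 2)[:, None]  # (n, 1, S, H, W) channels-first
    for layer in model.layers:
        kind = layer.__class__.__name__
        if kind == "Conv3d":
            w, b = layer.w.astype(np.float64), layer.b
            oc, cin, ks, kh, kw = w.shape
            _, _, s, h, wd = a.shape
            ps = (ks - 1) // 2
            ap = np.pad(a, ((0, 0), (0, 0), (ps, ps), (0, 0), (0, 0)))
            ho, wo = h - kh + 1, wd - kw + 1
            out = np.zeros((n, oc, s, ho, wo))
            for o in range(oc):
                for t in range(s):
                    for i in range(ho):
                        for j in range(wo):
                            out[:, o, t, i, j] = (
                                ap[:, :, t:t + ks, i:i + kh, j:j + kw] * w[o]
                            ).sum(axis=(1, 2, 3, 4)) + b[o]
            a = out
        elif kind == "SpectralConv":
            w, b = layer.w.astype(np.float64), layer.b
            oc, cin, k = w.shape
            st = layer.stride
            _, _, s, h, wd = a.shape
            ap = np.pad(a, ((0, 0), (0, 0), (1, 1), (0, 0), (0, 0)))
            so = (s + 2 - k) // st + 1
            out = np.zeros((n, oc, so, h, wd))
            for o in range(oc):
                for t in range(so):
                    out[:, o, t] = (ap[:, :, st * t:st * t + k]
                                    * w[o][None, :, :, None, None]).sum(axis=(1, 2)) + b[o]
            a = out
        elif kind == "ReLU":
            a = np.maximum(a, 0)
        elif kind == "Flatten":
            a = a[:, :, :, 0, 0].transpose(0, 2, 1).reshape(n, -1)
        elif kind == "Linear":
            a = a @ layer.w.T.astype(np.float64) + layer.b
    return a


class TestArchitecture:
    def test_per_layer_parameter_counts(self, default_model):
        per_layer, total = count_parameters(default_model)
        assert per_layer == EXPECTED_COUNTS
        assert total == 31_532

    def test_fc_count_closed_form(self, default_model):
        fc = default_model.trainable_layers[-1]
        assert fc.n_params() == 455 * 2 + 2 == 912

    def test_conv2_count_closed_form(self, default_model):
        conv2 = dict((l.name, l) for l in default_model.trainable_layers)["Conv2"]
        assert conv2.n_params() == 3 * 3 * 3 * 20 * 35 + 35 == 18_935

    def test_declared_shape_trace(self):
        trace = default_model_spec().shape_trace()
        assert trace["fc_in"] == 455
        assert trace["spectral"][-1] == 13
        assert trace["spatial"] == [5, 3, 1]

    def test_observed_forward_shape_trace(self, default_model):
        trace = default_model.observed_shape_trace()
        assert trace["spectral"] == [100, 50, 25, 13]
        assert trace["spatial"] == [5, 3, 1]

    def test_inconsistent_spec_names_offending_layer(self):
        bad = ModelSpec(layers=(
            ("conv3d", "Conv1", 20, (3, 3, 3)),
            ("conv3d", "Conv2", 35, (3, 3, 3)),
            ("conv3d", "Conv3", 35, (3, 3, 3)),  # spatial extent exhausted
            ("fc", "FC", 2),
        ))
        with pytest.raises(ModelSpecError, match="Conv3"):
            build_model(bad)

    def test_seeded_init_reproducible(self):
        a, b = build_model(seed=9), build_model(seed=9)
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)


class TestForwardBackward:
    def test_forward_matches_direct_summation_oracle(self, default_model):
        rng = np.random.default_rng(1)
        x = rng.random((3, 5, 5, 100), dtype=np.float32)
        fast = default_model.forward_logits(x)
        slow = naive_forward(default_model, x)
        np.testing.assert_allclose(fast, slow, atol=1e-4)

    def test_gradients_match_finite_differences(self):
        model = build_model(seed=4)
        rng = np.random.default_rng(2)
        x = rng.random((4, 5, 5, 100), dtype=np.float32)
        y = np.array([0, 1, 1, 0])
        wts = np.array([1.0, 2.5, 2.5, 1.0])

        def loss():
            p = softmax(model.forward_logits(x).astype(np.float64))
            return float(np.mean(wts * -np.log(p[np.arange(4), y])))

        logits = model.forward_logits(x, train=True)
        p = softmax(logits)
        g = p
        g[np.arange(4), y] -= 1.0
        g *= (wts / 4)[:, None]
        model.backward(g.astype(np.float32))

        probe = np.random.default_rng(3)
        for layer in model.trainable_layers:  # the input layer still gets dW
            w, gw = layer.params()["w"], layer.grads()["w"]
            flat = w.ravel()
            for _ in range(2):
                i = int(probe.integers(flat.size))
                old = flat[i]
                eps = 1e-3
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert gw.ravel()[i] == pytest.approx(num, rel=0.05, abs=1e-4)

    def test_input_layer_weight_gradient_nonzero(self):
        model = build_model(seed=4)
        x = np.random.default_rng(0).random((4, 5, 5, 100), dtype=np.float32)
        logits = model.forward_logits(x, train=True)
        model.backward(np.ones_like(logits) / 8)
        conv1 = model.trainable_layers[0]
        assert np.abs(conv1.grads()["w"]).max() > 0


class TestPredictScores:
    def test_rows_sum_to_one(self, default_model):
        x = np.random.default_rng(0).random((17, 5, 5, 100), dtype=np.float32)
        scores = default_model.predict_scores(x)
        assert scores.shape == (17, 2)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_patches_get_identical_rows(self, default_model):
        x = np.tile(np.random.default_rng(1).random((1, 5, 5, 100),
                                                    dtype=np.float32), (6, 1, 1, 1))
        scores = default_model.predict_scores(x)
        # rows agree to float32 resolution (BLAS blocking may reorder sums)
        assert np.allclose(scores, scores[0], atol=1e-6)

    def test_zero_logits_give_half_half(self):
        np.testing.assert_allclose(softmax(np.zeros((3, 2))), 0.5)

    def test_wrong_patch_shape_names_expectation(self, default_model):
        with pytest.raises(ShapeError, match="5, 5, 100"):
            default_model.predict_scores(np.zeros((2, 3, 3, 100), dtype=np.float32))


def small_scene(seed=0, h=16, w=14):
    rng = np.random.default_rng(seed)
    wl = np.arange(500.0, 1000.0, 5.0, dtype=np.float32)
    cube = Hypercube(rng.random((h, w, 100)).astype(np.float32), wl, "scene")
    labels = np.zeros((h, w), dtype=np.uint8)
    labels[4:8, 4:8] = 1
    labels[10:12, 3:9] = 2
    return cube, AnnotationMask(labels)


class TestPredictMap:
    def test_empty_support_predicts_nothing(self, default_model):
        cube, _ = small_scene()
        empty = AnnotationMask(np.zeros(cube.shape[:2], dtype=np.uint8))
        pm = predict_map(default_model, cube, support=empty)
        assert pm.class_map.sum() == 0

    def test_result_independent_of_batch_size(self, default_model):
        cube, mask = small_scene()
        a = predict_map(default_model, cube, support=mask, batch_size=7)
        b = predict_map(default_model, cube, support=mask, batch_size=4096)
        np.testing.assert_array_equal(a.class_map, b.class_map)
        np.testing.assert_allclose(a.score_map, b.score_map, atol=1e-6)

    def test_class_map_is_argmax_of_scores(self, default_model):
        cube, mask = small_scene(seed=2)
        pm = predict_map(default_model, cube, support=mask)
        sel = pm.evaluated()
        np.testing.assert_array_equal(
            pm.class_map[sel],
            np.where(pm.score_map[sel][:, 0] >= pm.score_map[sel][:, 1], 1, 2))
        assert set(np.unique(pm.class_map)) <= {0, 1, 2}

    def test_support_all_covers_interior(self, default_model):
        cube, _ = small_scene()
        pm = predict_map(default_model, cube, support="all")
        h, w, _ = cube.shape
        assert (pm.class_map > 0).sum() == (h - 4) * (w - 4)

    def test_mismatched_band_count_rejected(self, default_model):
        wl = np.arange(500.0, 750.0, 5.0, dtype=np.float32)
        cube = Hypercube(np.ones((10, 10, 50), dtype=np.float32), wl, "x")
        with pytest.raises(ShapeError, match="bands"):
            predict_map(default_model, cube)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, default_model):
        x = np.random.default_rng(5).random((4, 5, 5, 100), dtype=np.float32)
        before = default_model.predict_scores(x)
        save_checkpoint(default_model, tmp_path / "ckpt.npz")
        restored = load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(restored.predict_scores(x), before)
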