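"""Decay classifier machinery: patch grids, overlap-tile recombination,
threshold selection, longitudinal smoothing, quantification and training."""

import numpy as np
import pytest

from deadwoodct.ctvolume import ParameterError
from deadwoodct.decay import (
    AnnotationSet,
    DataError,
    SegmentationNet,
    TrainConfig,
    build_patch_grid,
    cosine_weight_window,
    overlap_percent,
    predict_slice,
    quantify_decay,
    select_threshold,
    smooth_longitudinal,
    train_decay_model,
)
from deadwoodct.decay.patches import ProbabilityVolume


class TestPatchGrid:
    def test_standard_slice_enumeration(self):
        grid = build_patch_grid((96, 96), 48, 12)
        assert grid.rows == (0, 12, 24, 36, 48)
        assert grid.cols == (0, 12, 24, 36, 48)
        assert len(grid) == 25

    def test_stride_equal_size_tiles_without_overlap(self):
        grid = build_patch_grid((96, 96), 48, 48)
        assert grid.rows == (0, 48)
        covered = np.zeros((96, 96), dtype=int)
        for r, c in grid.positions:
            covered[r : r + 48, c : c + 48] += 1
        assert (covered == 1).all()

    def test_border_anchors_clamped(self):
        grid = build_patch_grid((50, 50), 48, 12)
        assert grid.rows == (0, 2)

    def test_full_coverage(self):
        grid = build_patch_grid((70, 55), 48, 12)
        covered = np.zeros((70, 55), dtype=bool)
        for r, c in grid.positions:
            covered[r : r + 48, c : c + 48] = True
        assert covered.all()

    def test_patch_larger_than_slice_rejected(self):
        with pytest.raises(ParameterError):
            build_patch_grid((40, 96), 48, 12)


class TestOverlap:
    @pytest.mark.parametrize("size,stride,expected", [(48, 12, 75.0), (48, 48, 0.0),
                                                      (48, 24, 50.0)])
    def test_reference_values(self, size, stride, expected):
        assert overlap_percent(size, stride) == pytest.approx(expected)

    def test_matches_pixel_set_intersection_for_all_small_sizes(self):
        # brute-force oracle: row overlap of two neighboring patches
        for size in range(2, 65):
            for stride in range(1, size + 1):
                shared = len(set(range(size)) & set(range(stride, stride + size)))
                assert overlap_percent(size, stride) == pytest.approx(100.0 * shared / size)

    def test_stride_beyond_size_rejected(self):
        with pytest.raises(ParameterError):
            overlap_percent(48, 49)


class TestCosineWindow:
    def test_center_is_maximal_and_corners_minimal_positive(self):
        w = cosine_weight_window(48)
        assert w.max() == w[23:25, 23:25].max()
        corners = [w[0, 0], w[0, -1], w[-1, 0], w[-1, -1]]
        assert len(set(corners)) == 1
        assert corners[0] == w.min() > 0

    def test_eightfold_symmetry(self):
        w = cosine_weight_window(32)
        np.testing.assert_allclose(w, w[::-1])
        np.testing.assert_allclose(w, w[:, ::-1])
        np.testing.assert_allclose(w, w.T)


class TestPredictSlice:
    def test_constant_model_reproduces_constant(self, constant_model):
        image = np.zeros((96, 96), dtype=np.float32)
        for size, stride in [(48, 12), (48, 48), (48, 17), (32, 8)]:
            grid = build_patch_grid(image.shape, size, stride)
            out = predict_slice(constant_model(0.7), image, grid,
                                cosine_weight_window(size))
            np.testing.assert_allclose(out, 0.7, atol=1e-12)

    def test_identity_model_reproduces_input(self, identity_model):
        rng = np.random.default_rng(0)
        image = rng.random((96, 96)).astype(np.float32)
        out = predict_slice(identity_model, image)
        np.testing.assert_allclose(out, image, atol=1e-6)

    def test_non_overlapping_box_weights_equal_naive_tiling(self, identity_model):
        rng = np.random.default_rng(1)
        image = rng.random((96, 96)).astype(np.float32)
        grid = build_patch_grid(image.shape, 48, 48)
        out = predict_slice(identity_model, image, grid, np.ones((48, 48)))
        np.testing.assert_allclose(out, image, atol=1e-12)

    def test_slice_smaller_than_patch_rejected(self, constant_model):
        with pytest.raises(ParameterError):
            predict_slice(constant_model(0.5), np.zeros((30, 30)))


def _brute_force_threshold(probs, labels, candidates):
    best_t, best_f1 = None, -1.0
    for t in candidates:
        pred = probs >= t
        tp = np.sum(pred & labels)
        fp = np.sum(pred & ~labels)
        fn = np.sum(~pred & labels)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t, best_f1


class TestSelectThreshold:
    def test_perfect_probabilities_pick_lowest_candidate(self):
        labels = np.array([0, 1, 0, 1, 1], dtype=bool)
        t = select_threshold(labels.astype(float), labels)
        assert t.threshold == pytest.approx(0.01)
        assert t.f1 == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        candidates = np.round(np.arange(0.01, 1.0, 0.01), 2)
        for _ in range(20):
            labels = rng.random(50) < 0.4
            if not labels.any():
                labels[0] = True
            probs = np.clip(labels + rng.normal(0, 0.4, 50), 0, 1)
            got = select_threshold(probs, labels, candidates)
            want_t, want_f1 = _brute_force_threshold(probs, labels, candidates)
            assert got.threshold == pytest.approx(want_t)
            assert got.f1 == pytest.approx(want_f1)

    def test_probability_shift_moves_the_optimum(self):
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1, 1, 0], dtype=bool)
        probs = np.array([0.8, 0.7, 0.65, 0.3, 0.2, 0.4, 0.35, 0.75, 0.6, 0.25])
        candidates = np.round(np.arange(0.01, 1.0, 0.01), 2)
        base = select_threshold(probs, labels, candidates)
        shifted = select_threshold(np.clip(probs + 0.1, 0, 1), labels, candidates)
        want_t, _ = _brute_force_threshold(np.clip(probs + 0.1, 0, 1), labels, candidates)
        assert shifted.threshold == pytest.approx(want_t)
        assert shifted.threshold >= base.threshold

    def test_no_positive_labels_is_an_error(self):
        with pytest.raises(ParameterError, match="no positive"):
            select_threshold(np.array([0.2, 0.8]), np.array([0, 0]))


def _prob_volume(values):
    return ProbabilityVolume(np.asarray(values, dtype=np.float32), (0.5, 0.5), 1.0)


class TestSmoothLongitudinal:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        pv = _prob_volume(rng.random((10, 8, 8)))
        np.testing.assert_array_equal(smooth_longitudinal(pv, 0.0).values, pv.values)

    def test_constant_volume_unchanged(self):
        pv = _prob_volume(np.full((12, 6, 6), 0.3))
        np.testing.assert_allclose(smooth_longitudinal(pv, 5.0).values, 0.3, atol=1e-7)

    def test_alternating_slices_converge_to_half(self):
        values = np.zeros((120, 4, 4), dtype=np.float32)
        values[::2] = 1.0
        out = smooth_longitudinal(_prob_volume(values), 8.0).values
        # central slices: outside the reach of boundary padding
        np.testing.assert_allclose(out[40:80], 0.5, atol=1e-3)

    def test_reduces_adjacent_slice_fraction_jitter(self):
        # slice-wise jitter on a smooth longitudinal decay profile
        rng = np.random.default_rng(4)
        base = 0.5 + 0.3 * np.sin(np.linspace(0, np.pi, 30))[:, None, None]
        noisy = np.clip(base + rng.normal(0, 0.15, (30, 1, 1)), 0, 1)
        pv = _prob_volume(np.broadcast_to(noisy, (30, 16, 16)).copy())
        frac = lambda v: (v >= 0.6).mean(axis=(1, 2))
        jitter = lambda v: np.abs(np.diff(frac(v))).mean()
        smoothed = smooth_longitudinal(pv, 1.5)
        assert jitter(smoothed.values) < jitter(pv.values)


class TestQuantifyDecay:
    def test_all_zero_probability_is_zero_percent(self):
        wood = np.ones((4, 8, 8), dtype=bool)
        assert quantify_decay(_prob_volume(np.zeros((4, 8, 8))), 0.5, wood) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        pv = _prob_volume(rng.random((4, 8, 8)))
        wood = np.ones((4, 8, 8), dtype=bool)
        estimates = [quantify_decay(pv, t, wood) for t in (0.2, 0.5, 0.8)]
        assert estimates[0] >= estimates[1] >= estimates[2]

    def test_crack_voxels_never_counted(self):
        pv = _prob_volume(np.ones((2, 4, 4)))
        wood = np.ones((2, 4, 4), dtype=bool)
        crack = np.zeros((2, 4, 4), dtype=bool)
        crack[0] = True
        assert quantify_decay(pv, 0.5, wood, crack) == pytest.approx(50.0)

    def test_empty_wood_mask_is_an_error(self):
        with pytest.raises(ParameterError):
            quantify_decay(_prob_volume(np.zeros((2, 4, 4))), 0.5,
                           np.zeros((2, 4, 4), dtype=bool))


class TestSegmentationNet:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = SegmentationNet(base_channels=2, seed=1)
        x = rng.normal(0.3, 0.1, size=(2, 8, 8))
        y = (rng.random((2, 8, 8)) > 0.7).astype(float)
        _, grads = net.loss_and_grads(x, y)
        eps = 1e-6
        for name in ("c1a.w", "c2.w", "c3.w", "u2.w", "u1.w", "out.w"):
            flat = net.params[name].ravel()
            g = grads[name].ravel()
            for i in rng.integers(0, flat.size, size=3):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = net.loss_and_grads(x, y)
                flat[i] = orig - eps
                lm, _ = net.loss_and_grads(x, y)
                flat[i] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(g[i], rel=1e-4, abs=1e-7)

    def test_output_shape_and_range(self):
        from deadwoodct.decay import DecayModel

        model = DecayModel(net=SegmentationNet(2, seed=0), config=TrainConfig())
        patches = np.random.default_rng(0).random((3, 16, 16))
        out = model.predict(patches)
        assert out.shape == patches.shape
        assert out.min() >= 0 and out.max() <= 1


def _texture_annotations(n_slices=6, size=40, seed=0):
    """Synthetic annotations: dark flat decay band in a bright striped field."""
    rng = np.random.default_rng(seed)
    images, masks = [], []
    for _ in range(n_slices):
        img = 0.28 + 0.06 * np.sin(np.arange(size) / 2.0)[None, :] * np.ones((size, 1))
        mask = np.zeros((size, size), dtype=np.uint8)
        r0, c0 = rng.integers(4, size - 20, size=2)
        h, w = rng.integers(8, 16, size=2)
        mask[r0 : r0 + h, c0 : c0 + w] = 1
        img = img + rng.normal(0, 0.008, img.shape)
        img[mask == 1] = 0.18 + rng.normal(0, 0.008, int(mask.sum()))
        images.append(img.astype(np.float32))
        masks.append(mask)
    return AnnotationSet(images=images, masks=masks)


class TestTraining:
    def test_loss_decreases_on_synthetic_texture(self):
        ann = _texture_annotations()
        config = TrainConfig(epochs=5, n_patches=48, patch_size=16, base_channels=4,
                             learning_rate=5e-3, seed=0)
        _, history = train_decay_model(ann, config)
        assert np.isfinite(history).all()
        assert history[-1] < history[0]

    def test_all_background_labels_give_background_prediction(self):
        ann = _texture_annotations(seed=1)
        for m in ann.masks:
            m[:] = 0
        ann.masks[0][0, 0] = 0  # keep binary
        config = TrainConfig(epochs=6, n_patches=48, patch_size=16, base_channels=4,
                             learning_rate=5e-3, balance=False, seed=0)
        model, _ = train_decay_model(ann, config)
        fractions = [
            (model.predict(img[:16, :16]) >= 0.5).mean() for img in ann.images
        ]
        assert max(fractions) < 0.01

    def test_empty_annotation_set_rejected(self):
        with pytest.raises(DataError):
            train_decay_model(AnnotationSet(images=[], masks=[]))

    def test_training_is_seed_deterministic(self):
        ann = _texture_annotations()
        config = TrainConfig(epochs=2, n_patches=16, patch_size=16, base_channels=2,
                             seed=3)
        m1, h1 = train_decay_model(ann, config)
        m2, h2 = train_decay_model(ann, config)
        assert h1 == h2
        for k in m1.net.params:
            np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])

    def test_model_round_trips_through_disk(self, tmp_path):
        ann = _texture_annotations()
        config = TrainConfig(epochs=1, n_patches=8, patch_size=16, base_channels=2,
                             seed=0)
        model, _ = train_decay_model(ann, config)
        model.save(tmp_path / "model")
        from deadwoodct.decay import DecayModel

        back = DecayModel.load(tmp_path / "model")
        x = np.random.default_rng(0).random((2, 16, 16))
        np.testing.assert_allclose(back.predict(x), model.predict(x))
        assert back.digest == model.digest


class TestFoldAssignment:
    def test_folds_cover_all_slices_evenly(self):
        ann = _texture_annotations(n_slices=11)
        ann.assign_folds(n_folds=5, seed=0)
        counts = {f: ann.split.count(f) for f in set(ann.split)}
        assert sum(counts.values()) == 11
        assert max(counts.values()) - min(counts.values()) <= 1
        sub = ann.subset({"0"})
        assert len(sub) == counts["0"]
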