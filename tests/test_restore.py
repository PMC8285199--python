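"""Observation model, enhancement, segmentation and edge detection."""

import numpy as np
import pytest

from mritool import (
    AcquisitionModel,
    EnhancementProblem,
    as_image,
    best_threshold_segment,
    edge_detect,
    enhance,
    enhancement_cost,
    forward_observe,
    make_phantom,
    reconstruct,
    run_length_encode,
)
from mritool.errors import DegenerateInputError, InputError
from mritool.restore import _convolve_same, between_class_variance, gradient_magnitude


class TestForwardObserve:
    def test_identity_weighting_copies_pixels(self, rng):
        img = as_image(rng.uniform(0, 1, (4, 4)))
        P = 16
        model = AcquisitionModel(np.eye(P)[None], np.zeros((1, P)), P)
        frames = forward_observe(img, model)
        np.testing.assert_array_equal(frames[0], img.values.ravel())

    def test_zero_weights_return_offsets(self, rng):
        img = as_image(rng.uniform(0, 1, (4, 4)))
        offsets = rng.normal(size=(2, 5))
        model = AcquisitionModel(np.zeros((2, 5, 16)), offsets, 16)
        frames = forward_observe(img, model)
        np.testing.assert_array_equal(np.stack(frames), offsets)

    def test_matches_triple_loop(self, rng):
        img = as_image(rng.uniform(0, 1, (6, 6)))
        M, N, P = 3, 20, 36
        Q = rng.normal(size=(M, N, P))
        offs = rng.normal(size=(M, N))
        model = AcquisitionModel(Q, offs, P)
        frames = np.stack(forward_observe(img, model))
        x = img.values.ravel()
        expected = np.zeros((M, N))
        for m in range(M):
            for n in range(N):
                acc = offs[m, n]
                for s in range(P):
                    acc += Q[m, n, s] * x[s]
                expected[m, n] = acc
        np.testing.assert_allclose(frames, expected, atol=1e-12)

    def test_size_mismatch_rejected(self, rng):
        img = as_image(rng.uniform(0, 1, (4, 4)))
        model = AcquisitionModel(np.zeros((1, 2, 9)), np.zeros((1, 2)), 9)
        with pytest.raises(InputError):
            forward_observe(img, model)


class TestReconstruct:
    def test_noiseless_invertible_recovery(self, rng):
        img = as_image(rng.uniform(0.1, 1, (5, 5)))
        P = 25
        Q = (np.eye(P) + 0.1 * rng.normal(size=(P, P)))[None]
        model = AcquisitionModel(Q, rng.normal(size=(1, P)) * 0.1, P)
        frames = forward_observe(img, model)
        rec = reconstruct(frames, model)
        assert not rec.rank_deficient
        np.testing.assert_allclose(rec.estimate, img.values.ravel(), atol=1e-8)

    def test_residual_orthogonal_to_column_space(self, rng):
        P = 16
        Q = rng.normal(size=(3, 10, P))
        model = AcquisitionModel(Q, np.zeros((3, 10)), P)
        frames = rng.normal(size=(3, 10))
        rec = reconstruct(frames, model)
        A = Q.reshape(-1, P)
        resid = A @ rec.estimate - frames.ravel()
        np.testing.assert_allclose(A.T @ resid, 0.0, atol=1e-9)

    def test_error_grows_with_offset_noise(self, rng):
        img = as_image(rng.uniform(0.1, 1, (5, 5)))
        P = 25
        Q = (np.eye(P) + 0.05 * rng.normal(size=(P, P)))[None]
        errs = []
        for sigma in (0.0, 0.01, 0.1):
            noise_rng = np.random.default_rng(42)
            model = AcquisitionModel(Q, np.zeros((1, P)), P)
            frames = np.stack(forward_observe(img, model))
            frames = frames + noise_rng.normal(0, sigma, frames.shape)
            rec = reconstruct(frames, model)
            errs.append(np.linalg.norm(rec.estimate - img.values.ravel()))
        assert errs[0] < errs[1] < errs[2]

    def test_underdetermined_rejected(self, rng):
        model = AcquisitionModel(rng.normal(size=(1, 4, 16)), np.zeros((1, 4)), 16)
        with pytest.raises(InputError):
            reconstruct(rng.normal(size=(1, 4)), model)


class TestEnhancement:
    def test_perfect_candidate_has_zero_cost(self, rng):
        g = rng.uniform(0, 1, (8, 8))
        psf = np.array([[0.0, 1, 0], [1, 4, 1], [0, 1, 0]]) / 8
        b = _convolve_same(g, psf)
        assert enhancement_cost(EnhancementProblem(b, psf, g)) == pytest.approx(0.0)

    def test_matches_double_loop_convolution(self, rng):
        b = rng.uniform(0, 1, (5, 5))
        g = rng.uniform(0, 1, (5, 5))
        psf = rng.uniform(0, 1, (3, 3))
        # direct convolution with centred kernel and replicate padding
        padded = np.pad(g, 1, mode="edge")
        conv = np.zeros_like(g)
        for i in range(5):
            for j in range(5):
                acc = 0.0
                for u in range(3):
                    for v in range(3):
                        # convolution flips the kernel
                        acc += psf[2 - u, 2 - v] * padded[i + u, j + v]
                conv[i, j] = acc
        expected = float(np.sum((b - conv) ** 2))
        assert enhancement_cost(EnhancementProblem(b, psf, g)) == pytest.approx(
            expected, abs=1e-12)

    def test_delta_psf_returns_input(self, rng):
        b = rng.uniform(0, 1, (8, 8))
        psf = np.zeros((3, 3))
        psf[1, 1] = 1.0
        np.testing.assert_allclose(enhance(b, psf, iterations=1), b)

    def test_descent_reduces_cost_and_is_deterministic(self, rng):
        truth = make_phantom((32, 32), "blobs", 5).values
        psf = np.ones((3, 3)) / 9.0
        b = _convolve_same(truth, psf)
        g1 = enhance(b, psf, iterations=100)
        g2 = enhance(b, psf, iterations=100)
        np.testing.assert_array_equal(g1, g2)
        c0 = enhancement_cost(EnhancementProblem(b, psf, b))
        c1 = enhancement_cost(EnhancementProblem(b, psf, g1))
        assert c1 < c0
        assert np.all(g1 >= 0)

    def test_empty_psf_rejected(self):
        with pytest.raises(InputError):
            enhancement_cost(EnhancementProblem(np.ones((4, 4)),
                                                np.empty((0, 0)),
                                                np.ones((4, 4))))


class TestSegmentation:
    def test_bimodal_split_exact(self):
        img = make_phantom((64, 64), "step_wedge", 0)  # levels 0.25 / 0.75
        res = best_threshold_segment(img)
        assert 0.25 < res.threshold <= 0.75
        np.testing.assert_array_equal(res.mask, img.values >= 0.75)

    def test_matches_exhaustive_scan(self, rng):
        # independent oracle: sigma_b^2 = w0 mu0^2 + w1 mu1^2 - mu^2
        for seed in range(10):
            img = as_image(np.random.default_rng(seed).uniform(0, 1, (24, 24)))
            res = best_threshold_segment(img, levels=64)
            v = img.values
            lo, hi = v.min(), v.max()
            cands = np.linspace(lo, hi, 65)[1:-1]
            best_t, best_c = None, -1.0
            mu = v.mean()
            for t in cands:
                m = v >= t
                if m.all() or not m.any():
                    c = 0.0
                else:
                    w1 = m.mean()
                    w0 = 1 - w1
                    c = w0 * v[~m].mean() ** 2 + w1 * v[m].mean() ** 2 - mu ** 2
                if c > best_c:
                    best_t, best_c = t, c
            assert res.threshold == pytest.approx(best_t)
            assert res.criterion_value == pytest.approx(best_c, abs=1e-12)

    def test_inversion_complements_mask(self):
        img = make_phantom((64, 64), "blobs", 4)
        res = best_threshold_segment(img)
        inv = as_image(img.values.max() - img.values)
        res_inv = best_threshold_segment(inv)
        # away from threshold ties the two masks are complementary
        strict = (np.abs(img.values - res.threshold) > 1e-9) & \
                 (np.abs(inv.values - res_inv.threshold) > 1e-9)
        assert np.array_equal(res.mask[strict], ~res_inv.mask[strict])

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            best_threshold_segment(as_image(np.full((8, 8), 0.5)))

    def test_criterion_is_between_class_variance(self, rng):
        v = rng.uniform(0, 1, (12, 12))
        t = 0.5
        m = v >= t
        w1 = m.mean()
        expected = (1 - w1) * w1 * (v[m].mean() - v[~m].mean()) ** 2
        assert between_class_variance(v, t) == pytest.approx(expected)


class TestEdges:
    def test_constant_image_has_no_edges(self):
        assert not edge_detect(as_image(np.full((16, 16), 0.3)), 0.0).any()

    def test_vertical_step_flags_step_columns(self):
        img = make_phantom((16, 16), "step_wedge", 0)
        edges = edge_detect(img, threshold=0.1)
        expected = np.zeros((16, 16), dtype=bool)
        expected[:, 7:9] = True  # central difference spans the step
        np.testing.assert_array_equal(edges, expected)

    def test_matches_neighborhood_difference_loop(self, rng):
        v = rng.uniform(0, 1, (10, 10))
        mag = gradient_magnitude(v)
        expected = np.zeros_like(v)
        for i in range(10):
            for j in range(10):
                ip, im = min(i + 1, 9), max(i - 1, 0)
                jp, jm = min(j + 1, 9), max(j - 1, 0)
                gy = (v[ip, j] - v[im, j]) / 2.0
                gx = (v[i, jp] - v[i, jm]) / 2.0
                expected[i, j] = np.hypot(gy, gx)
        np.testing.assert_allclose(mag, expected, atol=1e-12)

    def test_homogeneity_under_intensity_scaling(self, rng):
        v = rng.uniform(0, 1, (12, 12))
        e1 = edge_detect(as_image(v), threshold=0.2)
        e2 = edge_detect(as_image(2 * v), threshold=0.4)
        np.testing.assert_array_equal(e1, e2)


def test_run_length_encode_round_trip(rng):
    mask = rng.uniform(size=30) > 0.5
    runs = run_length_encode(mask)
    rebuilt = np.zeros(30, dtype=bool)
    for start, length in runs:
        rebuilt[start:start + length] = True
    np.testing.assert_array_equal(rebuilt, mask)
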