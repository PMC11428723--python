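"""Loss terms versus independent brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepreg import (DisplacementField, LossConfig, local_ncc, similarity_loss,
                     smoothness_loss, total_loss)
from stepreg.volumes import BinaryMask


def ncc_map_bruteforce(f, w, n, eps, variant="squared"):
    """Naive double-loop local NCC over border-truncated windows."""
    r = n // 2
    out = np.zeros(f.shape)
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            for k in range(f.shape[2]):
                sl = tuple(slice(max(0, q - r), min(s, q + r + 1))
                           for q, s in zip((i, j, k), f.shape))
                fw = f[sl].ravel()
                ww = w[sl].ravel()
                m = float(fw.size)
                cross = fw @ ww - fw.sum() * ww.sum() / m
                varf = fw @ fw - fw.sum() ** 2 / m
                varw = ww @ ww - ww.sum() ** 2 / m
                if variant == "squared":
                    out[i, j, k] = cross * cross / (varf * varw + eps)
                else:
                    out[i, j, k] = cross / np.sqrt(varf * varw + eps)
    return out


def smoothness_bruteforce(u):
    """Triple-loop forward-difference gradient energy on the common interior."""
    _, L, W, D = u.shape
    acc = 0.0
    for c in range(3):
        for i in range(L - 1):
            for j in range(W - 1):
                for k in range(D - 1):
                    acc += (u[c, i + 1, j, k] - u[c, i, j, k]) ** 2
                    acc += (u[c, i, j + 1, k] - u[c, i, j, k]) ** 2
                    acc += (u[c, i, j, k + 1] - u[c, i, j, k]) ** 2
    return acc / ((L - 1) * (W - 1) * (D - 1))


class TestLocalNCC:
    def test_self_correlation_is_one(self, rng):
        a = rng.random((10, 10, 10))
        _, mean = local_ncc(a, a, window=5)
        assert mean == pytest.approx(1.0, abs=1e-3)

    def test_affine_intensity_invariance(self, rng):
        a = rng.random((10, 10, 10))
        _, mean = local_ncc(a, 2.0 * a + 3.0, window=5)
        assert mean == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("variant", ["signed", "squared"])
    def test_matches_bruteforce_oracle(self, rng, variant):
        f = rng.random((7, 7, 7))
        w = rng.random((7, 7, 7))
        cc, _ = local_ncc(f, w, window=5, epsilon=1e-5, variant=variant)
        expected = ncc_map_bruteforce(f, w, 5, 1e-5, variant)
        np.testing.assert_allclose(cc, expected, atol=1e-5)

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError):
            local_ncc(rng.random((6, 6, 6)), rng.random((6, 6, 6)), window=4)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            local_ncc(rng.random((6, 6, 6)), rng.random((6, 6, 5)), window=3)


class TestSimilarityLoss:
    def test_identical_images_empty_mask(self, rng):
        a = rng.random((12, 12, 12))
        cfg = LossConfig(ncc_window=5)
        assert similarity_loss(a, a, None, cfg) == pytest.approx(-1.0, abs=1e-3)

    def test_mask_excludes_corrupted_corner(self, rng):
        a = rng.random((14, 14, 14))
        b = a.copy()
        mask = np.zeros(a.shape)
        b[:5, :5, :5] = 0.0  # corrupt a corner
        mask[:7, :7, :7] = 1  # mask it out generously (window bleed)
        cfg = LossConfig(ncc_window=5)
        got = similarity_loss(a, b, BinaryMask(mask.astype(np.uint8)), cfg)
        assert got == pytest.approx(-1.0, abs=5e-3)

    def test_all_ones_mask_returns_zero_with_warning(self, rng):
        a = rng.random((6, 6, 6))
        cfg = LossConfig(ncc_window=3)
        with pytest.warns(RuntimeWarning):
            assert similarity_loss(a, a, np.ones(a.shape), cfg) == 0.0

    def test_masked_mean_oracle(self, rng):
        """Count-normalized masked aggregation equals the explicit average."""
        f = rng.random((8, 8, 8))
        w = rng.random((8, 8, 8))
        mask = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        cfg = LossConfig(ncc_window=5)
        cc, _ = local_ncc(f, w, 5, cfg.epsilon)
        expected = -cc[mask == 0].mean()
        got = similarity_loss(f, w, BinaryMask(mask), cfg)
        assert got == pytest.approx(expected, abs=1e-10)


class TestSmoothnessLoss:
    def test_constant_field_scores_zero(self):
        u = np.ones((3, 6, 6, 6)) * 3.3
        assert smoothness_loss(DisplacementField(u)) == 0.0

    def test_unit_slope_scores_one(self):
        from stepreg.transform import identity_grid

        u = np.zeros((3, 6, 6, 6))
        u[0] = identity_grid((6, 6, 6))[0]
        assert smoothness_loss(DisplacementField(u)) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        u = rng.standard_normal((3, 5, 4, 6))
        got = smoothness_loss(DisplacementField(u))
        assert got == pytest.approx(smoothness_bruteforce(u), abs=1e-6)

    @settings(max_examples=15, deadline=None)
    @given(st.floats(-5, 5), st.integers(0, 2 ** 31 - 1))
    def test_invariant_to_constant_offset(self, c, seed):
        u = np.random.default_rng(seed).standard_normal((3, 5, 5, 5))
        a = smoothness_loss(DisplacementField(u))
        b = smoothness_loss(DisplacementField(u + c))
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            smoothness_loss(DisplacementField(np.zeros((3, 1, 4, 4))))


class TestTotalLoss:
    def test_identity_case(self, rng):
        a = rng.random((10, 10, 10))
        cfg = LossConfig(ncc_window=5)
        z = DisplacementField.zero(a.shape)
        total, parts = total_loss(a, a, None, z, cfg)
        assert total == pytest.approx(-1.0, abs=1e-3)
        assert parts["regularization"] == 0.0

    def test_default_lambda(self):
        assert LossConfig().lambda_reg == pytest.approx(0.1)

    def test_lambda_zero_equals_similarity(self, rng):
        a = rng.random((8, 8, 8))
        b = rng.random((8, 8, 8))
        f = DisplacementField(rng.standard_normal((3, 8, 8, 8)))
        cfg = LossConfig(ncc_window=3, lambda_reg=0.0)
        total, parts = total_loss(a, b, None, f, cfg)
        assert total == parts["similarity"]

    def test_breakdown_identity(self, rng):
        a = rng.random((8, 8, 8))
        b = rng.random((8, 8, 8))
        f = DisplacementField(rng.standard_normal((3, 8, 8, 8)) * 0.3)
        cfg = LossConfig(ncc_window=3, lambda_reg=0.1)
        total, parts = total_loss(a, b, None, f, cfg)
        assert total == pytest.approx(
            parts["similarity"] + 0.1 * parts["regularization"], abs=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LossConfig(ncc_window=4)
        with pytest.raises(ValueError):
            LossConfig(lambda_reg=-0.1)


class TestDifferentiability:
    """Finite-difference checks of the training-time loss gradients."""

    @pytest.mark.parametrize("variant", ["signed", "squared"])
    def test_similarity_gradient_wrt_warped(self, rng, variant):
        from stepreg import _engine as eng

        f = rng.random((8, 8, 8))
        w0 = f + 0.2 * rng.standard_normal((8, 8, 8))
        mask = (rng.random((8, 8, 8)) < 0.2).astype(float)
        wt = eng.parameter(w0.copy())
        loss = eng.masked_ncc_loss(f, wt, mask, 5, 1e-5, variant)
        loss.backward()
        g = wt.grad
        eps = 1e-5
        flat = wt.data.ravel()
        for i in rng.choice(flat.size, 12, replace=False):
            keep = flat[i]
            flat[i] = keep + eps
            lp = float(eng.masked_ncc_loss(f, eng.parameter(wt.data), mask,
                                           5, 1e-5, variant).data)
            flat[i] = keep - eps
            lm = float(eng.masked_ncc_loss(f, eng.parameter(wt.data), mask,
                                           5, 1e-5, variant).data)
            flat[i] = keep
            fd = (lp - lm) / (2 * eps)
            assert g.ravel()[i] == pytest.approx(fd, rel=1e-2, abs=1e-7)

    def test_smoothness_gradient_wrt_field(self, rng):
        from stepreg import _engine as eng

        u = eng.parameter(rng.standard_normal((3, 8, 8, 8)))
        loss = eng.gradient_l2_loss(u)
        loss.backward()
        g = u.grad
        eps = 1e-6
        flat = u.data.ravel()
        for i in rng.choice(flat.size, 12, replace=False):
            keep = flat[i]
            flat[i] = keep + eps
            lp = float(eng.gradient_l2_loss(eng.parameter(u.data)).data)
            flat[i] = keep - eps
            lm = float(eng.gradient_l2_loss(eng.parameter(u.data)).data)
            flat[i] = keep
            fd = (lp - lm) / (2 * eps)
            assert g.ravel()[i] == pytest.approx(fd, rel=1e-2, abs=1e-8)
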