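import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepreg import (DisplacementField, Volume, compose,
                     jacobian_folding_fraction, read_field, sample_field,
                     upsample_field, warp, write_field)
from stepreg.transform import downsample_field, identity_grid


def const_field(shape, vec):
    u = np.zeros((3, *shape))
    for c in range(3):
        u[c] = vec[c]
    return DisplacementField(u)


class TestWarp:
    def test_zero_field_is_identity(self, rng):
        vol = rng.random((8, 7, 6))
        out = warp(vol, DisplacementField.zero(vol.shape))
        np.testing.assert_array_equal(out, vol)

    def test_integer_translation_matches_index_shift(self, rng):
        vol = rng.random((10, 9, 8))
        out = warp(vol, const_field(vol.shape, (1, 0, 0)))
        # output(x) = vol(x+1) on the interior
        np.testing.assert_allclose(out[:-1], vol[1:], atol=1e-12)

    def test_constant_volume_any_field(self, rng):
        vol = np.full((8, 8, 8), 4.2)
        f = DisplacementField(rng.standard_normal((3, 8, 8, 8)) * 2)
        np.testing.assert_allclose(warp(vol, f), 4.2)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            warp(rng.random((4, 4, 4)), DisplacementField.zero((5, 4, 4)))

    def test_volume_wrapper_preserves_metadata(self, rng):
        v = Volume(rng.random((6, 6, 6)), spacing=(2, 2, 2))
        out = warp(v, DisplacementField.zero(v.shape))
        assert isinstance(out, Volume) and out.spacing == (2.0, 2.0, 2.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_range_within_input_range(self, seed):
        r = np.random.default_rng(seed)
        vol = r.random((6, 6, 6))
        f = DisplacementField(r.standard_normal((3, 6, 6, 6)) * 3)
        out = warp(vol, f)
        assert out.min() >= vol.min() - 1e-12
        assert out.max() <= vol.max() + 1e-12


class TestSampleField:
    def test_exact_at_grid_points(self, smooth_field):
        pts = np.array([[2, 3, 4], [0, 0, 0], [11, 9, 7]], dtype=float)
        got = sample_field(smooth_field, pts)
        for p, g in zip(pts.astype(int), got):
            np.testing.assert_allclose(g, smooth_field.u[:, p[0], p[1], p[2]])

    def test_midpoint_linear_interpolation(self):
        u = np.zeros((3, 4, 4, 4))
        u[0, 1] = 0.0
        u[0, 2] = 2.0
        f = DisplacementField(u)
        got = sample_field(f, [[1.5, 1, 1]])
        np.testing.assert_allclose(got[0, 0], 1.0)

    def test_constant_field_everywhere(self):
        f = const_field((5, 5, 5), (1.0, -2.0, 0.5))
        got = sample_field(f, [[0.3, 4.9, 2.2], [-3, 99, 1]])
        np.testing.assert_allclose(got, [[1, -2, 0.5]] * 2)


class TestCompose:
    def test_zero_is_identity_element(self, smooth_field):
        z = DisplacementField.zero(smooth_field.shape)
        np.testing.assert_allclose(compose(z, smooth_field).u, smooth_field.u, atol=1e-9)
        np.testing.assert_allclose(compose(smooth_field, z).u, smooth_field.u, atol=1e-9)

    def test_constant_fields_add(self):
        a = const_field((6, 6, 6), (1, 0, 0))
        b = const_field((6, 6, 6), (0, 2, 0))
        np.testing.assert_allclose(compose(a, b).u, (a.u + b.u))

    def test_sequential_warp_oracle(self, rng, smooth_field):
        """warp(vol, compose(outer, inner)) ~ warp(warp(vol, outer), inner)."""
        from scipy.ndimage import gaussian_filter

        vol = gaussian_filter(rng.random((12, 10, 8)), 1.5)
        inner = DisplacementField(smooth_field.u * 0.5)
        outer = DisplacementField(np.roll(smooth_field.u, 3, axis=1) * 0.5)
        once = warp(vol, compose(outer, inner))
        twice = warp(warp(vol, outer), inner)
        interior = (slice(2, -2),) * 3
        assert np.abs(once[interior] - twice[interior]).max() < 5e-3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose(DisplacementField.zero((4, 4, 4)), DisplacementField.zero((5, 4, 4)))


class TestUpsample:
    def test_constant_field_scales_displacements(self):
        f = const_field((8, 8, 4), (1, 0, 0))
        up = upsample_field(f, (16, 16, 8))
        np.testing.assert_allclose(up.u[0], 2.0)
        np.testing.assert_allclose(up.u[1:], 0.0)

    def test_zero_field_stays_zero(self):
        up = upsample_field(DisplacementField.zero((4, 4, 4)), (9, 13, 31))
        assert up.shape == (9, 13, 31)
        np.testing.assert_array_equal(up.u, 0)

    def test_linear_field_matches_closed_form(self):
        shape = (9, 9, 5)
        grid = identity_grid(shape)
        u = np.zeros((3, *shape))
        u[0] = 0.25 * grid[0]  # linear ramp along axis 0
        f = DisplacementField(u)
        tgt = (17, 17, 9)
        up = upsample_field(f, tgt)
        tgrid = identity_grid(tgt)
        # physical position x_t maps to source x_t*(S-1)/(T-1); displacement
        # scales by T/S
        expected = 0.25 * (tgrid[0] * (shape[0] - 1) / (tgt[0] - 1)) * (tgt[0] / shape[0])
        np.testing.assert_allclose(up.u[0], expected, atol=1e-5)

    def test_downscale_request_rejected(self):
        with pytest.raises(ValueError):
            upsample_field(DisplacementField.zero((8, 8, 8)), (4, 8, 8))

    def test_round_trip_constant_exact(self):
        f = const_field((6, 6, 6), (0.5, -1.0, 2.0))
        back = downsample_field(upsample_field(f, (12, 12, 12)), (6, 6, 6))
        np.testing.assert_allclose(back.u, f.u, atol=1e-12)


class TestJacobian:
    def test_zero_field_has_no_folding(self):
        assert jacobian_folding_fraction(DisplacementField.zero((6, 6, 6))) == 0.0

    def test_reflection_folds_everywhere(self):
        grid = identity_grid((8, 8, 8))
        f = DisplacementField(-2.0 * grid)  # x -> -x, det = (-1)^3
        assert jacobian_folding_fraction(f) == 1.0

    def test_small_smooth_field_fold_free(self, smooth_field):
        tiny = DisplacementField(smooth_field.u * 0.1)
        assert jacobian_folding_fraction(tiny) == 0.0

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            jacobian_folding_fraction(DisplacementField.zero((2, 4, 4)))


class TestFieldIO:
    def test_round_trip_with_convention_note(self, tmp_path, smooth_field):
        p = tmp_path / "f.nii.gz"
        write_field(smooth_field, p)
        back = read_field(p)
        np.testing.assert_allclose(back.u, smooth_field.u, atol=1e-6)
        assert (tmp_path / "f_convention.txt").exists()

    def test_nonfinite_field_rejected(self):
        bad = np.zeros((3, 4, 4, 4))
        bad[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            DisplacementField(bad)
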