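"""Warping, composition, Jacobian and affine resampling against naive oracles."""

import numpy as np
import pytest

from petnorm.geometry import (apply_affine, compose_displacements, invert_mapping,
                              jacobian_determinant, warp_labels, warp_volume)
from petnorm.volume import AffineTransform, DisplacementField, Volume


def naive_trilinear_warp(data: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Reference per-voxel trilinear pull-warp with zero padding."""
    out = np.zeros(data.shape, dtype=np.float64)
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                x = i + u[i, j, k, 0]
                y = j + u[i, j, k, 1]
                z = k + u[i, j, k, 2]
                x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
                fx, fy, fz = x - x0, y - y0, z - z0
                acc = 0.0
                for dx in (0, 1):
                    for dy in (0, 1):
                        for dz in (0, 1):
                            xi, yj, zk = x0 + dx, y0 + dy, z0 + dz
                            if 0 <= xi < nx and 0 <= yj < ny and 0 <= zk < nz:
                                w = ((fx if dx else 1 - fx) * (fy if dy else 1 - fy)
                                     * (fz if dz else 1 - fz))
                                acc += w * data[xi, yj, zk]
                out[i, j, k] = acc
    return out


def random_smooth_field(shape, amplitude, rng, sigma=1.5):
    from scipy.ndimage import gaussian_filter
    u = np.stack([gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)],
                 axis=-1)
    u *= amplitude / max(np.abs(u).max(), 1e-12)
    return DisplacementField(u=u.astype(np.float64))


class TestWarpVolume:
    def test_zero_field_identity_bitexact_both_modes(self, rng):
        data = rng.uniform(0, 2, (6, 7, 8)).astype(np.float32)
        vol = Volume(data)
        zero = DisplacementField.zeros(vol.shape)
        for mode in ("linear", "nearest"):
            out = warp_volume(vol, zero, mode=mode)
            assert np.array_equal(out.data, data)
            assert out.data.dtype == data.dtype

    def test_matches_naive_interpolation_oracle(self, rng):
        for _ in range(20):
            data = rng.uniform(0, 1, (7, 6, 8))
            fld = DisplacementField(u=rng.uniform(-3, 3, (7, 6, 8, 3)))
            got = warp_volume(Volume(data), fld).data
            assert np.abs(got - naive_trilinear_warp(data, fld.u)).max() < 1e-6

    def test_ramp_shifted_by_constant_field(self):
        data = np.broadcast_to(np.arange(8, dtype=np.float64)[:, None, None],
                               (8, 4, 4)).copy()
        u = np.zeros((8, 4, 4, 3))
        u[..., 0] = 1.0
        out = warp_volume(Volume(data), DisplacementField(u=u))
        # interior voxel at index i now holds i + 1
        assert np.allclose(out.data[:7], data[:7] + 1.0)

    def test_midpoint_interpolation_forced(self):
        data = np.zeros((2, 2, 2))
        data[1] = 2.0
        u = np.zeros((2, 2, 2, 3))
        u[0, :, :, 0] = 0.5
        out = warp_volume(Volume(data), DisplacementField(u=u))
        assert out.data[0, 0, 0] == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self, rng):
        vol = Volume(rng.uniform(0, 1, (5, 5, 5)))
        with pytest.raises(ValueError, match="grid"):
            warp_volume(vol, DisplacementField.zeros((4, 5, 5)))

    def test_bad_mode_rejected(self, rng):
        vol = Volume(rng.uniform(0, 1, (5, 5, 5)))
        with pytest.raises(ValueError, match="mode"):
            warp_volume(vol, DisplacementField.zeros((5, 5, 5)), mode="cubic")


class TestWarpLabels:
    def test_zero_field_identity(self):
        lab = Volume(np.arange(27).reshape(3, 3, 3))
        out = warp_labels(lab, DisplacementField.zeros((3, 3, 3)))
        assert np.array_equal(out.data, lab.data)

    def test_integer_translation_moves_label_exactly(self):
        lab = np.zeros((6, 6, 6), dtype=np.int32)
        lab[3, 3, 3] = 7
        u = np.zeros((6, 6, 6, 3))
        u[..., 0], u[..., 1], u[..., 2] = 1, -1, 2
        out = warp_labels(Volume(lab), DisplacementField(u=u))
        # pull: output at x reads source at x+u, so the label lands at x = src - u
        expected = np.zeros_like(lab)
        expected[2, 4, 1] = 7
        assert np.array_equal(out.data, expected)

    def test_field_outside_grid_gives_background(self):
        lab = Volume(np.ones((4, 4, 4), dtype=np.int32))
        u = np.full((4, 4, 4, 3), 50.0)
        out = warp_labels(lab, DisplacementField(u=u))
        assert np.array_equal(out.data, np.zeros((4, 4, 4), dtype=np.int32))

    def test_label_set_is_subset(self, rng):
        lab = Volume(rng.integers(0, 5, (8, 8, 8)).astype(np.int32))
        out = warp_labels(lab, random_smooth_field((8, 8, 8), 2.5, rng))
        assert set(np.unique(out.data)) <= set(np.unique(lab.data)) | {0}

    def test_non_integer_rejected(self, rng):
        with pytest.raises(ValueError, match="integer"):
            warp_labels(Volume(rng.uniform(0, 1, (4, 4, 4))),
                        DisplacementField.zeros((4, 4, 4)))


class TestCompose:
    def test_compose_with_zero_is_identity(self, rng):
        u = random_smooth_field((8, 8, 8), 2.0, rng)
        zero = DisplacementField.zeros((8, 8, 8))
        assert np.allclose(compose_displacements(u, zero).u, u.u, atol=1e-6)
        assert np.allclose(compose_displacements(zero, u).u, u.u, atol=1e-6)

    def test_constant_translations_add_on_interior(self):
        a = DisplacementField(u=np.full((8, 8, 8, 3), 1.0))
        b = DisplacementField(u=np.full((8, 8, 8, 3), -0.5))
        w = compose_displacements(a, b)
        assert np.allclose(w.u[2:-2, 2:-2, 2:-2], 0.5, atol=1e-6)

    def test_composition_consistent_with_sequential_warps(self, rng):
        shape = (12, 12, 12)
        # smooth compact-support image (object in air, like PET): the
        # property is about interpolation error, second-order in curvature
        grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
        r2 = sum((g - 5.5) ** 2 for g in grids)
        img = Volume(np.exp(-r2 / 18.0))
        first = random_smooth_field(shape, 1.2, rng, sigma=2.5)
        second = random_smooth_field(shape, 1.2, rng, sigma=2.5)
        two_step = warp_volume(warp_volume(img, first), second)
        one_step = warp_volume(img, compose_displacements(first, second))
        rng_range = img.data.max() - img.data.min()
        assert np.abs(two_step.data - one_step.data).max() < 0.05 * rng_range

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            compose_displacements(DisplacementField.zeros((5, 5, 5)),
                                  DisplacementField.zeros((6, 5, 5)))


class TestJacobian:
    def test_zero_field_is_exactly_one(self):
        det = jacobian_determinant(DisplacementField.zeros((6, 6, 6)))
        assert np.array_equal(det.data, np.ones((6, 6, 6)))

    def test_uniform_expansion_analytic(self):
        shape = (8, 8, 8)
        grids = np.stack(np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                                     indexing="ij"), axis=-1)
        det = jacobian_determinant(DisplacementField(u=0.1 * grids))
        assert np.allclose(det.data[1:-1, 1:-1, 1:-1], 1.1 ** 3, atol=1e-10)

    def test_matches_independent_finite_difference_oracle(self, rng):
        fld = random_smooth_field((9, 9, 9), 2.0, rng)
        u = fld.u
        det = jacobian_determinant(fld).data
        # independent oracle: explicit central differences at one interior voxel
        for (i, j, k) in [(3, 4, 5), (2, 2, 2), (6, 3, 4)]:
            J = np.eye(3)
            for comp in range(3):
                J[comp, 0] += (u[i + 1, j, k, comp] - u[i - 1, j, k, comp]) / 2
                J[comp, 1] += (u[i, j + 1, k, comp] - u[i, j - 1, k, comp]) / 2
                J[comp, 2] += (u[i, j, k + 1, comp] - u[i, j, k - 1, comp]) / 2
            assert det[i, j, k] == pytest.approx(np.linalg.det(J), abs=1e-6)


class TestApplyAffine:
    def test_identity_bitexact(self, rng):
        vol = Volume(rng.uniform(0, 1, (6, 6, 6)).astype(np.float32))
        out = apply_affine(vol, AffineTransform.identity())
        assert np.array_equal(out.data, vol.data)

    def test_integer_translation_index_oracle(self, rng):
        data = rng.uniform(0, 1, (8, 8, 8))
        tf = AffineTransform(translation=np.array([2.0, 0.0, -1.0]))
        out = apply_affine(Volume(data), tf)
        expected = np.zeros_like(data)
        expected[:6, :, 1:] = data[2:, :, :7]
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_scaling_constant_volume_stays_constant_inside(self):
        vol = Volume(np.full((10, 10, 10), 3.5))
        tf = AffineTransform(matrix=0.5 * np.eye(3))  # pull scale -> 2x magnification
        out = apply_affine(vol, tf)
        assert np.allclose(out.data[1:-1, 1:-1, 1:-1], 3.5)

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(matrix=np.zeros((3, 3)))


class TestInvertMapping:
    def test_roundtrip_accuracy(self, rng):
        shape = (16, 16, 16)
        fld = random_smooth_field(shape, 2.0, rng)
        tf = AffineTransform(matrix=np.diag([1.02, 0.98, 1.0]),
                             translation=np.array([0.5, -0.3, 0.2]))
        y = invert_mapping(fld, tf)
        # forward map applied at y should land back on the identity grid
        from scipy.ndimage import map_coordinates
        u_at_y = np.stack([map_coordinates(fld.u[..., c].astype(np.float64),
                                           np.moveaxis(y, -1, 0), order=1, mode="nearest")
                           for c in range(3)], axis=-1)
        fwd = (y + u_at_y) @ tf.matrix.T + tf.translation
        grids = np.stack(np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                                     indexing="ij"), axis=-1)
        interior = (slice(2, -2),) * 3
        assert np.abs((fwd - grids)[interior]).max() < 0.05
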