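"""Warping, resampling, field composition and differential diagnostics.

All operations use pull (backward) semantics on voxel-space coordinates:
the output at voxel ``x`` samples its source at a mapped location, and
samples falling outside the source grid read 0 (PET background is air).
Resampling itself is delegated to ``scipy.ndimage``; this module owns the
coordinate conventions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import AffineTransform, DisplacementField, Volume

__all__ = [
    "warp_volume",
    "warp_labels",
    "compose_displacements",
    "jacobian_determinant",
    "apply_affine",
    "invert_mapping",
    "resample_chain",
]


def _identity_coords(shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel index grid, shape (3, nx, ny, nz), float64."""
    return np.stack(np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape),
                                indexing="ij"))


def warp_volume(source: Volume, field: DisplacementField, mode: str = "linear") -> Volume:
    """Pull-warp ``source`` by ``field``: output(x) = source(x + u(x)).

    Parameters
    ----------
    source:
        Volume to sample from.
    field:
        Displacement on the *output* grid, voxel units.
    mode:
        ``"linear"`` (trilinear) or ``"nearest"``. Out-of-grid samples
        return 0.

    Notes
    -----
    A zero field returns a bit-exact copy (short-circuited so the identity
    guarantee does not depend on interpolator rounding).
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if field.grid_shape != source.shape:
        raise ValueError(
            f"field grid {field.grid_shape} does not match output grid {source.shape}")
    if not field.u.any():
        return source.copy()
    coords = _identity_coords(field.grid_shape) + np.moveaxis(field.u.astype(np.float64), -1, 0)
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(source.data, coords, order=order, mode="grid-constant", cval=0.0)
    return source.copy(data=out.astype(source.data.dtype, copy=False))


def warp_labels(labels: Volume, field: DisplacementField) -> Volume:
    """Nearest-neighbour pull-warp of an integer label volume.

    Label identity is preserved — values are never averaged — and the
    output label set is a subset of the input set plus background 0.
    """
    if not labels.is_integer():
        raise ValueError("warp_labels requires an integer label volume")
    return warp_volume(labels, field, mode="nearest")


def compose_displacements(first: DisplacementField, second: DisplacementField) -> DisplacementField:
    """Compose two pull fields: ``w(x) = second(x) + first(x + second(x))``.

    Warping once by ``w`` equals warping by ``second`` and then by
    ``first`` (up to interpolation error). ``first`` is interpolated
    linearly; samples beyond its grid contribute zero displacement,
    matching the zero-padding warp convention.
    """
    if first.grid_shape != second.grid_shape:
        raise ValueError(
            f"cannot compose fields on grids {first.grid_shape} and {second.grid_shape}")
    coords = _identity_coords(second.grid_shape) + np.moveaxis(second.u.astype(np.float64), -1, 0)
    sampled = np.empty(first.u.shape, dtype=np.float64)
    for c in range(3):
        sampled[..., c] = ndimage.map_coordinates(
            first.u[..., c].astype(np.float64), coords, order=1, mode="grid-constant", cval=0.0)
    return DisplacementField(u=(second.u.astype(np.float64) + sampled).astype(np.float32))


def jacobian_determinant(field: DisplacementField) -> Volume:
    """Determinant of ``∂(x + u)/∂x`` per voxel.

    Central differences on interior voxels, one-sided at the boundary
    (``numpy.gradient`` convention). Values ≤ 0 flag folding.
    """
    shape = field.grid_shape
    if min(shape) < 3:
        raise ValueError("jacobian needs at least 3 voxels per axis")
    u = field.u.astype(np.float64)
    jac = np.empty(shape + (3, 3), dtype=np.float64)
    for comp in range(3):
        grads = np.gradient(u[..., comp], axis=(0, 1, 2))
        for ax in range(3):
            jac[..., comp, ax] = grads[ax]
        jac[..., comp, comp] += 1.0
    a = jac
    det = (a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
           - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
           + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]))
    return Volume(data=det, id="jacobian_determinant")


def apply_affine(volume: Volume, transform: AffineTransform,
                 out_shape: tuple[int, int, int] | None = None,
                 mode: str = "linear") -> Volume:
    """Resample ``volume`` under a pull affine: output(x) = volume(Mx + t).

    An exact identity transform with an unchanged grid returns the input
    bit-exactly. Interpolation is trilinear by default (``mode="nearest"``
    for label volumes), zero-padded outside the source grid.
    """
    out_shape = tuple(out_shape) if out_shape is not None else volume.shape
    if transform.is_identity() and out_shape == volume.shape:
        return volume.copy()
    order = 1 if mode == "linear" else 0
    out = ndimage.affine_transform(
        volume.data.astype(np.float64) if order == 1 else volume.data,
        transform.matrix, offset=transform.translation, output_shape=out_shape,
        order=order, mode="grid-constant", cval=0.0)
    return volume.copy(data=out.astype(volume.data.dtype, copy=False))


def resample_chain(volume: Volume, transform: AffineTransform, field: DisplacementField,
                   mode: str = "linear") -> Volume:
    """Single-interpolation resampling through ``x -> M(x + u(x)) + t``.

    Equivalent to ``warp_volume(apply_affine(volume, transform), field)``
    but samples the source only once, avoiding double interpolation blur.
    Used by the phantom generator to realize its ground-truth mapping.
    """
    if transform.is_identity() and not field.u.any() and field.grid_shape == volume.shape:
        return volume.copy()
    pts = _identity_coords(field.grid_shape) + np.moveaxis(field.u.astype(np.float64), -1, 0)
    coords = np.einsum("ab,b...->a...", transform.matrix, pts)
    coords += transform.translation[:, None, None, None]
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(volume.data, coords, order=order, mode="grid-constant", cval=0.0)
    return volume.copy(data=out.astype(volume.data.dtype, copy=False))


def invert_mapping(field: DisplacementField, transform: AffineTransform,
                   n_iter: int = 20) -> np.ndarray:
    """Numerically invert the pull mapping ``g(x) = M(x + u(x)) + t``.

    Returns an array ``y`` of shape ``grid + (3,)`` with ``g(y(x)) ≈ x``
    for every voxel ``x`` of the grid, found by fixed-point iteration
    ``y <- M⁻¹(x − t) − u(y)`` with linear interpolation of ``u``
    (edge-replicated beyond the grid). Converges for the smooth,
    non-folding fields this package produces.
    """
    shape = field.grid_shape
    x = np.moveaxis(_identity_coords(shape), 0, -1)  # (nx,ny,nz,3)
    inv = transform.inverse()
    base = x @ inv.matrix.T + inv.translation
    y = base.copy()
    u64 = field.u.astype(np.float64)
    for _ in range(n_iter):
        coords = np.moveaxis(y, -1, 0)
        u_at_y = np.stack([
            ndimage.map_coordinates(u64[..., c], coords, order=1, mode="nearest")
            for c in range(3)], axis=-1)
        y = base - u_at_y
    return y
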