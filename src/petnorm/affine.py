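"""Conventional 12-parameter affine registration to the template grid.

The deformable network consumes *affine-registered* PET, so a linear
pre-alignment stage is required. It maximizes global normalized
cross-correlation over translation, rotation, anisotropic log-scale and
shear with a multi-resolution (factor-2 pyramid) derivative-free simplex
search, initialized from intensity centroids. Global (unwindowed) NCC
gives a smooth objective for linear alignment; windowed NCC is reserved
for the deformable stage. The stage is intentionally replaceable behind
:func:`register_affine`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .volume import AffineTransform, Volume

__all__ = ["AffineRegResult", "register_affine", "global_ncc"]


@dataclass
class AffineRegResult:
    transform: AffineTransform
    final_similarity: float
    levels: int
    converged: bool


def global_ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equally-shaped grids (similarity, not loss)."""
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom <= 0:
        return 0.0
    return float((a @ b) / denom)


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> AffineTransform:
    """(t, rot, log-scale, shear) -> pull transform about the grid center."""
    t, ang, ls, sh = p[0:3], p[3:6], p[6:9], p[9:12]
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    shear = np.array([[1.0, sh[0], sh[1]], [0.0, 1.0, sh[2]], [0.0, 0.0, 1.0]])
    m = rz @ ry @ rx @ shear @ np.diag(np.exp(ls))
    return AffineTransform(matrix=m, translation=center - m @ center + t)


def _resample(moving: np.ndarray, tf: AffineTransform, out_shape) -> np.ndarray:
    return ndimage.affine_transform(moving, tf.matrix, offset=tf.translation,
                                    output_shape=out_shape, order=1,
                                    mode="grid-constant", cval=0.0)


def _centroid(data: np.ndarray) -> np.ndarray:
    w = np.clip(data.astype(np.float64), 0.0, None)
    total = w.sum()
    if total <= 0:
        return (np.asarray(data.shape, dtype=np.float64) - 1) / 2
    grids = np.meshgrid(*(np.arange(n) for n in data.shape), indexing="ij")
    return np.array([(g * w).sum() / total for g in grids])


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data.astype(np.float64)
    return ndimage.zoom(data.astype(np.float64), 1.0 / factor, order=1,
                        mode="nearest", grid_mode=True)


def register_affine(moving: Volume, fixed: Volume, levels: int = 2,
                    max_iter: int = 400, seed: int = 0) -> AffineRegResult:
    """Estimate the pull affine resampling ``moving`` onto ``fixed``'s grid.

    Coarse-to-fine Nelder-Mead maximization of global NCC: a rigid pass
    (translation + rotation) followed by a full 12-parameter pass at the
    coarsest level, then a shorter full-parameter refinement per finer
    level. Fully deterministic; ``seed`` is accepted for interface
    stability but the search uses no randomness. If the refined optimum
    somehow scores below the centroid initialization, the initialization
    is returned instead (``converged=False``).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    for name, vol in (("moving", moving), ("fixed", fixed)):
        if np.ptp(vol.data) == 0:
            raise ValueError(f"{name} volume is constant; similarity is undefined")

    t0 = _centroid(moving.data) - _centroid(fixed.data)
    p = np.zeros(12)
    p[0:3] = t0

    converged = True
    for li, level in enumerate(range(levels - 1, -1, -1)):
        f = 2 ** level
        mv = _downsample(moving.data, f)
        fx = _downsample(fixed.data, f)
        center = (np.asarray(fx.shape, dtype=np.float64) - 1) / 2
        scale_vec = np.array([f] * 3 + [1.0] * 9)

        def neg_ncc(q, active):
            full = p / scale_vec
            full = full.copy()
            full[active] = q
            tf = _params_to_transform(full, center)
            return -global_ncc(_resample(mv, tf, fx.shape), fx)

        passes = []
        if li == 0:
            passes.append((list(range(6)), max_iter))          # rigid first
        passes.append((list(range(12)), max_iter if li == 0 else max(150, max_iter // 2)))

        steps = np.array([2.0, 2.0, 2.0, 0.06, 0.06, 0.06,
                          0.05, 0.05, 0.05, 0.03, 0.03, 0.03])
        for active, maxfev in passes:
            q0 = (p / scale_vec)[active]
            simplex = np.vstack([q0] + [q0 + steps[a] * e for a, e in
                                        zip(active, np.eye(len(active)))])
            res = optimize.minimize(
                neg_ncc, q0, args=(active,), method="Nelder-Mead",
                options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-6,
                         "initial_simplex": simplex})
            converged = converged and bool(res.success)
            scaled = p / scale_vec
            scaled[active] = res.x
            p = scaled * scale_vec

    center_full = (np.asarray(fixed.shape, dtype=np.float64) - 1) / 2
    best_tf = _params_to_transform(p, center_full)
    best_sim = global_ncc(_resample(moving.data.astype(np.float64), best_tf, fixed.shape),
                          fixed.data)

    init = np.zeros(12)
    init[0:3] = t0
    init_tf = _params_to_transform(init, center_full)
    init_sim = global_ncc(_resample(moving.data.astype(np.float64), init_tf, fixed.shape),
                          fixed.data)
    if init_sim > best_sim:
        return AffineRegResult(transform=init_tf, final_similarity=init_sim,
                               levels=levels, converged=False)
    return AffineRegResult(transform=best_tf, final_similarity=best_sim,
                           levels=levels, converged=converged)
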