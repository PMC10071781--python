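"""Core spatial data containers: :class:`Volume`, :class:`AffineTransform`,
:class:`DisplacementField`, and their NIfTI-1 serialization.

Conventions
-----------
* Grids are indexed ``(i, j, k)`` with 0-based voxel indices; axis 0 is
  left-right, axis 1 posterior-anterior and axis 2 inferior-superior
  (RAS-like), so "inferior" means a smaller axis-2 coordinate.
* Displacement fields use the *pull* convention in voxel units: a warped
  image reads its source at ``x + u(x)``.
* The world affine is carried along for I/O but all registration,
  training and quantification operate in voxel space on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "AffineTransform", "DisplacementField"]


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """A 3-D scalar grid (PET, MR, template, probability or label map).

    Parameters
    ----------
    data:
        3-D array. Finite everywhere; any operation producing NaN/Inf is a
        bug and is rejected at construction.
    spacing:
        Voxel size in mm per axis, strictly positive.
    affine:
        4x4 homogeneous index-to-world map (RAS). Defaults to a diagonal
        built from ``spacing``.
    id:
        Free-text label used in reports and file names.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 2:
            raise ValueError(f"every grid dimension must be >= 2, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 homogeneous matrix")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self, data: np.ndarray | None = None, id: str | None = None) -> "Volume":
        """Shallow metadata copy, optionally swapping in new data."""
        return Volume(
            data=self.data.copy() if data is None else data,
            spacing=self.spacing,
            affine=self.affine.copy(),
            id=self.id if id is None else id,
        )

    def is_integer(self) -> bool:
        """True when the grid holds (possibly float-typed) integer labels."""
        if np.issubdtype(self.data.dtype, np.integer):
            return True
        return bool(np.all(self.data == np.round(self.data)))

    # -- NIfTI I/O ---------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asanyarray(self.data), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, id: str = "") -> "Volume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a scalar 3-D NIfTI, got shape {data.shape}")
        zooms = img.header.get_zooms()[:3]
        return cls(data=data, spacing=tuple(float(z) for z in zooms),
                   affine=np.asarray(img.affine), id=id or Path(path).name)


@dataclass
class AffineTransform:
    """12-parameter pull transform in voxel space.

    Maps an output-grid voxel coordinate ``x`` to the source-grid sampling
    location ``matrix @ x + translation``.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.matrix.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("affine transform needs a 3x3 matrix and a 3-vector")
        if abs(np.linalg.det(self.matrix)) <= 1e-9:
            raise ValueError("affine linear part is numerically singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    def is_identity(self, tol: float = 0.0) -> bool:
        return (np.abs(self.matrix - np.eye(3)).max() <= tol
                and np.abs(self.translation).max() <= tol)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map an ``(..., 3)`` array of voxel coordinates."""
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(matrix=inv, translation=-inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform equivalent to applying ``self`` after ``other`` in pull
        order: ``(self ∘ other)(x) = self(other(x))``."""
        return AffineTransform(matrix=self.matrix @ other.matrix,
                               translation=self.matrix @ other.translation + self.translation)

    def as_matrix_3x4(self) -> np.ndarray:
        return np.hstack([self.matrix, self.translation[:, None]])

    def to_json_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "AffineTransform":
        return cls(matrix=np.asarray(d["matrix"]), translation=np.asarray(d["translation"]))


@dataclass
class DisplacementField:
    """Dense per-voxel displacement ``u`` in voxel units, pull convention.

    ``u`` has shape ``grid_shape + (3,)``; the warped image at voxel ``x``
    samples its source at ``x + u(x)``.
    """

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64 if np.asarray(self.u).dtype == np.float64 else np.float32)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError(f"displacement field must have shape (nx, ny, nz, 3), got {self.u.shape}")
        if not np.isfinite(self.u).all():
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]

    @classmethod
    def zeros(cls, grid_shape: tuple[int, int, int], dtype=np.float32) -> "DisplacementField":
        return cls(u=np.zeros(tuple(grid_shape) + (3,), dtype=dtype))

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.u.astype(np.float64) ** 2).sum(axis=-1))

    def max_magnitude(self) -> float:
        return float(self.magnitude().max())

    # -- NIfTI I/O (4-D, vector component last) ----------------------------
    def to_nifti(self, path: str | Path, spacing=(2.0, 2.0, 2.0)) -> None:
        img = nib.Nifti1Image(self.u, _default_affine(spacing))
        img.header["descrip"] = b"pull displacement field, voxel units"
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "DisplacementField":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector-intent layout
            data = data[:, :, :, 0, :]
        return cls(u=data)
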