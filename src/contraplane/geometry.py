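"""Coordinate conventions, grid/volume containers and plane-frame algebra.

Conventions used throughout the package:

* Voxel indices are 0-based integer triples in array order ``(x, y, z)``,
  matching the on-disk NIfTI array order.
* The world coordinate of a voxel is the position of its **center** in mm:
  ``world(v) = origin_mm + v * spacing_mm`` (elementwise).
* A standard-plane frame stores the common intersection point of the three
  planes plus one unit normal per plane (sagittal, axial, coronal).  The
  matrix with the normals as columns is orthogonal; its determinant encodes
  handedness (+1 right, −1 left), which flips under mirroring and therefore
  tags anatomical laterality.
* Sign convention: the axial normal points from the tibial plafond toward
  the proximal tibia (along the shaft); sagittal and coronal signs complete
  the frame of the declared handedness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DegenerateFrameError, ObliqueAffineError

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "StandardPlaneFrame",
    "voxel_to_world",
    "world_to_voxel",
    "orthonormalize_frame",
    "read_nifti",
    "write_nifti",
    "rotation_matrix",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D scalar lattice: shape, spacing and origin.

    ``origin_mm`` is the world position (mm) of the center of voxel (0,0,0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a triple of positive ints, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_mm must be a triple of positive reals, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge length per axis, counting a full voxel per sample."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    @property
    def center_mm(self) -> np.ndarray:
        """World position of the geometric center of the lattice."""
        return np.asarray(self.origin_mm) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing_mm
        )

    def contains_world(self, point_mm) -> bool:
        """True if ``point_mm`` falls inside the lattice (voxel-center hull)."""
        idx = world_to_voxel(point_mm, self)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        axes = [
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a] for a in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


@dataclass
class ScalarVolume:
    """A 3D scalar image: a :class:`VolumeGrid` plus one value per voxel."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )


def voxel_to_world(index, grid: VolumeGrid) -> np.ndarray:
    """World position (mm) of a voxel center: ``origin + index * spacing``.

    ``index`` may be fractional or out of bounds (useful for padding math)
    and may be an ``(..., 3)`` array of indices.
    """
    index = np.asarray(index, dtype=float)
    return np.asarray(grid.origin_mm) + index * np.asarray(grid.spacing_mm)


def world_to_voxel(point_mm, grid: VolumeGrid) -> np.ndarray:
    """Continuous voxel index of a world point; exact inverse of voxel_to_world.

    Rounding to the nearest lattice index is left to the caller.
    """
    point_mm = np.asarray(point_mm, dtype=float)
    return (point_mm - np.asarray(grid.origin_mm)) / np.asarray(grid.spacing_mm)


_PLANE_NAMES = ("sagittal", "axial", "coronal")


@dataclass
class StandardPlaneFrame:
    """Intersection point plus the three orthonormal standard-plane normals.

    ``n_sag``, ``n_ax`` and ``n_cor`` are unit normals of the sagittal,
    axial and coronal planes.  ``handedness`` is the sign of
    ``det([n_sag n_ax n_cor])``: ``"right"`` for +1, ``"left"`` for −1.
    """

    intersection_mm: np.ndarray
    n_sag: np.ndarray
    n_ax: np.ndarray
    n_cor: np.ndarray
    handedness: str = field(init=False)

    def __post_init__(self):
        self.intersection_mm = np.asarray(self.intersection_mm, dtype=float).reshape(3)
        for name in ("n_sag", "n_ax", "n_cor"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            norm = np.linalg.norm(v)
            if abs(norm - 1.0) > 1e-9:
                raise ValueError(f"{name} must be unit length (|{norm} - 1| > 1e-9)")
            setattr(self, name, v)
        m = self.matrix
        off = m.T @ m - np.eye(3)
        if np.max(np.abs(off[~np.eye(3, dtype=bool)])) >= 1e-6:
            raise ValueError("frame normals are not pairwise orthogonal within 1e-6")
        det = float(np.linalg.det(m))
        if abs(abs(det) - 1.0) > 1e-6:
            raise ValueError(f"frame determinant {det} is not ±1 within 1e-6")
        self.handedness = "right" if det > 0 else "left"

    @property
    def matrix(self) -> np.ndarray:
        """3×3 matrix with columns ``[n_sag, n_ax, n_cor]``."""
        return np.stack([self.n_sag, self.n_ax, self.n_cor], axis=1)

    @property
    def normals(self) -> dict[str, np.ndarray]:
        return {"sagittal": self.n_sag, "axial": self.n_ax, "coronal": self.n_cor}

    def transformed(self, linear: np.ndarray, translation=None) -> "StandardPlaneFrame":
        """Apply an orthogonal linear map (plus optional translation) to the frame."""
        linear = np.asarray(linear, dtype=float)
        p = linear @ self.intersection_mm
        if translation is not None:
            p = p + np.asarray(translation, dtype=float)
        cols = linear @ self.matrix
        return StandardPlaneFrame(p, cols[:, 0], cols[:, 1], cols[:, 2])

    # --- JSON round trip (9 significant digits) -------------------------------

    def to_dict(self) -> dict:
        def sig9(arr):
            return [float(f"{x:.9g}") for x in np.asarray(arr)]

        return {
            "intersection_mm": sig9(self.intersection_mm),
            "n_sag": sig9(self.n_sag),
            "n_ax": sig9(self.n_ax),
            "n_cor": sig9(self.n_cor),
            "handedness": self.handedness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardPlaneFrame":
        raw = np.stack(
            [np.asarray(d["n_sag"], float), np.asarray(d["n_ax"], float), np.asarray(d["n_cor"], float)],
            axis=1,
        )
        # 9-digit serialization can leave norms ~1e-10 off; re-orthonormalize.
        frame = orthonormalize_frame(raw, np.asarray(d["intersection_mm"], float))
        if "handedness" in d and frame.handedness != d["handedness"]:
            raise ValueError("stored handedness does not match the normals' determinant")
        return frame

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "StandardPlaneFrame":
        return cls.from_dict(json.loads(Path(path).read_text()))


def orthonormalize_frame(raw_normals: np.ndarray, intersection_mm) -> StandardPlaneFrame:
    """Assemble a frame from three roughly-orthogonal raw normals.

    ``raw_normals`` is a 3×3 matrix with the raw sagittal, axial and coronal
    normals as *columns*.  The three normals are replaced by the nearest
    orthogonal matrix in the Frobenius sense (the orthogonal polar factor,
    computed by SVD), which treats the three planes symmetrically instead of
    privileging one as Gram–Schmidt would.  Each output column keeps a
    non-negative dot product with its input column, so input directions are
    preserved.  Handedness is read off the determinant.

    Raises :class:`DegenerateFrameError` if any two raw normals are within
    30° of parallel (or anti-parallel).
    """
    n = np.asarray(raw_normals, dtype=float).copy()
    if n.shape != (3, 3):
        raise ValueError("raw_normals must be a 3x3 matrix of column normals")
    norms = np.linalg.norm(n, axis=0)
    if np.any(norms < 1e-12):
        raise DegenerateFrameError("raw normal with zero length")
    n /= norms
    for i in range(3):
        for j in range(i + 1, 3):
            c = abs(float(n[:, i] @ n[:, j]))
            if c > np.cos(np.deg2rad(30.0)):
                raise DegenerateFrameError(
                    f"raw normals {_PLANE_NAMES[i]} and {_PLANE_NAMES[j]} are within 30° of parallel"
                )
    u, _, vt = np.linalg.svd(n)
    q = u @ vt
    # Columns of the polar factor of a frame satisfying the angular
    # precondition already align with their inputs; guard regardless.
    for i in range(3):
        if float(q[:, i] @ n[:, i]) < 0:
            q[:, i] = -q[:, i]
    return StandardPlaneFrame(np.asarray(intersection_mm, float), q[:, 0], q[:, 1], q[:, 2])


def rotation_matrix(angles_deg, order: str = "xyz") -> np.ndarray:
    """Rotation matrix from per-axis Euler angles, applied x-then-y-then-z.

    ``R = Rz @ Ry @ Rx`` so a column vector is rotated about x first.
    """
    ax, ay, az = [np.deg2rad(a) for a in angles_deg]
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    mats = {"x": rx, "y": ry, "z": rz}
    r = np.eye(3)
    for axis in order:
        r = mats[axis] @ r
    return r


# --- NIfTI I/O ----------------------------------------------------------------


def read_nifti(path) -> ScalarVolume:
    """Read an axis-aligned NIfTI volume into a :class:`ScalarVolume`.

    Spacing and origin are taken from the header affine.  Oblique affines
    (any off-diagonal rotation/shear, or negative scales) are rejected:
    only axis-aligned grids are supported.
    """
    img = nib.load(str(path))
    affine = img.affine
    lin = affine[:3, :3]
    off_diag = lin[~np.eye(3, dtype=bool)]
    diag = np.diag(lin)
    if np.any(np.abs(off_diag) > 1e-6 * max(1.0, np.max(np.abs(diag)))) or np.any(diag <= 0):
        raise ObliqueAffineError(
            f"{path}: affine is oblique or axis-flipped; only axis-aligned grids "
            "with positive spacing are supported"
        )
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    grid = VolumeGrid(tuple(data.shape), tuple(float(d) for d in diag), tuple(float(t) for t in affine[:3, 3]))
    return ScalarVolume(grid, data.astype(np.float32, copy=False))


def write_nifti(volume: ScalarVolume, path, dtype=None) -> None:
    """Write a :class:`ScalarVolume` as NIfTI-1 with an axis-aligned affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.grid.spacing_mm)
    affine[:3, 3] = volume.grid.origin_mm
    values = volume.values if dtype is None else volume.values.astype(dtype)
    nib.save(nib.Nifti1Image(values, affine), str(path))
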