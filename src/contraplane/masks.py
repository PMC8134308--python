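"""Artificial segmentation targets: the sphere landmark and the cylinder cross.

The localization stage is trained on a binary mask of a 5 mm-radius sphere
centered on the tibia-plateau landmark.  The plane-estimation stage is
trained on a 4-class label volume in which each standard plane is a thin
cylinder (disc of radius ``radius_mm``, thickness ``height_mm``) around the
intersection point; voxels where two or more cylinders overlap are demoted
to background so class labels never overlap.

Membership tests are evaluated in world mm on voxel centers with inclusive
(≤) boundaries, which makes the masks deterministic and exactly
reproducible by brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScalarVolume, StandardPlaneFrame, VolumeGrid, write_nifti

__all__ = [
    "SphereMaskSpec",
    "CylinderMaskSpec",
    "PlaneLabelVolume",
    "make_sphere_mask",
    "make_plane_cylinder_masks",
    "LABEL_NAMES",
]

#: label integers of the plane classes (0 is background)
LABEL_NAMES = {1: "sagittal", 2: "axial", 3: "coronal"}


@dataclass(frozen=True)
class SphereMaskSpec:
    """Sphere landmark: 5 mm radius around the plateau center by default."""

    center_mm: tuple[float, float, float]
    radius_mm: float = 5.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass(frozen=True)
class CylinderMaskSpec:
    """Three-cylinder plane mask around a frame's intersection point.

    Typical radii are 20/25/30 mm with heights 2/3 mm; the default 25 mm /
    2 mm is the configuration of the main accuracy experiment.
    """

    frame: StandardPlaneFrame
    radius_mm: float = 25.0
    height_mm: float = 2.0

    def __post_init__(self):
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise ValueError("radius_mm and height_mm must be positive")
        if self.radius_mm <= self.height_mm / 2:
            raise ValueError("radius_mm must exceed height_mm/2 (disc, not rod)")


@dataclass
class PlaneLabelVolume:
    """4-class label lattice: 0 background, 1 sagittal, 2 axial, 3 coronal."""

    grid: VolumeGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if tuple(self.labels.shape) != tuple(self.grid.shape):
            raise ValueError("labels shape does not match grid shape")
        if self.labels.dtype != np.uint8:
            if np.any((self.labels < 0) | (self.labels > 3)):
                raise ValueError("labels must be in {0,1,2,3}")
            self.labels = self.labels.astype(np.uint8)

    def class_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def to_nifti(self, path) -> None:
        write_nifti(ScalarVolume(self.grid, self.labels.astype(np.uint8)), path, dtype=np.uint8)


def make_sphere_mask(spec: SphereMaskSpec, grid: VolumeGrid) -> np.ndarray:
    """Binary mask: voxel v is 1 iff ``‖world(v) − center‖ ≤ radius``.

    Centers outside the grid simply yield the clipped (possibly empty)
    intersection.
    """
    center = np.asarray(spec.center_mm, dtype=float)
    # separable squared distance keeps memory at O(sum of axes)
    d2 = np.zeros(grid.shape, dtype=float)
    for a in range(3):
        coords = grid.origin_mm[a] + np.arange(grid.shape[a]) * grid.spacing_mm[a]
        da = (coords - center[a]) ** 2
        shape = [1, 1, 1]
        shape[a] = grid.shape[a]
        d2 = d2 + da.reshape(shape)
    return (d2 <= spec.radius_mm**2).astype(np.uint8)


def make_plane_cylinder_masks(spec: CylinderMaskSpec, grid: VolumeGrid) -> PlaneLabelVolume:
    """Voxelize the three plane cylinders and omit their intersections.

    Voxel v belongs to cylinder k with unit normal n_k through point p iff

        |(world(v) − p)·n_k| ≤ height/2   and
        ‖(world(v) − p) − ((world(v) − p)·n_k) n_k‖ ≤ radius.

    Voxels inside exactly one cylinder receive that class label (1 sagittal,
    2 axial, 3 coronal); voxels inside two or more cylinders are omitted
    (label 0) so the classes never overlap.
    """
    frame = spec.frame
    p = frame.intersection_mm
    coords = grid.world_coordinates()  # (X,Y,Z,3)
    d = coords - p
    d2 = np.einsum("...i,...i->...", d, d)
    half_h = spec.height_mm / 2.0
    r2 = spec.radius_mm**2

    member = []
    for n in (frame.n_sag, frame.n_ax, frame.n_cor):
        proj = d @ n
        radial2 = d2 - proj**2
        # clamp tiny negative values from cancellation
        radial2 = np.maximum(radial2, 0.0)
        member.append((np.abs(proj) <= half_h) & (radial2 <= r2))

    count = member[0].astype(np.uint8) + member[1] + member[2]
    labels = np.zeros(grid.shape, dtype=np.uint8)
    for k, m in enumerate(member, start=1):
        labels[m & (count == 1)] = k
    return PlaneLabelVolume(grid, labels)
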