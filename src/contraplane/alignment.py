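"""Stage 3 — laterality handling, frame mirroring and comparison slices.

Left and right ankles are mirror images, so their standard-plane frames
form one left- and one right-handed coordinate system.  Sampling each
ankle's multiplanar-reconstruction slice in its *own* (handed) basis bakes
the mirroring in: the in-plane axes of the left-handed frame are a
reflected pair, so the two slices come out in the same display laterality
and can be compared pixel by pixel.  Comparison slices are offered at the
three clinical levels along the axial normal: talar dome (−6 mm), tibial
plafond (0 mm) and incisura (+10 mm), plus a single signed axial offset
correction applied to both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import LateralityError
from .geometry import ScalarVolume, StandardPlaneFrame, world_to_voxel

__all__ = [
    "ComparisonView",
    "LEVEL_OFFSETS_MM",
    "mirror_frame",
    "resample_slice",
    "build_comparison",
    "classify_laterality",
    "orient_frame_to_anatomy",
]

#: clinical viewing levels, measured along the axial normal from the intersection
LEVEL_OFFSETS_MM = {"lower": -6.0, "plateau": 0.0, "upper": 10.0}

#: in-plane axes (row direction, column direction) per slice plane
_INPLANE_AXES = {
    "axial": ("n_sag", "n_cor"),
    "sagittal": ("n_ax", "n_cor"),
    "coronal": ("n_sag", "n_ax"),
}
_PLANE_NORMALS = {"axial": "n_ax", "sagittal": "n_sag", "coronal": "n_cor"}


@dataclass
class ComparisonView:
    """Side-by-side slice pair with shared in-plane geometry."""

    left_slice: np.ndarray
    right_slice: np.ndarray
    level: str
    plane: str
    pixel_mm: float
    extent_mm: float
    axial_offset_correction_mm: float = 0.0


def mirror_frame(frame: StandardPlaneFrame, axis, plane_coord_mm: float = 0.0) -> StandardPlaneFrame:
    """Reflect a frame through the world plane ``{axis = plane_coord_mm}``.

    The intersection point is reflected, the corresponding normal components
    are negated, and the handedness flips.  Mirroring twice about the same
    plane is the identity.
    """
    axis = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    p = frame.intersection_mm.copy()
    p[axis] = 2.0 * plane_coord_mm - p[axis]
    m = frame.matrix.copy()
    m[axis, :] = -m[axis, :]
    return StandardPlaneFrame(p, m[:, 0], m[:, 1], m[:, 2])


def resample_slice(
    volume: ScalarVolume,
    frame: StandardPlaneFrame,
    plane: str = "axial",
    offset_mm: float = 0.0,
    extent_mm: float = 60.0,
    pixel_mm: float = 0.5,
) -> np.ndarray:
    """Trilinear MPR slice through ``intersection + offset · n_plane``.

    The slice is spanned by the frame's other two normals (fixed axis order
    and signs, see ``_INPLANE_AXES``), centered on the offset point, with
    out-of-volume samples set to zero.
    """
    if pixel_mm <= 0 or extent_mm <= 0:
        raise ValueError("pixel_mm and extent_mm must be positive")
    n_pix = int(round(extent_mm / pixel_mm))
    normal = getattr(frame, _PLANE_NORMALS[plane])
    u = getattr(frame, _INPLANE_AXES[plane][0])
    v = getattr(frame, _INPLANE_AXES[plane][1])
    center = frame.intersection_mm + offset_mm * normal
    ticks = (np.arange(n_pix) - (n_pix - 1) / 2.0) * pixel_mm
    pu, pv = np.meshgrid(ticks, ticks, indexing="ij")
    points = center + pu[..., None] * u + pv[..., None] * v
    idx = world_to_voxel(points, volume.grid)
    return ndimage.map_coordinates(
        volume.values.astype(np.float64), np.moveaxis(idx, -1, 0), order=1, mode="constant", cval=0.0
    )


def classify_laterality(frame: StandardPlaneFrame, volume: ScalarVolume | None = None) -> str:
    """Anatomical side of a frame: the handedness of its normal matrix.

    Under the package's sign conventions a right ankle assembles a
    right-handed frame and a left ankle a left-handed one.  If ``volume``
    is given, the frame signs are first re-anchored to the image content
    via :func:`orient_frame_to_anatomy`, so a frame whose signs came from
    an arbitrary reference is still classified correctly.
    """
    if volume is not None:
        frame = orient_frame_to_anatomy(frame, volume)
    return frame.handedness


def orient_frame_to_anatomy(
    frame: StandardPlaneFrame, volume: ScalarVolume, radius_mm: float = 45.0
) -> StandardPlaneFrame:
    """Fix the sign of each normal from first intensity moments of the image.

    Cylinder masks are symmetric under normal flips, so segmentation alone
    cannot orient the frame; the image can.  Each normal is flipped so the
    intensity moment ``Σ I(v) · ((world(v) − p) · n)`` over an
    anatomy-specific window is non-negative:

    * axial — sphere of ``radius_mm``: the tibial shaft puts most mass on
      the proximal (+axial) side;
    * sagittal — slab within 12 mm of the plateau, radius 25 mm: the medial
      malleolus sits on the +sagittal side while tibia, fibula and talus are
      laterally symmetric there;
    * coronal — slab within 18 mm of the plateau, radius 35 mm: the fibula
      lies on the +coronal side.

    The slabs keep the symmetric structures inside the placement margin, so
    partial volume-boundary clipping cannot flip a sign.
    """
    grid = volume.grid
    d = grid.world_coordinates() - frame.intersection_mm
    d2 = np.einsum("...i,...i->...", d, d)
    intensity = np.clip(volume.values, 0.0, None)
    proj_ax = d @ frame.n_ax

    windows = {
        "n_ax": d2 <= radius_mm**2,
        "n_sag": (np.abs(proj_ax) <= 12.0) & (d2 - proj_ax**2 <= 25.0**2),
        "n_cor": (np.abs(proj_ax) <= 18.0) & (d2 - proj_ax**2 <= 35.0**2),
    }
    cols = []
    for name in ("n_sag", "n_ax", "n_cor"):
        n = getattr(frame, name)
        sel = windows[name]
        moment = float(np.sum(intensity[sel] * (d[sel] @ n)))
        cols.append(-n if moment < 0 else n)
    return StandardPlaneFrame(frame.intersection_mm, cols[0], cols[1], cols[2])


def build_comparison(
    volume: ScalarVolume,
    frames: tuple[StandardPlaneFrame, StandardPlaneFrame],
    level: str = "plateau",
    correction_mm: float = 0.0,
    plane: str = "axial",
    extent_mm: float = 60.0,
    pixel_mm: float = 0.5,
) -> ComparisonView:
    """Side-by-side comparison slices of a bilateral volume.

    Requires exactly one left- and one right-handed frame.  Each ankle is
    sliced in its own frame basis at the level's offset (−6 / 0 / +10 mm)
    plus ``correction_mm`` along its own axial normal; the handed bases
    realize the mirroring to a common display laterality, so a healthy
    mirror-symmetric pair produces near-identical slices.
    """
    if level not in LEVEL_OFFSETS_MM:
        raise ValueError(f"level must be one of {sorted(LEVEL_OFFSETS_MM)}")
    if len(frames) != 2:
        raise LateralityError("build_comparison needs exactly two frames")
    sides = [classify_laterality(f) for f in frames]
    if sorted(sides) != ["left", "right"]:
        raise LateralityError(f"need one left and one right frame, got {sides}")
    by_side = {side: f for side, f in zip(sides, frames)}
    offset = LEVEL_OFFSETS_MM[level] + correction_mm
    slices = {
        side: resample_slice(volume, by_side[side], plane, offset, extent_mm, pixel_mm)
        for side in ("left", "right")
    }
    return ComparisonView(slices["left"], slices["right"], level, plane, pixel_mm, extent_mm, correction_mm)
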