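"""Subchondral bone-plate (SBP) shell extraction.

The bone plate of a vertebral endplate is isolated algorithmically as
"first bone voxel per (x, y) column from the chosen end, plus a fixed
depth into the bone".  With z index 0 at the cranial end, the superior
shell spans ``[surface_height, surface_height + depth_vox)`` (moving
caudally into the bone) and the inferior shell spans
``(surface_height - depth_vox, surface_height]`` (moving cranially).
Shell membership is additionally intersected with the mask, so the shell
never exits the bone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import EmptyMaskError, ParameterError
from .volume_io import CTVolume, LabelMask

#: surface_height value for columns outside the footprint
NO_BONE = -1


@dataclass
class SBPShell:
    """Depth-limited subchondral shell for one endplate.

    ``surface_height[x, y]`` is the z index of the first bone voxel seen
    from the cranial (superior) or caudal (inferior) end; ``NO_BONE``
    outside the footprint.
    """

    surface_height: np.ndarray
    depth_vox: int
    side: str
    footprint: np.ndarray
    mask_voxels: np.ndarray  # same-grid mask, used to clip the shell

    def __post_init__(self) -> None:
        if self.side not in ("superior", "inferior"):
            raise ParameterError(f"side must be superior|inferior, got {self.side!r}")
        if self.depth_vox < 1:
            raise ParameterError("depth_vox must be >= 1")

    def member(self) -> np.ndarray:
        """Boolean 3D array of shell membership (always a subset of the mask)."""
        nz = self.mask_voxels.shape[2]
        z = np.arange(nz)[None, None, :]
        h = self.surface_height[:, :, None]
        if self.side == "superior":
            in_range = (z >= h) & (z < h + self.depth_vox)
        else:
            in_range = (z <= h) & (z > h - self.depth_vox)
        return in_range & (self.footprint[:, :, None] == 1) & (self.mask_voxels == 1)


def orient_perpendicular(
    vol: CTVolume,
    mask: LabelMask,
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    center_mm: tuple[float, float, float] | None = None,
) -> tuple[CTVolume, LabelMask]:
    """Rotate and resample so the endplate is viewed en face.

    The volume is resampled with trilinear interpolation onto an
    isotropic grid at the finest input spacing; the mask with nearest
    neighbour.  Euler angles are extrinsic x-y-z in degrees, applied
    about the mask centroid (or ``center_mm`` if given).  The output
    grid tightly crops the rotated mask with a 2-voxel margin.
    """
    if vol.shape != mask.shape:
        raise ParameterError(f"volume {vol.shape} and mask {mask.shape} shapes differ")
    mask.require_nonempty()
    rotation_deg = tuple(float(a) for a in rotation_deg)
    if not all(np.isfinite(rotation_deg)):
        raise ParameterError("rotation angles must be finite")

    sp = np.asarray(vol.spacing)
    s = float(sp.min())  # target isotropic spacing
    rot = Rotation.from_euler("xyz", rotation_deg, degrees=True)
    R = rot.as_matrix()

    idx = np.argwhere(mask.voxels == 1).astype(float)
    phys = idx * sp  # physical coords of mask voxel centers
    center = phys.mean(axis=0) if center_mm is None else np.asarray(center_mm, float)
    rotated = (phys - center) @ R.T + center

    lo = np.floor(rotated.min(axis=0) / s).astype(int) - 2
    hi = np.ceil(rotated.max(axis=0) / s).astype(int) + 2
    out_shape = tuple(int(n) for n in (hi - lo + 1))
    origin = lo * s  # physical coordinate of output voxel (0,0,0)

    # map output index -> input index:  p_in = R^-1 (i*s + origin - c) + c, / spacing
    # affine_transform computes input_index = M @ output_index + off
    M = (R.T * s) / sp[:, None]
    off = (R.T @ (origin - center) + center) / sp

    out_vox = ndimage.affine_transform(
        vol.voxels.astype(float), M, offset=off, output_shape=out_shape,
        order=1, mode="constant", cval=float(vol.voxels.min()),
    )
    out_mask = ndimage.affine_transform(
        mask.voxels, M, offset=off, output_shape=out_shape,
        order=0, mode="constant", cval=0,
    )
    if not out_mask.any():
        raise EmptyMaskError("rotation moved all mask voxels outside the sampled field")
    out_vol = CTVolume(voxels=out_vox, spacing=(s, s, s))
    return out_vol, LabelMask(voxels=out_mask, label=mask.label)


def extract_surface(mask: LabelMask, side: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-column height of the first bone voxel from the chosen end.

    Returns ``(surface_height, footprint)``; columns with no bone carry
    ``NO_BONE`` and footprint 0.
    """
    if side not in ("superior", "inferior"):
        raise ParameterError(f"side must be superior|inferior, got {side!r}")
    mask.require_nonempty()
    m = mask.voxels.astype(bool)
    footprint = m.any(axis=2).astype(np.uint8)
    nz = m.shape[2]
    if side == "superior":  # scan from cranial end (z=0) downward
        height = np.argmax(m, axis=2)
    else:  # scan from caudal end (z=nz-1) upward
        height = nz - 1 - np.argmax(m[:, :, ::-1], axis=2)
    height = np.where(footprint == 1, height, NO_BONE)
    return height.astype(int), footprint


def extract_shell(
    mask: LabelMask,
    side: str,
    depth_mm: float,
    spacing: tuple[float, float, float],
) -> SBPShell:
    """Build the SBP shell: surface voxels plus ``depth_mm`` into the bone.

    ``depth_vox = max(1, round(depth_mm / dz))``.  Columns thinner than
    the depth are clipped at the opposite mask surface (membership is
    intersected with the mask).
    """
    if depth_mm <= 0:
        raise ParameterError(f"depth_mm must be > 0, got {depth_mm}")
    dz = float(spacing[2])
    depth_vox = max(1, round(depth_mm / dz))
    height, footprint = extract_surface(mask, side)
    return SBPShell(
        surface_height=height,
        depth_vox=depth_vox,
        side=side,
        footprint=footprint,
        mask_voxels=mask.voxels.copy(),
    )


__all__ = ["NO_BONE", "SBPShell", "orient_perpendicular", "extract_surface", "extract_shell"]
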