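"""Maximum-intensity projection through the SBP shell.

The MIP runs along the craniocaudal axis but only over shell voxels, not
the whole column: projecting the full column would leak trabecular or
cortical-wall signal into the endplate map.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .volume_io import CTVolume, Densitogram, PlateMeta


def project_mip(vol: CTVolume, shell, meta: PlateMeta | None = None) -> Densitogram:
    """Densitogram: per-column maximum HU over the shell voxels.

    Background (non-footprint) pixels carry NaN with valid=0.  The
    densitogram axes are (row=anteroposterior, col=mediolateral), i.e. the
    transpose of the volume's (x, y) in-plane order.
    """
    if vol.shape != shell.mask_voxels.shape:
        raise ParameterError(
            f"volume grid {vol.shape} does not match shell grid {shell.mask_voxels.shape}"
        )
    member = shell.member()
    vals = np.where(member, vol.voxels, -np.inf).max(axis=2)  # (x, y)
    valid = member.any(axis=2)
    values = np.where(valid, vals, np.nan)
    if meta is None:
        meta = PlateMeta(side=shell.side)
    dx, dy = float(vol.spacing[0]), float(vol.spacing[1])
    # transpose to (row=y, col=x)
    return Densitogram(
        values=values.T, valid=valid.T.astype(np.uint8), pixel_spacing=(dx, dy), meta=meta
    )


__all__ = ["project_mip"]
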