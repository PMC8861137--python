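"""On-disk contracts and core domain containers.

Conventions fixed here and used by every downstream stage:

* Volume axes are ``(x, y, z)`` = (mediolateral, anteroposterior,
  craniocaudal), with z index 0 at the cranial end.  All projections run
  along z.
* Densitogram arrays are ``(row, col)`` with rows along the
  anteroposterior axis (row 0 = anterior/ventral edge) and columns along
  the mediolateral axis (col 0 = subject-left).  Indices are 0-based.
* HU are stored losslessly; densitogram rasters are written as 16-bit
  TIFF with a fixed +1024 offset so negative HU survive the unsigned
  encoding, plus a JSON sidecar for spacing and metadata.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
import tifffile

from .errors import EmptyMaskError, FormatError, ParameterError, RangeError

HU_MIN = -1024
HU_MAX = 4095
#: Offset added to HU before 16-bit unsigned encoding of densitograms.
HU_OFFSET = 1024

SIDES = ("superior", "inferior")
CONDITIONS = ("healthy", "ddd")


@dataclass(frozen=True)
class PlateMeta:
    """Identity of one endplate measurement."""

    subject: str = ""
    level: str = ""
    side: str = "superior"
    condition: str = "healthy"

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ParameterError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.condition not in CONDITIONS:
            raise ParameterError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "level": self.level,
            "side": self.side,
            "condition": self.condition,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateMeta":
        return cls(**{k: d[k] for k in ("subject", "level", "side", "condition")})


@dataclass
class CTVolume:
    """3D Hounsfield-unit scalar field with voxel spacing in mm.

    ``voxels`` is indexed ``[x, y, z]``.  Values are integer-valued at
    acquisition but may become fractional after resampling.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ParameterError("volume must be 3D with at least 1 voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive floats, got {self.spacing}")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise RangeError(f"HU out of [{HU_MIN}, {HU_MAX}]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelMask:
    """Binary vertebra mask on the same grid as its CTVolume."""

    voxels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(np.uint8)
        if self.voxels.ndim != 3:
            raise ParameterError("mask must be 3D")
        if not np.isin(self.voxels, (0, 1)).all():
            raise ParameterError("mask voxels must be 0/1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def require_nonempty(self) -> None:
        if not self.voxels.any():
            raise EmptyMaskError(f"mask {self.label!r} has no voxels")


@dataclass
class Densitogram:
    """2D HU map of an endplate surface (the MIP output).

    ``values`` must be finite wherever ``valid`` is 1; invalid pixels are
    background (a sentinel, never HU 0 — 0 HU is legitimate tissue).
    """

    values: np.ndarray
    valid: np.ndarray
    pixel_spacing: tuple[float, float]
    meta: PlateMeta = field(default_factory=PlateMeta)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid).astype(np.uint8)
        if self.values.ndim != 2 or self.values.shape != self.valid.shape:
            raise ParameterError("values and valid must be equal-shape 2D arrays")
        if not self.valid.any():
            raise EmptyMaskError("densitogram has no valid pixels")
        if not np.isfinite(self.values[self.valid == 1]).all():
            raise ParameterError("values must be finite where valid=1")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if len(self.pixel_spacing) != 2 or any(s <= 0 for s in self.pixel_spacing):
            raise ParameterError("pixel_spacing must be 2 positive floats")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class MaximaRecord:
    """One local mineralization maximum on the 40x50 raster grid."""

    row: int
    col: int
    hu: float

    def __post_init__(self) -> None:
        if not (0 <= self.row < 40 and 0 <= self.col < 50):
            raise ParameterError(f"grid index out of range: ({self.row}, {self.col})")
        if not np.isfinite(self.hu):
            raise ParameterError("hu must be finite")


# ---------------------------------------------------------------------------
# Volumes


def _to_sitk(voxels: np.ndarray, spacing: Sequence[float]) -> sitk.Image:
    # our [x, y, z] -> SimpleITK array layout [z, y, x]
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(voxels, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume (NIfTI or NRRD) into the package axis convention.

    Spacing is taken from file metadata and preserved; HU are never
    rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"not a readable volume: {path} ({exc})") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3D volume, got {img.GetDimension()}D: {path}")
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise FormatError(f"missing or invalid voxel spacing in {path}: {spacing}")
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    voxels = np.transpose(arr, (2, 1, 0))
    return CTVolume(voxels=voxels, spacing=(spacing[0], spacing[1], spacing[2]))


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a CTVolume to NIfTI/NRRD (format from the file extension)."""
    sitk.WriteImage(_to_sitk(vol.voxels, vol.spacing), str(Path(path)))


def read_mask(path: str | Path, label: str = "") -> LabelMask:
    """Read a binary mask volume; any nonzero voxel counts as inside."""
    vol = read_volume(path)
    return LabelMask(voxels=(np.asarray(vol.voxels) != 0).astype(np.uint8), label=label)


def write_mask(mask: LabelMask, spacing: Sequence[float], path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(mask.voxels.astype(np.uint8), spacing), str(Path(path)))


# ---------------------------------------------------------------------------
# Densitograms: 16-bit TIFF (values+1024, background 0) + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_densitogram(d: Densitogram, path: str | Path) -> None:
    """Write a densitogram as 2-page 16-bit TIFF plus a JSON sidecar.

    Page 1 holds ``values + HU_OFFSET`` (background pixels encode 0),
    page 2 the validity mask.  Integer HU round-trip bit-exactly.
    """
    path = Path(path)
    vals = np.where(d.valid == 1, d.values, float(-HU_OFFSET))
    shifted = vals + HU_OFFSET
    if shifted.min() < 0 or shifted.max() > np.iinfo(np.uint16).max:
        raise RangeError(
            f"HU outside representable range after +{HU_OFFSET} offset: "
            f"[{vals.min()}, {vals.max()}]"
        )
    if not np.allclose(shifted, np.round(shifted)):
        raise RangeError("densitogram HU must be integer-valued for lossless storage")
    pages = np.stack(
        [np.round(shifted).astype(np.uint16), d.valid.astype(np.uint16)]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "pixel_spacing": list(d.pixel_spacing),
        "hu_offset": HU_OFFSET,
        "meta": d.meta.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_densitogram(path: str | Path) -> Densitogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing sidecar metadata file: {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise FormatError(f"expected a 2-page densitogram TIFF: {path}")
    offset = int(sidecar["hu_offset"])
    valid = pages[1].astype(np.uint8)
    values = pages[0].astype(float) - offset
    values[valid == 0] = np.nan
    return Densitogram(
        values=values,
        valid=valid,
        pixel_spacing=tuple(sidecar["pixel_spacing"]),
        meta=PlateMeta.from_dict(sidecar["meta"]),
    )


# ---------------------------------------------------------------------------
# Maxima tables


def write_maxima_table(records: Sequence[MaximaRecord], path: str | Path) -> None:
    """Write maxima as CSV with header ``row,col,hu`` in row-major order."""
    ordered = sorted(records, key=lambda r: (r.row, r.col))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "hu"])
        for rec in ordered:
            hu = rec.hu
            writer.writerow([rec.row, rec.col, int(hu) if hu == int(hu) else hu])


def read_maxima_table(path: str | Path) -> list[MaximaRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            MaximaRecord(row=int(r["row"]), col=int(r["col"]), hu=float(r["hu"]))
            for r in reader
        ]


__all__ = [
    "HU_MIN",
    "HU_MAX",
    "HU_OFFSET",
    "PlateMeta",
    "CTVolume",
    "LabelMask",
    "Densitogram",
    "MaximaRecord",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_densitogram",
    "write_densitogram",
    "read_maxima_table",
    "write_maxima_table",
    "replace",
]
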