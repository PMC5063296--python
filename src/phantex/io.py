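"""NIfTI-1 reading and writing for images, activity maps and masks.

Volumes are written RAS+ with the voxel spacing on the affine diagonal;
values round-trip bit-identically (float64 for images, uint8 for masks).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .phantoms import ActivityMap, ImageVolume
from .segmentation import VOIMask

__all__ = ["FormatError", "read_volume", "write_volume", "write_mask", "read_mask"]


class FormatError(ValueError):
    pass


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: ImageVolume | ActivityMap, path: str | Path) -> None:
    """Write an image or activity map as float64 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    descrip = getattr(volume, "provenance", None)
    if descrip:
        seed = descrip.get("seed")
        setting = descrip.get("setting")
        img.header["descrip"] = f"setting={setting} seed={seed}".encode()[:79]
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI-1 volume; values and mm spacing are preserved."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError("missing or non-positive voxel spacing")
    return ImageVolume(
        values=data.astype(np.float64),
        spacing=tuple(float(z) for z in zooms),
        provenance={"source": str(path)},
    )


def write_mask(mask: VOIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> VOIMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D mask, got {data.ndim}D")
    return VOIMask(data > 0, tuple(float(z) for z in img.header.get_zooms()[:3]))
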