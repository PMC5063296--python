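"""VOI definition: threshold isocontours and concentric spherical VOIs.

Two segmentation modes mirror the study protocols: an absolute SUV cut
(patient-style, e.g. SUV > 2.5 g/cm3) and a relative cut against the
background mean (phantom-style, value > 2.5 x background), both strict
inequalities, optionally restricted to a bounding box, keeping the largest
26-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationError",
    "VOIMask",
    "threshold_segment",
    "spherical_voi",
    "voi_volume",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    pass


@dataclass
class VOIMask:
    """Boolean VOI aligned voxel-for-voxel with its source image."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def volume_ml(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.spacing)) / 1000.0


def voi_volume(mask: VOIMask) -> float:
    """Volume in ml: voxel count times voxel volume."""
    return mask.volume_ml


def _auto_background(values: np.ndarray, spacing, box) -> np.ndarray:
    """Default background region: a ~1 cm shell starting ~2 cm outside the
    bounding box of the bright object, restricted to non-empty voxels."""
    hot = values > 0.5 * values.max()
    if not hot.any():
        raise SegmentationError("cannot auto-estimate background: image is empty")
    objs = ndimage.find_objects(hot.astype(np.int8))[0]
    inner = np.zeros(values.shape, dtype=bool)
    outer = np.zeros(values.shape, dtype=bool)

    def _grow(sl, margin_mm):
        out = []
        for s, n, sp in zip(sl, values.shape, spacing):
            m = int(round(margin_mm / sp))
            out.append(slice(max(0, s.start - m), min(n, s.stop + m)))
        return tuple(out)

    inner[_grow(objs, 20.0)] = True
    outer[_grow(objs, 30.0)] = True
    shell = outer & ~inner & (values > 0.05 * values.max())
    if not shell.any():
        raise SegmentationError("auto background shell is empty")
    return shell


def threshold_segment(
    image,
    mode: str = "relative",
    threshold: float = 2.5,
    background_roi: np.ndarray | None = None,
    bounding_box: tuple[slice, ...] | None = None,
    keep_largest: bool = True,
) -> VOIMask:
    """Isocontour segmentation.

    mode="absolute": keep voxels with value > threshold (image units).
    mode="relative": keep voxels with value > threshold * background mean,
    the background mean taken over ``background_roi`` if given, else over an
    automatically placed shell outside the bright object.
    """
    values = np.asarray(getattr(image, "values", image), dtype=float)
    spacing = getattr(image, "spacing", (1.0, 1.0, 1.0))

    if mode == "absolute":
        cut = float(threshold)
    elif mode == "relative":
        if background_roi is not None:
            bg = np.asarray(background_roi, dtype=bool)
            if bg.shape != values.shape:
                raise SegmentationError("background ROI shape mismatch")
        else:
            bg = _auto_background(values, spacing, bounding_box)
        bg_mean = float(values[bg].mean())
        if bg_mean <= 0:
            raise SegmentationError("background mean must be positive")
        cut = float(threshold) * bg_mean
    else:
        raise ValueError("mode must be 'absolute' or 'relative'")

    mask = values > cut
    if bounding_box is not None:
        box = np.zeros(values.shape, dtype=bool)
        box[tuple(bounding_box)] = True
        mask &= box
    if not mask.any():
        raise SegmentationError("no voxels above threshold")
    if keep_largest:
        lab, n = ndimage.label(mask, structure=_STRUCT_26)
        if n > 1:
            sizes = np.bincount(lab.ravel())[1:]
            mask = lab == (int(sizes.argmax()) + 1)
    return VOIMask(mask, tuple(spacing))


def sphere_radius_mm(volume_ml: float) -> float:
    """Radius of a sphere of the requested volume: (3V / 4 pi)^(1/3)."""
    return float((3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def spherical_voi(
    image,
    center_mm: tuple[float, float, float],
    volume_ml: float,
    within: np.ndarray | None = None,
) -> VOIMask:
    """Spherical VOI of the requested volume centred at ``center_mm``.

    Coordinates are mm relative to the grid centre.  If ``within`` is given
    (e.g. the phantom interior), any sphere voxel falling outside it raises,
    preventing background contamination of homogeneity curves.
    """
    if volume_ml <= 0:
        raise ValueError("volume must be > 0")
    values = np.asarray(getattr(image, "values", image), dtype=float)
    spacing = tuple(getattr(image, "spacing", (1.0, 1.0, 1.0)))
    r = sphere_radius_mm(volume_ml)

    coords = []
    for n, sp, c in zip(values.shape, spacing, center_mm):
        ax = (np.arange(n) - (n - 1) / 2.0) * sp - c
        lo, hi = ax[0] - sp / 2.0, ax[-1] + sp / 2.0
        if -r < lo or r > hi:
            raise SegmentationError("sphere exceeds the image grid")
        coords.append(ax)
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    mask = x**2 + y**2 + z**2 <= r**2
    if not mask.any():
        raise SegmentationError("sphere too small for this voxel grid")
    if within is not None and (mask & ~np.asarray(within, dtype=bool)).any():
        raise SegmentationError("sphere exceeds the phantom boundary")
    return VOIMask(mask, spacing)
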