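"""Grey-level discretisation of VOI intensities.

Texture matrices require a small finite alphabet of intensity values.  The
VOI voxels are linearly rescaled onto ``n_levels`` integer grey levels
(fixed-bin-number resampling, default 64 levels):

    V(x) = floor( n_levels * (I(x) - min I) / (max I - min I) + 1 )

with the single voxel at the maximum clipped back to ``n_levels`` so the
alphabet has exactly ``n_levels`` symbols.  A constant region maps every
voxel to level 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GreyLevelImage", "resample_grey_levels"]


@dataclass(frozen=True)
class GreyLevelImage:
    """Integer grey-level grid over a VOI.

    ``levels`` holds values in ``{1, ..., n_levels}`` inside the mask and the
    sentinel 0 outside; out-of-mask voxels never contribute to any texture
    matrix.  The original intensity range is kept for provenance.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    vmin: float
    vmax: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def resample_grey_levels(
    values: np.ndarray, mask: np.ndarray, n_levels: int = 64
) -> GreyLevelImage:
    """Discretise in-mask intensities to ``n_levels`` grey levels.

    Parameters
    ----------
    values : ndarray
        3D intensity grid (any real-valued units).
    mask : ndarray of bool
        VOI mask, same shape as ``values``.
    n_levels : int
        Number of grey levels (2**S for bit depth S; default 64).

    Returns
    -------
    GreyLevelImage
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not mask.any():
        raise ValueError("empty mask: no voxels to resample")

    inside = values[mask]
    vmin = float(inside.min())
    vmax = float(inside.max())

    levels = np.zeros(values.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask] = 1
    else:
        v = np.floor(n_levels * (inside - vmin) / (vmax - vmin) + 1.0)
        levels[mask] = np.clip(v, 1, n_levels).astype(np.int32)
    return GreyLevelImage(levels=levels, mask=mask, n_levels=n_levels, vmin=vmin, vmax=vmax)
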