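"""The 27 heterogeneity parameters.

Four co-occurrence indices (HOM, COR, ENT, CON), grey-level non-uniformity
of zones reported as Intensity Variability (IV), 10 run-length and 11
size-zone statistics, and the first-order Coefficient of Variation computed
on the raw (non-resampled) VOI intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .matrices import (
    CooccurrenceMatrix,
    RunLengthMatrix,
    SizeZoneMatrix,
    compute_cooccurrence,
    compute_runlength,
    compute_sizezone,
)
from .resample import resample_grey_levels

__all__ = [
    "PARAMETERS",
    "MATRIX_PARAMETERS",
    "FeatureVector",
    "cooccurrence_features",
    "intensity_variability",
    "runlength_features",
    "sizezone_features",
    "coefficient_of_variation",
    "compute_all_features",
]

#: canonical order of the 27 heterogeneity parameters
PARAMETERS: tuple[str, ...] = (
    "HOM", "COR", "ENT", "CON", "IV",
    "ZP", "SZV", "SZE", "LZE", "GLNU_Z", "LGLZE", "HGLZE",
    "SZLGLE", "SZHGLE", "LZLGLE", "LZHGLE",
    "RP", "SRE", "LRE", "GLNU_R", "LGLRE", "HGLRE",
    "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
    "CoV",
)

#: the 26 matrix-derived parameters (everything except CoV)
MATRIX_PARAMETERS: tuple[str, ...] = PARAMETERS[:-1]


@dataclass
class FeatureVector:
    """Named values of the 27 parameters for one (image, VOI) pair."""

    values: dict[str, float]
    volume_ml: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values, name="value")


def cooccurrence_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """Homogeneity, Correlation, Entropy (bits) and Contrast of a GLCM."""
    L = m.n_levels
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p = m.p
    hom = float((p / (1.0 + np.abs(ii - jj))).sum())
    con = float((((ii - jj) ** 2) * p).sum())
    pos = p[p > 0]
    ent = float(-(pos * np.log2(pos)).sum())
    var = m.variance
    if var <= 0:
        cor = 0.0  # degenerate single-level VOI; flagged upstream
    else:
        mu = m.mean
        cor = float((((ii - mu) * (jj - mu)) * p).sum() / var)
    return {"HOM": hom, "COR": cor, "ENT": ent, "CON": con}


def intensity_variability(z: SizeZoneMatrix) -> float:
    """Grey-level non-uniformity of zones: IV = sum_i (sum_s z(i,s))^2 / N_z."""
    nz = z.n_zones
    if nz == 0:
        return 0.0
    per_grey = z.counts.sum(axis=1).astype(float)
    return float((per_grey**2).sum() / nz)


def _weighted_stats(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    i = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    return counts.astype(float), i, l


def runlength_features(r: RunLengthMatrix) -> dict[str, float]:
    """The 10 run-length statistics (normalised by the total run count)."""
    c, i, l = _weighted_stats(r.counts)
    nr = c.sum()
    if nr == 0:
        raise ValueError("run-length matrix is empty")
    per_grey = c.sum(axis=1)
    return {
        "RP": float(nr / (r.n_voxels * r.n_directions)),
        "SRE": float((c / l**2).sum() / nr),
        "LRE": float((c * l**2).sum() / nr),
        "GLNU_R": float((per_grey**2).sum() / nr),
        "LGLRE": float((c / i**2).sum() / nr),
        "HGLRE": float((c * i**2).sum() / nr),
        "SRLGLE": float((c / (i**2 * l**2)).sum() / nr),
        "SRHGLE": float((c * i**2 / l**2).sum() / nr),
        "LRLGLE": float((c * l**2 / i**2).sum() / nr),
        "LRHGLE": float((c * i**2 * l**2).sum() / nr),
    }


def sizezone_features(z: SizeZoneMatrix) -> dict[str, float]:
    """The 11 size-zone statistics (normalised by the total zone count)."""
    c, i, s = _weighted_stats(z.counts)
    nz = c.sum()
    if nz == 0:
        raise ValueError("size-zone matrix is empty")
    per_grey = c.sum(axis=0)  # per size, for SZV
    return {
        "ZP": float(nz / z.n_voxels),
        "SZV": float((per_grey**2).sum() / nz),
        "SZE": float((c / s**2).sum() / nz),
        "LZE": float((c * s**2).sum() / nz),
        "GLNU_Z": float((c.sum(axis=1) ** 2).sum() / nz),
        "LGLZE": float((c / i**2).sum() / nz),
        "HGLZE": float((c * i**2).sum() / nz),
        "SZLGLE": float((c / (i**2 * s**2)).sum() / nz),
        "SZHGLE": float((c * i**2 / s**2).sum() / nz),
        "LZLGLE": float((c * s**2 / i**2).sum() / nz),
        "LZHGLE": float((c * i**2 * s**2).sum() / nz),
    }


def coefficient_of_variation(values: np.ndarray, mask: np.ndarray) -> float:
    """Sample SD over mean of the raw in-mask intensities.

    Computed on the original values, never the resampled grey levels; uses
    the n-1 (sample) standard deviation. A single-voxel or constant VOI
    returns 0.
    """
    inside = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
    if inside.size == 0:
        raise ValueError("empty mask")
    mean = float(inside.mean())
    if mean <= 0:
        raise ValueError("in-mask mean must be positive for CoV")
    if inside.size < 2:
        return 0.0
    return float(inside.std(ddof=1) / mean)


def compute_all_features(image, mask, n_levels: int = 64) -> FeatureVector:
    """Resample, build the three matrices and evaluate all 27 parameters.

    Parameters
    ----------
    image : ImageVolume or ndarray
        Reconstructed image (an object with ``.values`` and ``.spacing`` or a
        bare 3D array, in which case unit spacing is assumed).
    mask : VOIMask or ndarray of bool
    n_levels : int
        Grey levels for the matrix features (default 64).
    """
    values = getattr(image, "values", image)
    spacing = getattr(image, "spacing", (1.0, 1.0, 1.0))
    m = getattr(mask, "mask", mask)
    m = np.asarray(m, dtype=bool)

    grey = resample_grey_levels(values, m, n_levels)
    glcm = compute_cooccurrence(grey)
    rlm = compute_runlength(grey)
    szm = compute_sizezone(grey)

    out: dict[str, float] = {}
    out.update(cooccurrence_features(glcm))
    out["IV"] = intensity_variability(szm)
    out.update(sizezone_features(szm))
    out.update(runlength_features(rlm))
    out["CoV"] = coefficient_of_variation(values, m)
    out = {name: out[name] for name in PARAMETERS}

    voxel_ml = float(np.prod(spacing)) / 1000.0
    prov = {
        "n_levels": n_levels,
        "vmin": grey.vmin,
        "vmax": grey.vmax,
        "degenerate": grey.vmin == grey.vmax,
        "n_voxels": int(m.sum()),
    }
    prov.update(getattr(image, "provenance", {}) or {})
    return FeatureVector(values=out, volume_ml=int(m.sum()) * voxel_ml, provenance=prov)
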