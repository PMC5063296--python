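"""Naive reference implementations of the texture matrices and features.

Everything here is written for clarity, not speed: explicit voxel loops,
neighbour enumeration and flood fill.  Used only to cross-check the
vectorised implementations on tiny grids.
"""

from __future__ import annotations

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

DIRS_13 = []
for d in ALL_26:
    if tuple(-c for c in d) not in DIRS_13:
        DIRS_13.append(d)


def _in(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_oracle(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Direction-averaged symmetric co-occurrence matrix by full enumeration."""
    shape = levels.shape
    mats = []
    for d in DIRS_13:
        m = np.zeros((n_levels, n_levels))
        for p in np.ndindex(shape):
            if levels[p] == 0:
                continue
            q = tuple(c + o for c, o in zip(p, d))
            if not _in(shape, q) or levels[q] == 0:
                continue
            i, j = levels[p] - 1, levels[q] - 1
            m[i, j] += 1
            m[j, i] += 1
        if m.sum():
            mats.append(m / m.sum())
    return np.mean(mats, axis=0)


def glcm_features_oracle(p: np.ndarray) -> dict:
    L = p.shape[0]
    hom = cor = ent = con = 0.0
    marg = p.sum(axis=1)
    mu = sum((i + 1) * marg[i] for i in range(L))
    var = sum((i + 1 - mu) ** 2 * marg[i] for i in range(L))
    for i in range(L):
        for j in range(L):
            if p[i, j] > 0:
                ent -= p[i, j] * np.log2(p[i, j])
            hom += p[i, j] / (1 + abs(i - j))
            con += (i - j) ** 2 * p[i, j]
            if var > 0:
                cor += (i + 1 - mu) * (j + 1 - mu) * p[i, j] / var
    return {"HOM": hom, "COR": cor if var > 0 else 0.0, "ENT": ent, "CON": con}


def runs_oracle(levels: np.ndarray, directions=None) -> list[tuple[int, int]]:
    """All maximal in-mask runs as (grey, length) pairs."""
    if directions is None:
        directions = DIRS_13
    shape = levels.shape
    runs = []
    for d in directions:
        for p in np.ndindex(shape):
            g = levels[p]
            if g == 0:
                continue
            prev = tuple(c - o for c, o in zip(p, d))
            if _in(shape, prev) and levels[prev] == g:
                continue  # not a run start
            length = 0
            q = p
            while _in(shape, q) and levels[q] == g:
                length += 1
                q = tuple(c + o for c, o in zip(q, d))
            runs.append((int(g), length))
    return runs


def rlm_features_oracle(runs, n_voxels, n_directions) -> dict:
    nr = len(runs)
    s = lambda f: sum(f(i, l) for i, l in runs) / nr  # noqa: E731
    per_grey = {}
    for i, _ in runs:
        per_grey[i] = per_grey.get(i, 0) + 1
    return {
        "RP": nr / (n_voxels * n_directions),
        "SRE": s(lambda i, l: 1 / l**2),
        "LRE": s(lambda i, l: l**2),
        "GLNU_R": sum(c**2 for c in per_grey.values()) / nr,
        "LGLRE": s(lambda i, l: 1 / i**2),
        "HGLRE": s(lambda i, l: i**2),
        "SRLGLE": s(lambda i, l: 1 / (i**2 * l**2)),
        "SRHGLE": s(lambda i, l: i**2 / l**2),
        "LRLGLE": s(lambda i, l: l**2 / i**2),
        "LRHGLE": s(lambda i, l: i**2 * l**2),
    }


def zones_oracle(levels: np.ndarray) -> list[tuple[int, int]]:
    """All 26-connected constant-grey zones as (grey, size) pairs (flood fill)."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in np.ndindex(shape):
        if levels[p] == 0 or seen[p]:
            continue
        g = levels[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            q = stack.pop()
            size += 1
            for d in ALL_26:
                r = tuple(c + o for c, o in zip(q, d))
                if _in(shape, r) and not seen[r] and levels[r] == g:
                    seen[r] = True
                    stack.append(r)
        zones.append((int(g), size))
    return zones


def szm_features_oracle(zones, n_voxels) -> dict:
    nz = len(zones)
    s = lambda f: sum(f(i, z) for i, z in zones) / nz  # noqa: E731
    per_grey, per_size = {}, {}
    for i, z in zones:
        per_grey[i] = per_grey.get(i, 0) + 1
        per_size[z] = per_size.get(z, 0) + 1
    return {
        "ZP": nz / n_voxels,
        "SZV": sum(c**2 for c in per_size.values()) / nz,
        "SZE": s(lambda i, z: 1 / z**2),
        "LZE": s(lambda i, z: z**2),
        "GLNU_Z": sum(c**2 for c in per_grey.values()) / nz,
        "LGLZE": s(lambda i, z: 1 / i**2),
        "HGLZE": s(lambda i, z: i**2),
        "SZLGLE": s(lambda i, z: 1 / (i**2 * z**2)),
        "SZHGLE": s(lambda i, z: i**2 / z**2),
        "LZLGLE": s(lambda i, z: z**2 / i**2),
        "LZHGLE": s(lambda i, z: i**2 * z**2),
    }


def iv_oracle(zones) -> float:
    per_grey = {}
    for i, _ in zones:
        per_grey[i] = per_grey.get(i, 0) + 1
    return sum(c**2 for c in per_grey.values()) / len(zones)


def all_features_oracle(values: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    """Full 27-parameter vector through the naive path."""
    inside = values[mask]
    vmin, vmax = inside.min(), inside.max()
    levels = np.zeros(values.shape, dtype=int)
    if vmax == vmin:
        levels[mask] = 1
    else:
        levels[mask] = np.clip(
            np.floor(n_levels * (inside - vmin) / (vmax - vmin) + 1), 1, n_levels
        ).astype(int)
    out = glcm_features_oracle(glcm_oracle(levels, n_levels))
    zones = zones_oracle(levels)
    out["IV"] = iv_oracle(zones)
    out.update(szm_features_oracle(zones, int(mask.sum())))
    runs = runs_oracle(levels)
    out.update(rlm_features_oracle(runs, int(mask.sum()), 13))
    mean = inside.mean()
    out["CoV"] = inside.std(ddof=1) / mean if inside.size > 1 else 0.0
    return out
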