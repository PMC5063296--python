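"""Texture matrices on 3D grey-level images.

Three volumetric matrices are computed inside the VOI only; voxels outside
the mask never pair with, extend runs into, or join zones with in-mask
voxels:

* co-occurrence (GLCM): symmetric grey-pair probabilities for the 26
  nearest-neighbour directions, normalised per direction and averaged;
* run length (GLRLM): maximal collinear runs of equal grey level along the
  13 unique 3D directions, counts aggregated over directions;
* size zone (GLSZM): 26-connected components ("zones") of equal grey level,
  counted by grey and size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "SizeZoneMatrix",
    "compute_cooccurrence",
    "compute_runlength",
    "compute_sizezone",
]

def _unique_directions() -> list[tuple[int, int, int]]:
    """The 26-neighbourhood up to sign: 13 directions, first non-zero = +1."""
    seen = set()
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if tuple(-c for c in d) in seen:
                    continue
                seen.add(d)
                # normalise sign: first non-zero component positive
                for c in d:
                    if c:
                        if c < 0:
                            d = tuple(-x for x in d)
                        break
                out.append(d)
    return out


DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(_unique_directions())
assert len(DIRECTIONS_13) == 13


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Direction-averaged symmetric pair-probability matrix p(i, j)."""

    p: np.ndarray  # (n_levels, n_levels), sums to 1
    n_levels: int
    n_directions: int  # directions that contributed >=1 pair

    @property
    def marginal(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def mean(self) -> float:
        i = np.arange(1, self.n_levels + 1)
        return float((i * self.marginal).sum())

    @property
    def variance(self) -> float:
        i = np.arange(1, self.n_levels + 1)
        mu = self.mean
        return float((((i - mu) ** 2) * self.marginal).sum())


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts r(i, l), aggregated over directions.

    ``counts[i-1, l-1]`` is the number of maximal runs of grey level ``i``
    and length ``l`` summed over all directions used.
    """

    counts: np.ndarray  # (n_levels, max_len)
    n_levels: int
    n_voxels: int
    n_directions: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SizeZoneMatrix:
    """Zone counts z(i, s): 26-connected zones of grey ``i`` and size ``s``."""

    counts: np.ndarray  # (n_levels, max_size)
    n_levels: int
    n_voxels: int

    @property
    def n_zones(self) -> int:
        return int(self.counts.sum())


def _offset_views(arr: np.ndarray, off: tuple[int, int, int]):
    """Pair of views of ``arr`` displaced by ``off`` against each other."""
    sl_a, sl_b = [], []
    for n, o in zip(arr.shape, off):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def _bbox(mask: np.ndarray):
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    return sl


def compute_cooccurrence(grey, directions=None) -> CooccurrenceMatrix:
    """Co-occurrence matrix averaged over neighbour directions.

    Pairs are accumulated symmetrically (each unordered neighbour pair adds
    to both p(i,j) and p(j,i)), each direction's matrix is normalised to
    unit sum, and the matrices are averaged over the directions that have at
    least one valid pair.
    """
    if directions is None:
        directions = DIRECTIONS_13
    L = grey.n_levels
    levels = grey.levels[_bbox(grey.mask)]
    acc = np.zeros((L, L), dtype=float)
    used = 0
    for d in directions:
        a, b = _offset_views(levels, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        ia = a[valid].astype(np.int64) - 1
        ib = b[valid].astype(np.int64) - 1
        counts = np.bincount(ia * L + ib, minlength=L * L).reshape(L, L)
        m = counts + counts.T  # symmetric accumulation covers d and -d
        acc += m / m.sum()
        used += 1
    if used == 0:
        raise ValueError("no neighbour pairs inside the mask in any direction")
    p = acc / used
    return CooccurrenceMatrix(p=p, n_levels=L, n_directions=used)


def _runs_one_direction(levels: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """(grey, length) pairs of all maximal in-mask runs along direction d.

    The grid is sheared so that lines along ``d`` become rows of a 2D array,
    then every row is scanned in one vectorised pass with a sentinel column
    separating rows.
    """
    axes = [i for i, c in enumerate(d) if c]
    pivot = axes[0]  # d[pivot] == +1 by construction
    shape = levels.shape
    n_a = shape[pivot]

    idx = np.indices(shape).reshape(3, -1)
    c_a = idx[pivot]
    line_dims = []
    line_keys = []
    for j in range(3):
        if j == pivot:
            continue
        dj = d[j]
        lid = idx[j] - dj * c_a
        if dj > 0:
            lid = lid + (n_a - 1)
        line_dims.append(shape[j] + (n_a - 1 if dj != 0 else 0))
        line_keys.append(lid)
    row = line_keys[0] * line_dims[1] + line_keys[1]
    n_rows = line_dims[0] * line_dims[1]

    lines = np.zeros((n_rows, n_a + 1), dtype=levels.dtype)  # +1 sentinel col
    lines[row, c_a] = levels.ravel()
    seq = lines.ravel()

    change = np.flatnonzero(np.diff(seq) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [seq.size]))
    greys = seq[starts]
    keep = greys > 0
    return np.stack([greys[keep], (ends - starts)[keep]], axis=1)


def compute_runlength(grey, directions=None) -> RunLengthMatrix:
    """Run-length matrix, counts aggregated over the given directions."""
    if directions is None:
        directions = DIRECTIONS_13
    levels = grey.levels[_bbox(grey.mask)]
    L = grey.n_levels
    max_len = max(levels.shape)  # no line in the bbox is longer than this
    counts = np.zeros((L, max_len), dtype=np.int64)
    for d in directions:
        runs = _runs_one_direction(levels, d)
        if runs.size:
            key = (runs[:, 0].astype(np.int64) - 1) * max_len + (runs[:, 1] - 1)
            counts += np.bincount(key, minlength=L * max_len).reshape(L, max_len)
    last = int(np.flatnonzero(counts.any(axis=0)).max()) + 1 if counts.any() else 1
    return RunLengthMatrix(
        counts=counts[:, :last],
        n_levels=L,
        n_voxels=grey.n_voxels,
        n_directions=len(directions),
    )


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def compute_sizezone(grey) -> SizeZoneMatrix:
    """Size-zone matrix from 26-connected constant-grey components."""
    levels = grey.levels[_bbox(grey.mask)]
    L = grey.n_levels
    pairs: list[tuple[int, int]] = []  # (grey-1, size)
    max_size = 1
    for g in np.unique(levels[levels > 0]):
        lab, nlab = ndimage.label(levels == g, structure=_STRUCT_26)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            pairs.append((int(g) - 1, int(s)))
            max_size = max(max_size, int(s))
    counts = np.zeros((L, max_size), dtype=np.int64)
    for i, s in pairs:
        counts[i, s - 1] += 1
    return SizeZoneMatrix(counts=counts, n_levels=L, n_voxels=grey.n_voxels)
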