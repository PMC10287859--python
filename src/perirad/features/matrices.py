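"""Gray-level texture matrices (co-occurrence, run-length, size-zone,
dependence, neighbourhood gray-tone difference).

Intensities inside the mask are discretized with a fixed bin width anchored
at the region minimum (``level = floor((x - min)/width) + 1``), so texture
features are invariant to a constant intensity shift.  Direction-dependent
matrices use the 13 unique 3-D directions of the 26-neighbourhood and are
merged (summed) over directions before feature computation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# 13 unique direction offsets: lexicographically positive half of the
# 26-neighbourhood
DIRECTIONS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
assert len(DIRECTIONS) == 13

_NEIGHBORS26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def discretize(values: np.ndarray, mask: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Integer gray levels (1..Ng inside the mask, 0 outside)."""
    levels = np.zeros(values.shape, dtype=np.int64)
    inside = values[mask]
    lo = inside.min()
    levels[mask] = np.floor((inside - lo) / bin_width).astype(np.int64) + 1
    return levels, int(levels.max())


def _shift_slices(shape, off):
    src = tuple(slice(max(0, o), n + min(0, o)) for n, o in zip(shape, off))
    dst = tuple(slice(max(0, -o), n + min(0, -o)) for n, o in zip(shape, off))
    return src, dst


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts merged over the 13 directions."""
    P = np.zeros((n_levels, n_levels), dtype=np.float64)
    for off in DIRECTIONS:
        src, dst = _shift_slices(levels.shape, off)
        a = levels[dst]
        b = levels[src]
        valid = mask[dst] & mask[src]
        ai = a[valid] - 1
        bi = b[valid] - 1
        np.add.at(P, (ai, bi), 1.0)
        np.add.at(P, (bi, ai), 1.0)
    return P


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts merged over the 13 directions.

    Runs are maximal straight-line segments of equal gray level inside the
    mask.  Implemented by sorting voxels into lines via the cross-product
    line invariant, then vectorized run-length encoding.
    """
    coords = np.indices(levels.shape).reshape(3, -1)
    lv = np.where(mask, levels, 0).ravel()
    max_run = int(max(levels.shape))
    R = np.zeros((n_levels, max_run), dtype=np.float64)
    for off in DIRECTIONS:
        d = np.asarray(off)
        # line id: cross product of position with the direction (constant
        # along a line); order within line: projection onto the direction
        cross = np.cross(coords.T, d).T
        order = d @ coords
        idx = np.lexsort((order, cross[2], cross[1], cross[0]))
        lv_s = lv[idx]
        line = cross[:, idx]
        newline = np.empty(lv_s.size, dtype=bool)
        newline[0] = True
        newline[1:] = (np.diff(line, axis=1) != 0).any(axis=0)
        brk = newline | np.r_[True, lv_s[1:] != lv_s[:-1]]
        starts = np.flatnonzero(brk)
        lengths = np.diff(np.r_[starts, lv_s.size])
        run_levels = lv_s[starts]
        keep = run_levels > 0
        np.add.at(R, (run_levels[keep] - 1, lengths[keep] - 1), 1.0)
    used = R.sum(axis=0).nonzero()[0]
    return R[:, : used[-1] + 1] if used.size else R[:, :1]


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts; zones are 26-connected components of equal level."""
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, n_levels + 1):
        lab, n = ndimage.label(levels == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            max_size = max(max_size, int(s))
    S = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, s in zones:
        S[g - 1, s - 1] += 1.0
    return S


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence counts: per voxel, 1 + number of 26-neighbours (inside the
    mask) whose level differs by at most ``alpha``."""
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _NEIGHBORS26:
        src, dst = _shift_slices(levels.shape, off)
        valid = mask[dst] & mask[src]
        close = np.abs(levels[dst] - levels[src]) <= alpha
        dep[dst] += (valid & close).astype(np.int64)
    dmax = int(dep[mask].max()) + 1
    D = np.zeros((n_levels, dmax), dtype=np.float64)
    np.add.at(D, (levels[mask] - 1, dep[mask]), 1.0)
    return D


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level counts ``n_g`` and summed absolute differences ``s_g``
    between each voxel's level and the mean level of its in-mask
    26-neighbours.  Voxels with no in-mask neighbour are excluded."""
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in _NEIGHBORS26:
        src, dst = _shift_slices(levels.shape, off)
        valid = mask[dst] & mask[src]
        nb_sum[dst] += np.where(valid, levels[src], 0)
        nb_cnt[dst] += valid
    use = mask & (nb_cnt > 0)
    diffs = np.abs(levels[use] - nb_sum[use] / nb_cnt[use])
    n_g = np.zeros(n_levels, dtype=np.float64)
    s_g = np.zeros(n_levels, dtype=np.float64)
    np.add.at(n_g, levels[use] - 1, 1.0)
    np.add.at(s_g, levels[use] - 1, diffs)
    return n_g, s_g
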