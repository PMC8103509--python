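"""Gray-level discretization and the five texture-matrix builders.

All builders operate on a bounding-box-cropped integer level array ``lev``
(levels 1..Ng inside the ROI) plus a boolean validity mask of the same
shape. Texture neighborhoods are 3-D: 26-connectivity, Chebyshev
distance 1; directional matrices (GLCM, GLRLM) use the 13 unique
direction vectors (one of each antipodal pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DiscretizedRoi",
    "discretize",
    "roi_level_array",
    "DIRECTIONS_13",
    "OFFSETS_26",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_gldm",
    "build_ngtdm",
]


@dataclass(frozen=True)
class DiscretizedRoi:
    """ROI voxel values binned with a fixed bin width (default 25 HU).

    level(x) = floor(x/W) - floor(min/W) + 1, so the lowest occupied bin is
    level 1 and Ng is the highest occupied level.
    """

    values: np.ndarray  # original HU values, 1-D
    levels: np.ndarray  # integer level per voxel, 1-D
    bin_width: float
    n_levels: int


def discretize(values: np.ndarray, bin_width: float = 25.0) -> DiscretizedRoi:
    """Fixed-bin-width discretization anchored at the ROI minimum's bin."""
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("empty ROI cannot be discretized")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    base = np.floor(vals.min() / bin_width)
    levels = (np.floor(vals / bin_width) - base + 1).astype(np.int64)
    return DiscretizedRoi(
        values=vals, levels=levels, bin_width=float(bin_width),
        n_levels=int(levels.max()),
    )


def roi_level_array(
    voxels: np.ndarray, roi: np.ndarray, bin_width: float = 25.0
) -> tuple[np.ndarray, np.ndarray, DiscretizedRoi]:
    """Crop to the ROI bounding box and return (lev, valid, disc).

    ``lev`` holds discretized levels inside the ROI and 0 outside.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    sl = ndimage.find_objects(roi.astype(np.int8))[0]
    roi_c = roi[sl]
    disc = discretize(np.asarray(voxels, dtype=np.float64)[roi], bin_width)
    lev = np.zeros(roi_c.shape, dtype=np.int64)
    lev[roi_c] = disc.levels
    return lev, roi_c, disc


def _half_directions() -> list[tuple[int, int, int]]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) > (0, 0, 0):
                    dirs.append((dx, dy, dz))
    return dirs


DIRECTIONS_13: list[tuple[int, int, int]] = _half_directions()
OFFSETS_26: list[tuple[int, int, int]] = [
    d for d in DIRECTIONS_13
] + [(-a, -b, -c) for (a, b, c) in DIRECTIONS_13]


def _shift(arr: np.ndarray, off: tuple[int, int, int], fill=0) -> np.ndarray:
    """arr translated by ``off``; vacated cells take ``fill``."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, o in zip(arr.shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _pairs_along(lev, valid, d):
    """(levels here, levels there) for in-ROI voxel pairs offset by d."""
    v2 = _shift(valid, tuple(-x for x in d), fill=False)
    l2 = _shift(lev, tuple(-x for x in d))
    both = valid & v2
    return lev[both], l2[both]


def build_glcm(lev: np.ndarray, valid: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts, shape (Ng, Ng, 13)."""
    ng = n_levels
    out = np.zeros((ng, ng, len(DIRECTIONS_13)), dtype=np.float64)
    for a, d in enumerate(DIRECTIONS_13):
        li, lj = _pairs_along(lev, valid, d)
        if li.size:
            flat = np.bincount((li - 1) * ng + (lj - 1), minlength=ng * ng)
            m = flat.reshape(ng, ng).astype(np.float64)
            out[:, :, a] = m + m.T
    return out


def build_glrlm(lev: np.ndarray, valid: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts, shape (Ng, max_run, 13); maximal runs only."""
    ng = n_levels
    max_run = max(lev.shape) * 2  # diagonal runs cannot exceed any axis length
    out = np.zeros((ng, max_run, len(DIRECTIONS_13)), dtype=np.float64)
    for a, d in enumerate(DIRECTIONS_13):
        neg = tuple(-x for x in d)
        # same[v]: run continues from v to v+d
        same_v = _shift(valid, neg, fill=False)
        same = valid & same_v & (lev == _shift(lev, neg))
        # starts: in ROI and predecessor along d is absent or different
        prev_same = _shift(same, d, fill=False)
        starts = valid & ~prev_same
        # run length at each start = 1 + consecutive `same` steps
        length = np.zeros(lev.shape, dtype=np.int64)
        length[starts] = 1
        cont = starts & same
        step_same = same
        while cont.any():
            length[cont] += 1
            step_same = _shift(step_same, neg, fill=False)
            cont = cont & step_same
        ls = lev[starts]
        rl = length[starts]
        if ls.size:
            flat = np.bincount((ls - 1) * max_run + (rl - 1), minlength=ng * max_run)
            out[:, :, a] = flat.reshape(ng, max_run)
    # trim trailing all-zero run-length columns
    used = max(1, int(np.max(np.nonzero(out.any(axis=(0, 2)))[0])) + 1) if out.any() else 1
    return out[:, :used, :]


def build_glszm(lev: np.ndarray, valid: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts (26-connected components of equal level), (Ng, max_size)."""
    ng = n_levels
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    for i in range(1, ng + 1):
        comp, ncomp = ndimage.label(lev == i, structure=structure)
        if ncomp:
            sizes = np.bincount(comp.ravel())[1:]
            zones.extend((i, int(s)) for s in sizes)
    max_size = max(s for _, s in zones) if zones else 1
    out = np.zeros((ng, max_size), dtype=np.float64)
    for i, s in zones:
        out[i - 1, s - 1] += 1
    return out


def build_gldm(
    lev: np.ndarray, valid: np.ndarray, n_levels: int, alpha: int = 0
) -> np.ndarray:
    """Dependence counts: (Ng, Nd) where column j is dependence j-1."""
    ng = n_levels
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in OFFSETS_26:
        nb_valid = _shift(valid, tuple(-x for x in off), fill=False)
        nb_lev = _shift(lev, tuple(-x for x in off))
        dep += (valid & nb_valid & (np.abs(lev - nb_lev) <= alpha)).astype(np.int64)
    deps = dep[valid]
    levels = lev[valid]
    max_dep = int(deps.max()) if deps.size else 0
    out = np.zeros((ng, max_dep + 1), dtype=np.float64)
    np.add.at(out, (levels - 1, deps), 1.0)
    return out


def build_ngtdm(
    lev: np.ndarray, valid: np.ndarray, n_levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): occupancy and summed absolute difference from
    the mean level of the 26-neighborhood. Voxels with no in-ROI neighbor
    are excluded from both."""
    nb_sum = np.zeros(lev.shape, dtype=np.float64)
    nb_cnt = np.zeros(lev.shape, dtype=np.float64)
    for off in OFFSETS_26:
        nb_valid = _shift(valid, tuple(-x for x in off), fill=False)
        nb_lev = _shift(lev, tuple(-x for x in off))
        nb_sum += np.where(nb_valid, nb_lev, 0.0)
        nb_cnt += nb_valid
    has_nb = valid & (nb_cnt > 0)
    diff = np.zeros(lev.shape, dtype=np.float64)
    diff[has_nb] = np.abs(lev[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    n_i = np.zeros(n_levels, dtype=np.float64)
    s_i = np.zeros(n_levels, dtype=np.float64)
    np.add.at(n_i, lev[has_nb] - 1, 1.0)
    np.add.at(s_i, lev[has_nb] - 1, diff[has_nb])
    return n_i, s_i
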