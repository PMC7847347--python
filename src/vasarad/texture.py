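"""Gray-level discretization and 3-D texture matrix construction.

All four texture families (GLCM, GLRLM, GLSZM, NGTDM) operate on a volume
quantized to ``n_levels`` gray levels inside the tumor mask.  Quantization is
uniform between the in-mask minimum and maximum with a fixed bin count, so
the level grid adapts per subject while the number of levels — and hence the
texture-matrix dimensions — stays comparable across subjects.

Direction handling: pairwise statistics (GLCM, GLRLM) use the 13 unique 3-D
offsets at Chebyshev distance 1 (one representative per +/- pair) and the
per-direction matrices are summed ("merged") before any feature is computed,
giving one rotation-robust value per feature per subject.  Zones (GLSZM) use
26-connectivity.  Voxels outside the mask break runs and zones and are
excluded from co-occurrence pairs and neighborhood averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import MaskedVolume

#: 13 unique offsets at Chebyshev distance 1: the first nonzero component of
#: each canonical representative is positive.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
    and next(c for c in (dx, dy, dz) if c != 0) > 0
)

#: All 26 neighbor offsets (both signs), used by the NGTDM.
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


@dataclass
class GrayLevelVolume:
    """Discretized volume: levels 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray
    n_levels: int
    source_min: float
    source_max: float
    degenerate: bool = False

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.levels))


@dataclass
class TextureMatrices:
    """Merged texture matrices of one subject.

    glcm:   (Ng, Ng) symmetric joint probability, sums to 1.
    glrlm:  (Ng, Rmax) run counts merged over directions; ``glrlm_per_direction``
            keeps the (13, Ng, Rmax) stack for conservation checks.
    glszm:  (Ng, Zmax) zone counts under 26-connectivity.
    ngtdm_s:       per-level summed absolute difference from the neighborhood mean.
    ngtdm_counts:  per-level voxel counts (voxels with >= 1 in-mask neighbor).
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glrlm_per_direction: np.ndarray
    glszm: np.ndarray
    ngtdm_s: np.ndarray
    ngtdm_counts: np.ndarray
    n_levels: int
    n_voxels: int


def discretize(volume: MaskedVolume, n_levels: int = 32) -> GrayLevelVolume:
    """Uniformly quantize in-mask intensities to ``n_levels`` gray levels.

    The in-mask minimum maps to level 1 and the maximum to level
    ``n_levels``.  A constant in-mask volume cannot be binned; every voxel is
    assigned level 1 and the result is flagged degenerate.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vals = volume.values
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.mask.shape, dtype=np.int32)
    if vmax == vmin:
        levels[volume.mask] = 1
        return GrayLevelVolume(levels, n_levels, vmin, vmax, degenerate=True)
    binned = np.floor((vals - vmin) / (vmax - vmin) * n_levels).astype(np.int32) + 1
    np.clip(binned, 1, n_levels, out=binned)
    levels[volume.mask] = binned
    return GrayLevelVolume(levels, n_levels, vmin, vmax)


def _shift_slices(offset):
    """Source and destination slicing for a voxel offset."""
    src, dst = [], []
    for d in offset:
        if d == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif d > 0:
            src.append(slice(None, -d))
            dst.append(slice(d, None))
        else:
            src.append(slice(-d, None))
            dst.append(slice(None, d))
    return tuple(src), tuple(dst)


def build_glcm(glv: GrayLevelVolume) -> np.ndarray:
    """Symmetric co-occurrence probabilities merged over the 13 directions."""
    ng = glv.n_levels
    counts = np.zeros((ng + 1) * (ng + 1), dtype=np.int64)
    lv = glv.levels
    for off in DIRECTIONS_13:
        src, dst = _shift_slices(off)
        a = lv[src].ravel()
        b = lv[dst].ravel()
        valid = (a > 0) & (b > 0)
        pairs = a[valid].astype(np.int64) * (ng + 1) + b[valid]
        counts += np.bincount(pairs, minlength=counts.size)
    mat = counts.reshape(ng + 1, ng + 1)[1:, 1:].astype(float)
    mat = mat + mat.T  # count each pair in both orders -> symmetric
    total = mat.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs inside the mask")
    return mat / total


def build_glrlm(glv: GrayLevelVolume) -> np.ndarray:
    """Run-length count matrices, one per direction: shape (13, Ng, Rmax).

    Runs are maximal straight segments of equal gray level; out-of-mask
    voxels (level 0) break runs.  Vectorized by sorting voxels into scan
    order along each direction (line identity, then position on the line).
    """
    lv = glv.levels
    shape = lv.shape
    rmax = max(shape)
    flat = lv.ravel()
    idx = np.indices(shape).reshape(3, -1)
    out = np.zeros((len(DIRECTIONS_13), glv.n_levels + 1, rmax + 1), dtype=np.int64)
    for k, off in enumerate(DIRECTIONS_13):
        a0 = next(i for i, c in enumerate(off) if c != 0)  # off[a0] == +1
        t = idx[a0]
        keys = [idx[j] - off[j] * t for j in range(3) if j != a0]
        order = np.lexsort((t, keys[1], keys[0]))
        sl = flat[order]
        k0 = keys[0][order]
        k1 = keys[1][order]
        new_run = np.empty(sl.size, dtype=bool)
        new_run[0] = True
        new_run[1:] = (sl[1:] != sl[:-1]) | (k0[1:] != k0[:-1]) | (k1[1:] != k1[:-1])
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, sl.size))
        run_levels = sl[starts]
        keep = run_levels > 0
        np.add.at(out[k], (run_levels[keep], lengths[keep]), 1)
    return out[:, 1:, 1:]


def build_glszm(glv: GrayLevelVolume) -> np.ndarray:
    """Zone-size count matrix under 26-connectivity: shape (Ng, Zmax)."""
    structure = np.ones((3, 3, 3), dtype=int)
    nvox = glv.n_voxels
    out = np.zeros((glv.n_levels + 1, nvox + 1), dtype=np.int64)
    zmax = 0
    for g in range(1, glv.n_levels + 1):
        binary = glv.levels == g
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        np.add.at(out[g], sizes, 1)
        zmax = max(zmax, int(sizes.max()))
    return out[1:, 1 : max(zmax, 1) + 1]


def build_ngtdm(glv: GrayLevelVolume) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood gray-tone difference totals s(i) and level counts N_i.

    The neighborhood mean at a voxel averages the gray levels of its in-mask
    26-neighbors only; boundary voxels with a truncated neighborhood use
    whatever neighbors are available.  Voxels with no in-mask neighbor are
    excluded from the counts.
    """
    lv = glv.levels.astype(float)
    mask = glv.levels > 0
    nsum = np.zeros(lv.shape)
    ncnt = np.zeros(lv.shape)
    for off in OFFSETS_26:
        src, dst = _shift_slices(off)
        nsum[dst] += np.where(mask[src], lv[src], 0.0)
        ncnt[dst] += mask[src]
    valid = mask & (ncnt > 0)
    avg = np.zeros(lv.shape)
    avg[valid] = nsum[valid] / ncnt[valid]
    diff = np.abs(lv - avg)
    ng = glv.n_levels
    s = np.bincount(
        glv.levels[valid], weights=diff[valid], minlength=ng + 1
    )[1:]
    counts = np.bincount(glv.levels[valid], minlength=ng + 1)[1:]
    return s, counts.astype(np.int64)


def build_texture_matrices(glv: GrayLevelVolume) -> TextureMatrices:
    """Build all four texture-matrix families for one discretized volume."""
    glrlm_dirs = build_glrlm(glv)
    s, counts = build_ngtdm(glv)
    return TextureMatrices(
        glcm=build_glcm(glv),
        glrlm=glrlm_dirs.sum(axis=0),
        glrlm_per_direction=glrlm_dirs,
        glszm=build_glszm(glv),
        ngtdm_s=s,
        ngtdm_counts=counts,
        n_levels=glv.n_levels,
        n_voxels=glv.n_voxels,
    )
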