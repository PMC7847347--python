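"""Independent brute-force oracles for texture matrices and features.

Everything here is written as plain nested loops over voxels, offsets, runs
and zones, deliberately sharing no code with the package implementation.
Only small volumes (~6x6x6) are practical.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
    and next(c for c in (dx, dy, dz) if c != 0) > 0
]
OFFS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in_bounds(p, shape):
    return all(0 <= p[i] < shape[i] for i in range(3))


def glcm_matrix(levels, ng):
    """Pair enumeration over all 26 offsets (equals 13 merged + transpose)."""
    shape = levels.shape
    mat = np.zeros((ng, ng))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                i = levels[x, y, z]
                if i == 0:
                    continue
                for d in OFFS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if not _in_bounds(q, shape):
                        continue
                    j = levels[q]
                    if j == 0:
                        continue
                    mat[i - 1, j - 1] += 1
    return mat / mat.sum()


def glrlm_matrix(levels, ng, direction):
    """Run scanning along one direction; out-of-mask voxels break runs."""
    shape = levels.shape
    rmax = max(shape)
    mat = np.zeros((ng, rmax))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                prev = (x - direction[0], y - direction[1], z - direction[2])
                if _in_bounds(prev, shape) and levels[prev] == g:
                    continue  # not a run start
                length = 1
                cur = (x + direction[0], y + direction[1], z + direction[2])
                while _in_bounds(cur, shape) and levels[cur] == g:
                    length += 1
                    cur = (
                        cur[0] + direction[0],
                        cur[1] + direction[1],
                        cur[2] + direction[2],
                    )
                mat[g - 1, length - 1] += 1
    return mat


def glrlm_merged(levels, ng):
    return sum(glrlm_matrix(levels, ng, d) for d in DIRS_13)


def glszm_matrix(levels, ng):
    """26-connected flood fill per gray level."""
    shape = levels.shape
    nvox = int((levels > 0).sum())
    mat = np.zeros((ng, nvox))
    seen = np.zeros(shape, dtype=bool)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0 or seen[x, y, z]:
                    continue
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    p = queue.popleft()
                    size += 1
                    for d in OFFS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _in_bounds(q, shape) and not seen[q] and levels[q] == g:
                            seen[q] = True
                            queue.append(q)
                mat[g - 1, size - 1] += 1
    return mat


def ngtdm_arrays(levels, ng):
    """Per-voxel neighborhood means over available in-mask 26-neighbors."""
    shape = levels.shape
    s = np.zeros(ng)
    counts = np.zeros(ng, dtype=int)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                neigh = []
                for d in OFFS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _in_bounds(q, shape) and levels[q] > 0:
                        neigh.append(levels[q])
                if not neigh:
                    continue
                s[g - 1] += abs(g - sum(neigh) / len(neigh))
                counts[g - 1] += 1
    return s, counts


# --- naive feature formulas (straight sums over matrix cells) ---------------


def glcm_features(p):
    ng = p.shape[0]
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    sigma = math.sqrt(var)
    corr = 0.0
    if sigma > 0:
        corr = sum(
            (i + 1 - mu) * (j + 1 - mu) * p[i, j] / var
            for i in range(ng)
            for j in range(ng)
        )
    ent = -sum(
        p[i, j] * math.log2(p[i, j]) for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    return {
        "GLCM energy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "GLCM contrast": sum(
            (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "GLCM correlation": corr,
        "GLCM homogeneity": sum(
            p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        ),
        "GLCM entropy": ent,
        "GLCM variance": var,
        "GLCM sum average": sum(
            (i + j + 2) * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "GLCM dissimilarity": sum(
            abs(i - j) * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "GLCM autocorrelation": sum(
            (i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)
        ),
    }


def _run_zone_features(mat, n_voxels, prefix, length_word):
    ng, jm = mat.shape
    total = mat.sum()
    short = {"run": "short run", "zone": "small zone"}[length_word]
    long_ = {"run": "long run", "zone": "large zone"}[length_word]
    lg = {"run": "low gray-level run", "zone": "low gray-level zone"}[length_word]
    hg = {"run": "high gray-level run", "zone": "high gray-level zone"}[length_word]
    ln = {"run": "run-length", "zone": "zone-size"}[length_word]
    cell = lambda f: sum(
        f(i + 1, j + 1) * mat[i, j] for i in range(ng) for j in range(jm)
    )
    mu_i = cell(lambda i, j: i) / total
    mu_j = cell(lambda i, j: j) / total
    return {
        f"{prefix} {short} emphasis": cell(lambda i, j: 1 / j**2) / total,
        f"{prefix} {long_} emphasis": cell(lambda i, j: j**2) / total,
        f"{prefix} gray-level nonuniformity": sum(mat[i, :].sum() ** 2 for i in range(ng))
        / total,
        f"{prefix} {ln} nonuniformity": sum(mat[:, j].sum() ** 2 for j in range(jm))
        / total,
        f"{prefix} {'run' if length_word == 'run' else 'zone'} percentage": total
        / n_voxels,
        f"{prefix} {lg} emphasis": cell(lambda i, j: 1 / i**2) / total,
        f"{prefix} {hg} emphasis": cell(lambda i, j: i**2) / total,
        f"{prefix} {short} low gray-level emphasis": cell(lambda i, j: 1 / (i**2 * j**2))
        / total,
        f"{prefix} {short} high gray-level emphasis": cell(lambda i, j: i**2 / j**2)
        / total,
        f"{prefix} {long_} low gray-level emphasis": cell(lambda i, j: j**2 / i**2)
        / total,
        f"{prefix} {long_} high gray-level emphasis": cell(lambda i, j: i**2 * j**2)
        / total,
        f"{prefix} gray-level variance": cell(lambda i, j: (i - mu_i) ** 2) / total,
        f"{prefix} {ln} variance": cell(lambda i, j: (j - mu_j) ** 2) / total,
    }


def glrlm_features(mat, n_voxels_times_dirs):
    return _run_zone_features(mat, n_voxels_times_dirs, "GLRLM", "run")


def glszm_features(mat, n_voxels):
    return _run_zone_features(mat, n_voxels, "GLSZM", "zone")


def ngtdm_features(s, counts, eps=1e-12):
    ng = len(s)
    n = counts.sum()
    p = counts / n
    occ = [i for i in range(ng) if p[i] > 0]
    ps = sum(p[i] * s[i] for i in range(ng))
    coarseness = min(1 / max(ps, eps), 1 / eps)
    if len(occ) < 2:
        return {
            "NGTDM coarseness": coarseness,
            "NGTDM contrast": 0.0,
            "NGTDM busyness": 0.0,
            "NGTDM complexity": 0.0,
            "NGTDM strength": 0.0,
        }
    npair = len(occ) * (len(occ) - 1)
    contrast = (
        sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ) / npair
    ) * (s.sum() / n)
    busy_den = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in occ for j in occ
    )
    busyness = ps / max(busy_den, eps)
    complexity = sum(
        abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
        for i in occ
        for j in occ
    ) / n
    strength = sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ) / max(
        s.sum(), eps
    )
    return {
        "NGTDM coarseness": coarseness,
        "NGTDM contrast": contrast,
        "NGTDM busyness": busyness,
        "NGTDM complexity": complexity,
        "NGTDM strength": strength,
    }


def mutual_information(x, y):
    """Direct plug-in MI (bits) via explicit probability sums."""
    x = list(x)
    y = list(y)
    n = len(x)
    mi = 0.0
    for xv in set(x):
        for yv in set(y):
            pxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv) / n
            if pxy == 0:
                continue
            px = x.count(xv) / n
            py = y.count(yv) / n
            mi += pxy * math.log2(pxy / (px * py))
    return mi
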