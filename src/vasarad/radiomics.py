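"""The 56-feature ADC radiomics panel.

Families and counts: 3 shape, 13 first-order histogram, 9 GLCM, 13 GLRLM,
13 GLSZM, 5 NGTDM.  Feature names follow the field's conventional spellings
(e.g. "GLRLM short run low gray-level emphasis") and are listed, in extraction
order, in :data:`FEATURE_REGISTRY`.

Conventions worth noting:

* Texture features are computed on direction-merged matrices (see
  :mod:`vasarad.texture`), so each subject yields a single value per feature.
* Run percentage and zone percentage are normalized by the in-mask voxel
  count; for the merged run matrix this equals the sum over directions of
  runs divided by the voxel count.
* Histogram entropy and uniformity are computed on a fixed 64-bin in-mask
  histogram (configurable via ``entropy_bins``); all logs are base 2.
* NGTDM features use an epsilon guard (1e-12) on denominators that vanish
  for flat volumes; coarseness is capped at 1/epsilon in that case.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pandas as pd
from scipy import stats

from .texture import GrayLevelVolume, TextureMatrices, build_texture_matrices, discretize
from .types import FeatureTable, MaskedVolume

EPS = 1e-12

SHAPE_FEATURES = ["Eccentricity", "Volume", "Surface-to-volume ratio"]
HISTOGRAM_FEATURES = [
    "Histogram mean",
    "Histogram median",
    "Histogram minimum",
    "Histogram maximum",
    "Histogram range",
    "Histogram variance",
    "Histogram standard deviation",
    "Histogram skewness",
    "Histogram kurtosis",
    "Histogram energy",
    "Histogram entropy",
    "Histogram uniformity",
    "Histogram mean absolute deviation",
]
GLCM_FEATURES = [
    "GLCM energy",
    "GLCM contrast",
    "GLCM correlation",
    "GLCM homogeneity",
    "GLCM entropy",
    "GLCM variance",
    "GLCM sum average",
    "GLCM dissimilarity",
    "GLCM autocorrelation",
]
GLRLM_FEATURES = [
    "GLRLM short run emphasis",
    "GLRLM long run emphasis",
    "GLRLM gray-level nonuniformity",
    "GLRLM run-length nonuniformity",
    "GLRLM run percentage",
    "GLRLM low gray-level run emphasis",
    "GLRLM high gray-level run emphasis",
    "GLRLM short run low gray-level emphasis",
    "GLRLM short run high gray-level emphasis",
    "GLRLM long run low gray-level emphasis",
    "GLRLM long run high gray-level emphasis",
    "GLRLM gray-level variance",
    "GLRLM run-length variance",
]
GLSZM_FEATURES = [
    "GLSZM small zone emphasis",
    "GLSZM large zone emphasis",
    "GLSZM gray-level nonuniformity",
    "GLSZM zone-size nonuniformity",
    "GLSZM zone percentage",
    "GLSZM low gray-level zone emphasis",
    "GLSZM high gray-level zone emphasis",
    "GLSZM small zone low gray-level emphasis",
    "GLSZM small zone high gray-level emphasis",
    "GLSZM large zone low gray-level emphasis",
    "GLSZM large zone high gray-level emphasis",
    "GLSZM gray-level variance",
    "GLSZM zone-size variance",
]
NGTDM_FEATURES = [
    "NGTDM coarseness",
    "NGTDM contrast",
    "NGTDM busyness",
    "NGTDM complexity",
    "NGTDM strength",
]

#: Canonical extraction order of the full 56-feature panel.
FEATURE_REGISTRY: tuple[str, ...] = tuple(
    SHAPE_FEATURES
    + HISTOGRAM_FEATURES
    + GLCM_FEATURES
    + GLRLM_FEATURES
    + GLSZM_FEATURES
    + NGTDM_FEATURES
)


def shape_features(mask: np.ndarray, spacing) -> "OrderedDict[str, float]":
    """Eccentricity, physical volume (mm^3) and surface-to-volume ratio.

    Eccentricity is sqrt(1 - lambda_min / lambda_max) of the eigenvalues of
    the spatial covariance of in-mask voxel coordinates in physical units;
    a single-voxel mask has zero covariance and eccentricity 0.  Surface area
    counts exposed voxel faces, each weighted by its physical face area.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing, dtype=float)
    coords = np.argwhere(mask) * spacing
    n = coords.shape[0]
    if n == 1:
        ecc = 0.0
    else:
        cov = np.cov(coords.T, bias=True)
        eig = np.linalg.eigvalsh(cov)
        lmax = eig[-1]
        ecc = 0.0 if lmax <= 0 else float(np.sqrt(max(0.0, 1.0 - eig[0] / lmax)))
    voxel_vol = float(np.prod(spacing))
    volume = n * voxel_vol
    # exposed faces along each axis; face area = product of the other spacings
    area = 0.0
    for ax in range(3):
        face = voxel_vol / spacing[ax]
        padded = np.pad(mask, [(1, 1) if i == ax else (0, 0) for i in range(3)])
        exposed = np.abs(np.diff(padded.astype(np.int8), axis=ax)).sum()
        area += face * exposed
    return OrderedDict(zip(SHAPE_FEATURES, [ecc, volume, area / volume]))


def histogram_features(
    volume: MaskedVolume, entropy_bins: int = 64
) -> "OrderedDict[str, float]":
    """13 first-order statistics of the in-mask intensity distribution."""
    x = volume.values
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    if sd == 0:
        skew = kurt = 0.0
        entropy = 0.0
        uniformity = 1.0
    else:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))  # excess kurtosis
        hist, _ = np.histogram(x, bins=entropy_bins)
        p = hist[hist > 0] / n
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((np.square(hist / n)).sum())
    values = [
        mean,
        float(np.median(x)),
        float(x.min()),
        float(x.max()),
        float(x.max() - x.min()),
        var,
        sd,
        skew,
        kurt,
        float(np.square(x).sum()),
        entropy,
        uniformity,
        float(np.abs(x - mean).mean()),
    ]
    return OrderedDict(zip(HISTOGRAM_FEATURES, values))


def glcm_features(matrices: TextureMatrices) -> "OrderedDict[str, float]":
    """9 co-occurrence features on the merged symmetric matrix p(i, j)."""
    p = matrices.glcm
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    px = p.sum(axis=1)
    mu = float((i[:, 0] * px).sum())
    sigma2 = float(((i[:, 0] - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)
    if sigma == 0:
        corr = 0.0
    else:
        corr = float(((i - mu) * (j - mu) * p).sum() / sigma2)
    nz = p[p > 0]
    # sum average over the distribution of i+j
    ksum = np.arange(2, 2 * ng + 1)
    psum = np.array([p[(i + j) == k].sum() for k in ksum])
    values = [
        float((p**2).sum()),
        float(((i - j) ** 2 * p).sum()),
        corr,
        float((p / (1.0 + np.abs(i - j))).sum()),
        float(-(nz * np.log2(nz)).sum()),
        float(((i - mu) ** 2 * p).sum()),
        float((ksum * psum).sum()),
        float((np.abs(i - j) * p).sum()),
        float((i * j * p).sum()),
    ]
    return OrderedDict(zip(GLCM_FEATURES, values))


def _run_zone_features(mat: np.ndarray, n_voxels: int, names) -> "OrderedDict[str, float]":
    """Shared emphasis/nonuniformity/variance formulas for GLRLM and GLSZM.

    ``mat[i-1, j-1]`` counts runs (or zones) of gray level i and length
    (or size) j.  The run/zone percentage divides the total count by the
    in-mask voxel count.
    """
    total = mat.sum()
    if total == 0:
        raise ValueError("empty run/zone matrix")
    ng, jmax = mat.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, jmax + 1)[None, :].astype(float)
    pr = mat / total
    mu_i = float((i * pr).sum())
    mu_j = float((j * pr).sum())
    ri = mat.sum(axis=1)  # per gray level
    rj = mat.sum(axis=0)  # per length/size
    values = [
        float((mat / j**2).sum() / total),
        float((mat * j**2).sum() / total),
        float((ri**2).sum() / total),
        float((rj**2).sum() / total),
        float(total / n_voxels),
        float((mat / i**2).sum() / total),
        float((mat * i**2).sum() / total),
        float((mat / (i**2 * j**2)).sum() / total),
        float((mat * i**2 / j**2).sum() / total),
        float((mat * j**2 / i**2).sum() / total),
        float((mat * i**2 * j**2).sum() / total),
        float((pr * (i - mu_i) ** 2).sum()),
        float((pr * (j - mu_j) ** 2).sum()),
    ]
    return OrderedDict(zip(names, values))


def glrlm_features(matrices: TextureMatrices) -> "OrderedDict[str, float]":
    """13 run-length features on the direction-merged matrix.

    Run percentage uses the in-mask voxel count times the number of merged
    directions as denominator — i.e. the mean run percentage per direction.
    """
    n_dir = matrices.glrlm_per_direction.shape[0]
    return _run_zone_features(
        matrices.glrlm.astype(float), matrices.n_voxels * n_dir, GLRLM_FEATURES
    )


def glszm_features(matrices: TextureMatrices) -> "OrderedDict[str, float]":
    """13 size-zone features (26-connected zones)."""
    return _run_zone_features(
        matrices.glszm.astype(float), matrices.n_voxels, GLSZM_FEATURES
    )


def ngtdm_features(matrices: TextureMatrices) -> "OrderedDict[str, float]":
    """Coarseness, contrast, busyness, complexity and strength."""
    s = matrices.ngtdm_s
    counts = matrices.ngtdm_counts
    n = counts.sum()
    if n == 0:
        raise ValueError("no voxels with a valid neighborhood")
    p = counts / n
    occupied = np.flatnonzero(p > 0)
    ngp = occupied.size
    i = np.arange(1, s.size + 1).astype(float)

    ps = float((p * s).sum())
    coarseness = min(1.0 / max(ps, EPS), 1.0 / EPS)

    if ngp < 2:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    else:
        io = i[occupied]
        po = p[occupied]
        so = s[occupied]
        dif2 = (io[:, None] - io[None, :]) ** 2
        contrast = float(
            (po[:, None] * po[None, :] * dif2).sum()
            / (ngp * (ngp - 1))
            * (s.sum() / n)
        )
        denom = float(np.abs(io[:, None] * po[:, None] - io[None, :] * po[None, :]).sum())
        busyness = ps / max(denom, EPS)
        pair_w = (po[:, None] * so[:, None] + po[None, :] * so[None, :]) / (
            po[:, None] + po[None, :]
        )
        complexity = float((np.abs(io[:, None] - io[None, :]) * pair_w).sum() / n)
        strength = float(
            ((po[:, None] + po[None, :]) * dif2).sum() / max(float(s.sum()), EPS)
        )
    values = [coarseness, contrast, busyness, complexity, strength]
    return OrderedDict(zip(NGTDM_FEATURES, values))


def extract_all(
    volume: MaskedVolume, n_levels: int = 32, entropy_bins: int = 64
) -> "OrderedDict[str, float]":
    """Extract the full 56-feature panel from one masked ADC volume."""
    out: "OrderedDict[str, float]" = OrderedDict()
    out.update(shape_features(volume.mask, volume.spacing))
    out.update(histogram_features(volume, entropy_bins=entropy_bins))
    glv = discretize(volume, n_levels=n_levels)
    mats = build_texture_matrices(glv)
    out.update(glcm_features(mats))
    out.update(glrlm_features(mats))
    out.update(glszm_features(mats))
    out.update(ngtdm_features(mats))
    assert tuple(out.keys()) == FEATURE_REGISTRY
    return out


def extract_table(
    subjects: list[tuple[str, MaskedVolume, str]],
    n_levels: int = 32,
) -> FeatureTable:
    """Extract features for a list of (id, volume, label) into a FeatureTable."""
    rows = {}
    labels = {}
    for sid, vol, label in subjects:
        rows[sid] = extract_all(vol, n_levels=n_levels)
        labels[sid] = label
    data = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_REGISTRY)]
    return FeatureTable(data, pd.Series(labels).loc[data.index])


def normalize_features(
    table: FeatureTable, bounds: dict[str, tuple[float, float]] | None = None
) -> FeatureTable:
    """Min-max rescale every column to [0, 1].

    When ``bounds`` is None (training cohort) the per-column min/max are
    fitted from the table and stored on the result; otherwise (validation
    cohort) the provided training bounds are reused and out-of-range values
    are clipped into [0, 1].  Constant columns map to 0 and are flagged.
    """
    fitted = bounds is None
    if fitted:
        bounds = {
            name: (float(col.min()), float(col.max()))
            for name, col in table.data.items()
        }
    data = table.data.copy().astype(float)
    degenerate = set(table.degenerate)
    for name in data.columns:
        lo, hi = bounds[name]
        if hi == lo:
            data[name] = 0.0
            degenerate.add(name)
        else:
            data[name] = ((data[name] - lo) / (hi - lo)).clip(0.0, 1.0)
    return FeatureTable(
        data, table.labels.copy(), bounds=dict(bounds), degenerate=frozenset(degenerate)
    )
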