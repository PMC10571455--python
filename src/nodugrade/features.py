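"""The 72-element radiomic descriptor of a nodule patch.

Composition (registry version 1.0):

* 48 Haralick texture statistics — 16 statistics per co-occurrence
  distance d in {1, 2, 3}, each from a symmetric gray-level
  co-occurrence matrix (GLCM) accumulated over the four offsets
  0/45/90/135 degrees after quantizing G to 32 levels;
* 1 image entropy (Shannon, base 2, over the 32-level histogram of G);
* 13 geometric scalars from the binary mask B (centroid offset from the
  patch centre, axis lengths, eccentricity, orientation, convex area,
  filled area, Euler number, equivalent diameter, solidity, extent, and
  two perimeter estimators);
* 7 Hu invariant moments of B, signed-log transformed;
* 3 intensity moments (mean, population variance, biased Fisher
  skewness) of G restricted to B.

Texture and intensity features come from G, geometric and Hu features
from B. Index conventions for the Haralick statistics follow the
classic 1-based formulation; degenerate inputs (constant image, zero
variance) return the documented limits instead of NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.measure import moments_central, moments_hu, moments_normalized, regionprops

from .patches import NodulePatch

REGISTRY_VERSION = "1.0"
N_LEVELS = 32
DISTANCES = (1, 2, 3)

GLCM_STAT_NAMES = [
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "sum_of_squares",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
]

GEOMETRIC_NAMES = [
    "centroid_offset",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "orientation",
    "convex_area",
    "filled_area",
    "euler_number",
    "equiv_diameter",
    "solidity",
    "extent",
    "perimeter",
    "perimeter_old",
]

FEATURE_NAMES = (
    [f"glcm_d{d}_{s}" for d in DISTANCES for s in GLCM_STAT_NAMES]
    + ["image_entropy"]
    + [f"geom_{n}" for n in GEOMETRIC_NAMES]
    + [f"hu_{i+1}" for i in range(7)]
    + ["intensity_mean", "intensity_variance", "intensity_skewness"]
)
assert len(FEATURE_NAMES) == 72


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple = tuple(FEATURE_NAMES)
    registry_version: str = REGISTRY_VERSION

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (72,):
            raise ValueError("feature vector must have exactly 72 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def quantize(G: np.ndarray, n_levels: int = N_LEVELS) -> np.ndarray:
    """Uniformly quantize G onto integer levels 0..n_levels-1.

    A constant image maps to level 0 everywhere.
    """
    g = np.asarray(G, dtype=float)
    lo, hi = g.min(), g.max()
    if hi == lo:
        return np.zeros(g.shape, dtype=np.uint8)
    q = np.floor((g - lo) / (hi - lo) * n_levels).astype(int)
    return np.clip(q, 0, n_levels - 1).astype(np.uint8)


def glcm_matrix(quantized: np.ndarray, distance: int, n_levels: int = N_LEVELS) -> np.ndarray:
    """Symmetric GLCM summed over the 4 offsets, normalized to sum 1.

    Offsets follow the classic convention — (0, d), (-d, d), (-d, 0)
    and (-d, -d) for 0/45/90/135 degrees — where the diagonal
    displacement at distance d is (d, d), not the rounded
    d*(sin, cos) some implementations use.
    """
    q = quantized.astype(int)
    h, w = q.shape
    counts = np.zeros(n_levels * n_levels, dtype=float)
    for dr, dc in ((0, distance), (-distance, distance),
                   (-distance, 0), (-distance, -distance)):
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        counts += np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
    glcm = counts.reshape(n_levels, n_levels)
    glcm = glcm + glcm.T
    total = glcm.sum()
    return glcm / total if total > 0 else glcm


def glcm_stats_from_matrix(P: np.ndarray) -> dict:
    """The 16 Haralick statistics of one normalized GLCM (1-based indices)."""
    L = P.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    mu_x = float(np.sum(i * px))
    mu_y = mu_x  # symmetric matrix
    var_x = float(np.sum((i - mu_x) ** 2 * px))

    diff = np.abs(I - J)
    summ = I + J

    # p_{x+y}(k), k = 2..2L and p_{x-y}(k), k = 0..L-1
    p_sum = np.zeros(2 * L + 1)
    np.add.at(p_sum, summ.astype(int).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, diff.astype(int).ravel(), P.ravel())

    def ent(p):
        nz = p[p > 0]
        return float(-np.sum(nz * np.log2(nz)))

    if var_x > 0:
        correlation = float(np.sum((I - mu_x) * (J - mu_y) * P)) / var_x
    else:
        correlation = 0.0  # constant-image guard

    ks = np.arange(2 * L + 1, dtype=float)
    sum_average = float(np.sum(ks * p_sum))
    kd = np.arange(L, dtype=float)
    diff_mean = float(np.sum(kd * p_diff))

    return {
        "autocorrelation": float(np.sum(I * J * P)),
        "contrast": float(np.sum((I - J) ** 2 * P)),
        "correlation": correlation,
        "cluster_prominence": float(np.sum((summ - mu_x - mu_y) ** 4 * P)),
        "cluster_shade": float(np.sum((summ - mu_x - mu_y) ** 3 * P)),
        "dissimilarity": float(np.sum(diff * P)),
        "energy": float(np.sum(P ** 2)),
        "entropy": ent(P.ravel()),
        "homogeneity": float(np.sum(P / (1.0 + diff))),
        "maximum_probability": float(P.max()),
        "sum_of_squares": float(np.sum((I - mu_x) ** 2 * P)),
        "sum_average": sum_average,
        "sum_variance": float(np.sum((ks - sum_average) ** 2 * p_sum)),
        "sum_entropy": ent(p_sum),
        "difference_variance": float(np.sum((kd - diff_mean) ** 2 * p_diff)),
        "difference_entropy": ent(p_diff),
    }


def glcm_statistics(G: np.ndarray, n_levels: int = N_LEVELS,
                    distances: tuple = DISTANCES) -> np.ndarray:
    """48 texture values: 16 statistics at each co-occurrence distance."""
    q = quantize(G, n_levels)
    out = []
    for d in distances:
        stats_d = glcm_stats_from_matrix(glcm_matrix(q, d, n_levels))
        out.extend(stats_d[name] for name in GLCM_STAT_NAMES)
    return np.asarray(out)


def image_entropy(G: np.ndarray, n_levels: int = N_LEVELS) -> float:
    """Shannon entropy (bits) of the quantized intensity histogram."""
    q = quantize(G, n_levels)
    counts = np.bincount(q.ravel(), minlength=n_levels).astype(float)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def geometric_features(B: np.ndarray) -> np.ndarray:
    """13 shape scalars of the binary mask (registry order)."""
    b = np.asarray(B).astype(bool)
    if not b.any():
        raise ValueError("empty mask")
    # all foreground treated as one region
    props = regionprops(b.astype(np.uint8))[0]
    cy, cx = props.centroid
    center = ((b.shape[0] - 1) / 2.0, (b.shape[1] - 1) / 2.0)
    centroid_offset = float(np.hypot(cy - center[0], cx - center[1]))
    return np.array([
        centroid_offset,
        props.axis_major_length,
        props.axis_minor_length,
        props.eccentricity,
        props.orientation,
        float(props.area_convex),
        float(props.area_filled),
        float(props.euler_number),
        props.equivalent_diameter_area,
        props.solidity,
        props.extent,
        props.perimeter,
        props.perimeter_crofton,
    ])


def hu_moments(B: np.ndarray) -> np.ndarray:
    """Hu's 7 invariant moments of the mask, signed-log transformed.

    The mask is cropped to its bounding box first, so integer
    translations of the shape give bit-identical results.
    """
    b = np.asarray(B, dtype=float)
    if b.sum() == 0:
        raise ValueError("empty mask")
    rows = np.flatnonzero(b.any(axis=1))
    cols = np.flatnonzero(b.any(axis=0))
    b = b[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    hu = moments_hu(moments_normalized(moments_central(b)))
    out = np.zeros(7)
    nz = hu != 0
    out[nz] = np.sign(hu[nz]) * np.log10(np.abs(hu[nz]))
    return out


def intensity_features(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Mean, population variance and biased Fisher skewness inside the mask."""
    vals = np.asarray(G, dtype=float)[np.asarray(B).astype(bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    if vals.min() == vals.max():  # degenerate: constant interior
        return np.array([float(vals[0]), 0.0, 0.0])
    mean = float(vals.mean())
    var = float(vals.var(ddof=0))
    skew = 0.0 if var == 0 else float(stats.skew(vals, bias=True))
    return np.array([mean, var, skew])


def feature_vector(patch: NodulePatch) -> FeatureVector:
    """Concatenate all feature families in registry order (72 values)."""
    values = np.concatenate([
        glcm_statistics(patch.G),
        [image_entropy(patch.G)],
        geometric_features(patch.B),
        hu_moments(patch.B),
        intensity_features(patch.G, patch.B),
    ])
    return FeatureVector(values=values)


def feature_table(patches: list) -> "pd.DataFrame":
    """Feature matrix for a list of patches (one row per patch)."""
    import pandas as pd

    rows = []
    for p in patches:
        fv = feature_vector(p)
        rows.append({"case_id": p.case_id, "slice": p.slice_index,
                     **dict(zip(fv.names, fv.values))})
    return pd.DataFrame(rows)
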