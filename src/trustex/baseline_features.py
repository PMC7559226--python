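"""Comparison texture descriptors: GLCM, HOG and GLDS.

These are the standard baselines the fused LBP+GMRF descriptor is
benchmarked against.  Conventions are fixed and documented here because
each family admits many variants:

* GLCM — intensities quantized to ``levels`` gray levels, symmetric
  normalized co-occurrence at ``distance`` for angles 0/45/90/135
  degrees; five statistics (contrast, correlation, energy = angular
  second moment, homogeneity, entropy) averaged over angles.
  Correlation of a constant patch is defined as 0.
* HOG — unsigned gradients, 9 orientation bins, 8x8-pixel cells, 2x2
  cell blocks with L2 block normalization (delegated to scikit-image).
* GLDS — gray-level difference statistics of |I(p) - I(p+d)| for the
  four unit offsets; statistics (contrast, angular second moment,
  entropy, mean) of the normalized difference histogram, averaged over
  offsets.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix, hog
from sklearn.base import BaseEstimator, TransformerMixin

from trustex.texture_features import FeatureVector

GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
GLCM_STAT_NAMES = ("contrast", "correlation", "energy", "homogeneity", "entropy")
GLDS_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
GLDS_STAT_NAMES = ("contrast", "asm", "entropy", "mean")


def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError(f"expected uint8 image, got dtype {img.dtype}")
    return ((img.astype(np.int64) * levels) // 256).astype(np.uint8)


def _glcm_stats(p: np.ndarray) -> np.ndarray:
    """Five statistics of one normalized symmetric co-occurrence matrix."""
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(p * (ii - jj) ** 2))
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    var_i = float(np.sum(p * (ii - mu_i) ** 2))
    var_j = float(np.sum(p * (jj - mu_j) ** 2))
    if var_i > 0 and var_j > 0:
        correlation = float(np.sum(p * (ii - mu_i) * (jj - mu_j)) / np.sqrt(var_i * var_j))
    else:
        correlation = 0.0  # constant patch: correlation undefined, defined as 0
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return np.array([contrast, correlation, energy, homogeneity, entropy])


def glcm_features(img: np.ndarray, levels: int = 32, distance: int = 1) -> FeatureVector:
    """Angle-averaged Haralick-style GLCM statistics (5 values)."""
    img = np.asarray(img)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"GLCM needs an image >= 3x3, got {img.shape}")
    q = _quantize(img, levels)
    glcm = graycomatrix(
        q, distances=[distance], angles=list(GLCM_ANGLES), levels=levels,
        symmetric=True, normed=True,
    )
    stats = np.mean([_glcm_stats(glcm[:, :, 0, a]) for a in range(len(GLCM_ANGLES))], axis=0)
    return FeatureVector(values=stats, schema=[f"glcm_{s}" for s in GLCM_STAT_NAMES])


def hog_features(
    img: np.ndarray, cell: int = 8, block: int = 2, bins: int = 9
) -> FeatureVector:
    """Unsigned-gradient HOG descriptor with L2 block normalization."""
    img = np.asarray(img, dtype=np.float64)
    if img.shape[0] < cell * block or img.shape[1] < cell * block:
        raise ValueError(
            f"image {img.shape} smaller than one HOG block ({cell * block}x{cell * block})"
        )
    vec = hog(
        img,
        orientations=bins,
        pixels_per_cell=(cell, cell),
        cells_per_block=(block, block),
        block_norm="L2",
        feature_vector=True,
    )
    return FeatureVector(values=vec, schema=[f"hog_{i}" for i in range(len(vec))])


def glds_features(img: np.ndarray, offsets=GLDS_OFFSETS) -> FeatureVector:
    """Gray-level difference statistics averaged over the given offsets."""
    img = np.asarray(img, dtype=np.int64)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"GLDS needs an image >= 3x3, got {img.shape}")
    h, w = img.shape
    per_offset = []
    for dy, dx in offsets:
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        diff = np.abs(img[y0:y1, x0:x1] - img[y0 + dy : y1 + dy, x0 + dx : x1 + dx])
        hist = np.bincount(diff.ravel(), minlength=256).astype(np.float64)
        p = hist / hist.sum()
        d = np.arange(len(p), dtype=np.float64)
        nz = p[p > 0]
        per_offset.append(
            [
                float(np.sum(p * d**2)),         # contrast
                float(np.sum(p**2)),             # angular second moment
                float(-np.sum(nz * np.log2(nz))),  # entropy
                float(np.sum(p * d)),            # mean
            ]
        )
    stats = np.mean(per_offset, axis=0)
    return FeatureVector(values=stats, schema=[f"glds_{s}" for s in GLDS_STAT_NAMES])


class _PerImageTransformer(BaseEstimator, TransformerMixin):
    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.asarray([self._extract(img).values for img in X])


class GLCMFeatures(_PerImageTransformer):
    def __init__(self, levels: int = 32, distance: int = 1):
        self.levels = levels
        self.distance = distance

    def _extract(self, img):
        return glcm_features(img, levels=self.levels, distance=self.distance)


class HOGFeatures(_PerImageTransformer):
    def __init__(self, cell: int = 8, block: int = 2, bins: int = 9):
        self.cell = cell
        self.block = block
        self.bins = bins

    def _extract(self, img):
        return hog_features(img, cell=self.cell, block=self.block, bins=self.bins)


class GLDSFeatures(_PerImageTransformer):
    def __init__(self):
        pass

    def _extract(self, img):
        return glds_features(img)
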