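"""Optical-density preprocessing for B-mode ultrasound patches.

Ultrasound intensity is dominated by gain and depth-dependent
attenuation; the optical-density (OD) transform

    OD(i, j) = ln( I(i, j) / I_o ),     I_o = mean intensity of the ROI

removes the multiplicative component (a global gain `c` shifts every OD
by 0 since ln(cI / c I_o) = ln(I / I_o)) and expands contrast around the
mean echo level.  The OD values are then affinely remapped to 8-bit for
the downstream texture descriptors: min(OD) -> 0, max(OD) -> 255.

Conventions (the underlying definition fixes neither):

* natural logarithm — any other base only rescales OD and is nullified
  by the affine remap;
* zero intensities are clamped to ``clamp_floor`` (default 1) before the
  log, because ln(0) is undefined; the mean I_o uses the *unclamped*
  values;
* I_o is computed over the patch actually being transformed, not a
  surrounding frame;
* a constant-OD patch remaps to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class ODImage:
    """Real-valued optical densities plus the mean intensity used as I_o."""

    values: np.ndarray
    source_mean: float


def optical_density(img: np.ndarray, clamp_floor: int = 1) -> ODImage:
    """Eq-style OD transform OD = ln(I / I_o) with I_o the patch mean."""
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if clamp_floor < 1:
        raise ValueError(f"clamp_floor must be >= 1, got {clamp_floor}")
    i_o = float(img.mean())
    if i_o <= 0.0:
        raise ValueError("all-zero image: mean intensity is 0, OD transform undefined")
    od = np.log(np.maximum(img, clamp_floor) / i_o)
    return ODImage(values=od, source_mean=i_o)


def od_to_8bit(od: ODImage | np.ndarray) -> np.ndarray:
    """Affine remap of OD values to uint8: min -> 0, max -> 255.

    Rounding is half-to-even.  A constant OD grid maps to all zeros.
    """
    vals = np.asarray(getattr(od, "values", od), dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite optical densities")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.zeros(vals.shape, dtype=np.uint8)
    scaled = (vals - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint8)


def preprocess_image(img: np.ndarray, clamp_floor: int = 1) -> np.ndarray:
    """OD conversion followed by the 8-bit remap (the full preprocessing step)."""
    return od_to_8bit(optical_density(img, clamp_floor=clamp_floor))


class OpticalDensity(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer applying OD + 8-bit remap per image.

    Operates on an iterable of 2-D uint8 arrays and returns a list of
    2-D uint8 arrays, so it can head an image-to-features pipeline.
    """

    def __init__(self, clamp_floor: int = 1):
        self.clamp_floor = clamp_floor

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return [preprocess_image(img, clamp_floor=self.clamp_floor) for img in X]
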