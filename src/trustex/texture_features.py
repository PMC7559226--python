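"""Core texture descriptors: circular LBP and GMRF parameter estimation.

Local binary patterns (LBP)
---------------------------
For each interior pixel, N neighbours are sampled on a circle of radius
R by bilinear interpolation and thresholded against the centre value:

    code = sum_i s(G_i - G_0) * 2**i,    s(t) = 1 if t >= 0 else 0

with neighbour i at angle 2*pi*i/N from the +x axis, counter-clockwise.
Ties (t == 0) count as 1, strictly.  The raw 2**N codes can be collapsed
to a rotation-invariant form:

* ``ri``   — minimum over all N circular bit-rotations of the code
  (each orbit becomes one bin; 36 orbits for N = 8);
* ``riu2`` — uniform rotation-invariant bins: codes with at most two
  0/1 transitions map to their popcount, all others to a single
  miscellaneous bin (N + 2 bins).

Border pixels within the circle radius are dropped rather than padded.

Gaussian Markov random fields (GMRF)
------------------------------------
The patch is modelled as a stationary field in which each pixel's
conditional distribution given its neighbours is Gaussian with mean
linear in symmetric neighbour sums:

    E[x_s | rest] = sum_r theta_r * (x_{s+r} + x_{s-r}),  Var = nu

with symmetric offset pairs (0,1), (1,0) for order 1 plus (1,1), (1,-1)
for order 2.  Because the conditional mean is exactly linear in the
neighbour sums, ordinary least squares over interior pixels of the
standardized (zero-mean, unit-variance) patch is a consistent estimator
of theta; nu is the mean squared residual.  The fitted (theta, nu) are
the texture features: they summarise directional correlation strength
and residual roughness, and are scale-free thanks to standardization.

``gmrf_synthesize`` draws stationary realizations of the same model on
the torus by spectral sampling with power nu / (1 - 2 sum_r theta_r
cos(w.r)); the DC component is fixed at zero (zero-mean convention), so
validity requires positivity of that denominator at every *nonzero*
DFT frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

NEIGHBOR_PAIRS = {
    1: ((0, 1), (1, 0)),
    2: ((0, 1), (1, 0), (1, 1), (1, -1)),
}

MAPPINGS = ("raw", "ri", "riu2")


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-length real feature vector with an ordered name schema."""

    values: np.ndarray
    schema: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "schema", tuple(self.schema))
        if v.ndim != 1 or len(v) != len(self.schema):
            raise ValueError(
                f"feature length {v.shape} does not match schema length {len(self.schema)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LBPCodeImage:
    codes: np.ndarray
    n_points: int
    radius: float
    mapping: str

    @property
    def n_bins(self) -> int:
        return lbp_n_bins(self.n_points, self.mapping)


@dataclass(frozen=True)
class GMRFParams:
    theta: np.ndarray
    nu: float
    order: int

    def as_feature_vector(self, prefix: str = "gmrf") -> FeatureVector:
        names = [f"{prefix}_theta_{dy}{dx:+d}" for dy, dx in NEIGHBOR_PAIRS[self.order]]
        return FeatureVector(
            values=np.append(self.theta, self.nu), schema=names + [f"{prefix}_nu"]
        )


# ----------------------------------------------------------------- LBP


def _circle_offsets(n_points: int, radius: float) -> np.ndarray:
    """(dy, dx) sampling offsets, angle 2*pi*i/N from +x, counter-clockwise.

    Rounded to 9 decimals so symmetric positions (90-degree rotations of
    one another) are represented by bit-identical floats.
    """
    ang = 2.0 * np.pi * np.arange(n_points) / n_points
    # +y is "up" in the mathematical convention; rows grow downward, so dy = -R sin.
    off = np.stack([-radius * np.sin(ang), radius * np.cos(ang)], axis=1)
    return np.round(off, 9)


def _bilinear_plane(img: np.ndarray, dy: float, dx: float, border: int) -> np.ndarray:
    """Values of img sampled at (y+dy, x+dx) for every interior pixel (y, x)."""
    h, w = img.shape
    iy, ix = int(np.floor(dy)), int(np.floor(dx))
    fy, fx = dy - iy, dx - ix

    def block(oy, ox):
        return img[border + oy : h - border + oy, border + ox : w - border + ox]

    if fy == 0.0 and fx == 0.0:
        return block(iy, ix).astype(np.float64)
    # two-stage lerp: exact on constant patches (unlike the 4-product form)
    a, b = block(iy, ix), block(iy, ix + 1)
    c, d = block(iy + 1, ix), block(iy + 1, ix + 1)
    top = a + (b - a) * fx
    bot = c + (d - c) * fx
    return (top + (bot - top) * fy).astype(np.float64)


@lru_cache(maxsize=8)
def _rotation_min_table(n_points: int) -> np.ndarray:
    """code -> minimum over all circular bit-rotations (orbit representative)."""
    if n_points > 16:
        raise ValueError("rotation table supported up to N=16")
    codes = np.arange(2**n_points, dtype=np.int64)
    best = codes.copy()
    mask = 2**n_points - 1
    rot = codes
    for _ in range(n_points - 1):
        rot = ((rot >> 1) | (rot << (n_points - 1))) & mask
        best = np.minimum(best, rot)
    return best


@lru_cache(maxsize=8)
def _riu2_table(n_points: int) -> np.ndarray:
    """code -> uniform-pattern bin: popcount if <=2 transitions, else N+1."""
    codes = np.arange(2**n_points, dtype=np.int64)
    mask = 2**n_points - 1
    rot1 = ((codes >> 1) | (codes << (n_points - 1))) & mask
    transitions = np.array([bin(int(c)).count("1") for c in (codes ^ rot1)])
    popcount = np.array([bin(int(c)).count("1") for c in codes])
    return np.where(transitions <= 2, popcount, n_points + 1).astype(np.int64)


@lru_cache(maxsize=8)
def _ri_bin_index(n_points: int) -> tuple[np.ndarray, int]:
    """Dense bin index for ri orbit representatives; returns (code->bin, n_bins)."""
    table = _rotation_min_table(n_points)
    reps = np.unique(table)
    index = np.full(2**n_points, -1, dtype=np.int64)
    index[reps] = np.arange(len(reps))
    return index[table], len(reps)


def lbp_n_bins(n_points: int, mapping: str) -> int:
    if mapping == "raw":
        return 2**n_points
    if mapping == "ri":
        return _ri_bin_index(n_points)[1]
    if mapping == "riu2":
        return n_points + 2
    raise ValueError(f"unknown LBP mapping {mapping!r}; expected one of {MAPPINGS}")


def lbp_code_image(
    img: np.ndarray, n_points: int = 8, radius: float = 1.0, mapping: str = "ri"
) -> LBPCodeImage:
    """Circular LBP code image (border of ceil(radius) pixels dropped).

    ``mapping='raw'`` keeps the 2**N codes; ``'ri'`` stores the minimal
    circular rotation of each code; ``'riu2'`` stores the uniform-bin
    index (0..N for uniform popcounts, N+1 for the rest).
    """
    if mapping not in MAPPINGS:
        raise ValueError(f"unknown LBP mapping {mapping!r}; expected one of {MAPPINGS}")
    if n_points < 4:
        raise ValueError(f"n_points must be >= 4, got {n_points}")
    img = np.asarray(img, dtype=np.float64)
    border = int(np.ceil(radius))
    h, w = img.shape
    if h <= 2 * border or w <= 2 * border:
        raise ValueError(
            f"image {h}x{w} too small for LBP radius {radius} (needs > {2 * border + 1} per side)"
        )
    center = img[border : h - border, border : w - border]
    codes = np.zeros(center.shape, dtype=np.int64)
    for i, (dy, dx) in enumerate(_circle_offsets(n_points, radius)):
        neighbor = _bilinear_plane(img, dy, dx, border)
        codes |= (neighbor >= center).astype(np.int64) << i
    if mapping == "ri":
        codes = _rotation_min_table(n_points)[codes]
    elif mapping == "riu2":
        codes = _riu2_table(n_points)[codes]
    return LBPCodeImage(codes=codes, n_points=n_points, radius=radius, mapping=mapping)


def lbp_histogram(code_img: LBPCodeImage) -> FeatureVector:
    """Normalized histogram over the mapping's bin range (entries sum to 1)."""
    codes = code_img.codes
    if codes.size == 0:
        raise ValueError("empty LBP code image")
    n, mapping = code_img.n_points, code_img.mapping
    if mapping == "ri":
        bin_of_code, n_bins = _ri_bin_index(n)
        binned = bin_of_code[codes]
        labels = [f"lbp_ri_{r}" for r in np.unique(_rotation_min_table(n))]
    elif mapping == "raw":
        binned, n_bins = codes, 2**n
        labels = [f"lbp_raw_{i}" for i in range(n_bins)]
    else:
        binned, n_bins = codes, n + 2
        labels = [f"lbp_riu2_{i}" for i in range(n_bins)]
    hist = np.bincount(binned.ravel(), minlength=n_bins).astype(np.float64)
    return FeatureVector(values=hist / hist.sum(), schema=labels)


# ---------------------------------------------------------------- GMRF


def _interior_design(x: np.ndarray, pairs) -> tuple[np.ndarray, np.ndarray]:
    h, w = x.shape
    target = x[1:-1, 1:-1].ravel()
    cols = [
        (
            x[1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx]
            + x[1 - dy : h - 1 - dy, 1 - dx : w - 1 - dx]
        ).ravel()
        for dy, dx in pairs
    ]
    return np.stack(cols, axis=1), target


def gmrf_estimate(img: np.ndarray, order: int = 2) -> GMRFParams:
    """Least-squares GMRF coefficients and residual variance of a patch.

    The patch is standardized (zero mean, unit variance) first, making
    theta scale-free and nu comparable across patches.
    """
    if order not in NEIGHBOR_PAIRS:
        raise ValueError(f"order must be 1 or 2, got {order}")
    x = np.asarray(img, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 7 or x.shape[1] < 7:
        raise ValueError(f"GMRF estimation needs a >= 7x7 grid, got {x.shape}")
    sd = x.std()
    if sd == 0.0:
        raise ValueError("constant image: zero variance, GMRF undefined")
    x = (x - x.mean()) / sd
    A, b = _interior_design(x, NEIGHBOR_PAIRS[order])
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ValueError("degenerate texture: singular normal equations")
    theta = np.linalg.solve(gram, A.T @ b)
    resid = b - A @ theta
    return GMRFParams(theta=theta, nu=float(np.mean(resid**2)), order=order)


def gmrf_features(img: np.ndarray, order: int = 2, prefix: str = "gmrf") -> FeatureVector:
    """[theta..., nu] of the fitted GMRF as a named feature vector."""
    return gmrf_estimate(img, order=order).as_feature_vector(prefix=prefix)


def _spectrum_denominator(theta, shape, order) -> np.ndarray:
    h, w = shape
    wy = 2.0 * np.pi * np.fft.fftfreq(h)[:, None]
    wx = 2.0 * np.pi * np.fft.fftfreq(w)[None, :]
    denom = np.ones(shape)
    for t, (dy, dx) in zip(theta, NEIGHBOR_PAIRS[order]):
        denom -= 2.0 * t * np.cos(wy * dy + wx * dx)
    return denom


def gmrf_synthesize(
    theta, nu: float, shape: tuple[int, int], seed=None, order: int | None = None
) -> np.ndarray:
    """Draw a zero-mean stationary GMRF realization by spectral sampling.

    Power at frequency w is nu / (1 - 2 sum_r theta_r cos(w.r)); the DC
    component is set to zero, so the sample mean is exactly 0.  Raises
    if the denominator is non-positive at any nonzero frequency, naming
    the violating frequency.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if order is None:
        order = {2: 1, 4: 2}.get(len(theta))
        if order is None:
            raise ValueError(f"theta length {len(theta)} matches no supported order")
    if nu < 0:
        raise ValueError(f"nu must be >= 0, got {nu}")
    denom = _spectrum_denominator(theta, shape, order)
    nonzero = np.ones(shape, dtype=bool)
    nonzero[0, 0] = False
    if np.any(denom[nonzero] <= 0.0):
        bad = np.argwhere((denom <= 0.0) & nonzero)[0]
        fy = np.fft.fftfreq(shape[0])[bad[0]]
        fx = np.fft.fftfreq(shape[1])[bad[1]]
        raise ValueError(
            f"unstable theta {tuple(theta)}: spectrum denominator "
            f"{denom[bad[0], bad[1]]:.3g} <= 0 at frequency ({fy:.4f}, {fx:.4f}) cycles/px"
        )
    power = np.zeros(shape)
    power[nonzero] = nu / denom[nonzero]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(shape)
    return np.fft.ifft2(np.sqrt(power) * np.fft.fft2(z)).real


# ------------------------------------------------- sklearn transformers


class LBPHistogram(BaseEstimator, TransformerMixin):
    """Images -> matrix of normalized LBP histograms (one row per image)."""

    def __init__(self, n_points: int = 8, radius: float = 1.0, mapping: str = "ri"):
        self.n_points = n_points
        self.radius = radius
        self.mapping = mapping

    def fit(self, X, y=None):
        self.n_features_out_ = lbp_n_bins(self.n_points, self.mapping)
        return self

    def transform(self, X):
        rows = [
            lbp_histogram(
                lbp_code_image(img, self.n_points, self.radius, self.mapping)
            ).values
            for img in X
        ]
        return np.asarray(rows)


class GMRFFeatures(BaseEstimator, TransformerMixin):
    """Images -> matrix of [theta..., nu] GMRF parameter features."""

    def __init__(self, order: int = 2):
        self.order = order

    def fit(self, X, y=None):
        self.n_features_out_ = len(NEIGHBOR_PAIRS[self.order]) + 1
        return self

    def transform(self, X):
        return np.asarray([gmrf_features(img, order=self.order).values for img in X])
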