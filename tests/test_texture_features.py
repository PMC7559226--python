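import numpy as np
import pytest

from trustex import (
    gmrf_estimate,
    gmrf_synthesize,
    lbp_code_image,
    lbp_histogram,
)
from trustex.texture_features import (
    NEIGHBOR_PAIRS,
    _circle_offsets,
    _rotation_min_table,
    lbp_n_bins,
)

# ------------------------------------------------------------- oracles


def lbp_brute_force(img, n_points=8, radius=1.0):
    """Independent per-pixel double-loop LBP with manual bilinear sampling."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    border = int(np.ceil(radius))
    offsets = _circle_offsets(n_points, radius)  # shared sampling-position convention
    out = np.zeros((h - 2 * border, w - 2 * border), dtype=np.int64)
    for y in range(border, h - border):
        for x in range(border, w - border):
            center = img[y, x]
            code = 0
            for i, (dy, dx) in enumerate(offsets):
                sy, sx = y + dy, x + dx
                iy, ix = int(np.floor(sy)), int(np.floor(sx))
                fy, fx = sy - iy, sx - ix
                if fy == 0.0 and fx == 0.0:
                    val = img[iy, ix]
                else:
                    a, b = img[iy, ix], img[iy, ix + 1]
                    c, d = img[iy + 1, ix], img[iy + 1, ix + 1]
                    top = a + (b - a) * fx
                    bot = c + (d - c) * fx
                    val = top + (bot - top) * fy
                if val >= center:
                    code |= 1 << i
            out[y - border, x - border] = code
    return out


def gmrf_normal_equations_oracle(img, order=2):
    """Naive per-pixel accumulation of the least-squares normal equations."""
    x = np.asarray(img, dtype=np.float64)
    x = (x - x.mean()) / x.std()
    pairs = NEIGHBOR_PAIRS[order]
    p = len(pairs)
    ata = np.zeros((p, p))
    atb = np.zeros(p)
    h, w = x.shape
    n = 0
    sq = 0.0
    rows = []
    for yy in range(1, h - 1):
        for xx in range(1, w - 1):
            row = np.array([x[yy + dy, xx + dx] + x[yy - dy, xx - dx] for dy, dx in pairs])
            ata += np.outer(row, row)
            atb += row * x[yy, xx]
            rows.append((row, x[yy, xx]))
            n += 1
    theta = np.linalg.solve(ata, atb)
    nu = sum((t - row @ theta) ** 2 for row, t in rows) / n
    return theta, nu


# ----------------------------------------------------------------- LBP


class TestLBPCodes:
    def test_constant_image_all_ones_code(self):
        img = np.full((10, 10), 7, dtype=np.uint8)
        for mapping in ("raw", "ri"):
            out = lbp_code_image(img, mapping=mapping)
            assert np.all(out.codes == 255)  # s(0) = 1 for every neighbour

    def test_alternating_neighbors_code_85(self):
        # 3x3 patch: the four axial samples are 6 (>= center 5, bits 0/2/4/6),
        # corners chosen so each diagonal bilinear sample is 3.5 (< 5, bits clear)
        img = np.array([[1.17157287525381, 6, 1.17157287525381],
                        [6, 5, 6],
                        [1.17157287525381, 6, 1.17157287525381]])
        out = lbp_code_image(img, mapping="raw")
        assert out.codes.shape == (1, 1)
        assert out.codes[0, 0] == 0b01010101 == 85
        assert lbp_code_image(img, mapping="ri").codes[0, 0] == 85  # min rotation of 01010101

    def test_rotation_orbit_collapse(self):
        table = _rotation_min_table(8)
        assert table[1] == table[16] == 1  # 00000001 and 00010000 share an orbit
        assert lbp_n_bins(8, "ri") == 36
        assert lbp_n_bins(8, "riu2") == 10
        assert lbp_n_bins(8, "raw") == 256

    def test_vectorized_equals_brute_force(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            fast = lbp_code_image(img, mapping="raw").codes
            assert np.array_equal(fast, lbp_brute_force(img))

    def test_brute_force_equivalence_nondefault_geometry(self, rng):
        img = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        fast = lbp_code_image(img, n_points=12, radius=2.0, mapping="raw").codes
        assert np.array_equal(fast, lbp_brute_force(img, n_points=12, radius=2.0))

    def test_affine_intensity_invariance(self, rng):
        img = rng.integers(0, 100, (16, 16)).astype(np.float64)
        a = lbp_code_image(img, mapping="raw").codes
        b = lbp_code_image(2.0 * img + 11.0, mapping="raw").codes
        assert np.array_equal(a, b)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            lbp_code_image(np.zeros((3, 3)), radius=2.0)


class TestLBPHistogram:
    def test_constant_image_single_bin(self):
        codes = lbp_code_image(np.full((10, 10), 3, dtype=np.uint8), mapping="raw")
        hist = lbp_histogram(codes)
        assert hist.values[255] == 1.0
        assert hist.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_normalization(self, rng):
        img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        for mapping in ("raw", "ri", "riu2"):
            hist = lbp_histogram(lbp_code_image(img, mapping=mapping))
            assert hist.values.sum() == pytest.approx(1.0, abs=1e-12)
            assert len(hist) == lbp_n_bins(8, mapping)

    def test_ri_histogram_invariant_under_90deg_rotation(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, (18, 25)).astype(np.uint8)
            h0 = lbp_histogram(lbp_code_image(img, mapping="ri")).values
            for k in (1, 2, 3):
                hk = lbp_histogram(lbp_code_image(np.rot90(img, k), mapping="ri")).values
                assert np.array_equal(h0, hk)


# ---------------------------------------------------------------- GMRF


class TestGMRFEstimate:
    def test_white_noise_theta_near_zero(self):
        rng = np.random.default_rng(42)
        img = rng.standard_normal((128, 128))
        p = gmrf_estimate(img, order=2)
        assert np.all(np.abs(p.theta) < 0.05)
        assert p.nu == pytest.approx(1.0, abs=0.1)

    def test_parameter_recovery(self):
        theta0 = np.array([0.20, 0.20, 0.05, 0.05])
        field = gmrf_synthesize(theta0, 1.0, (256, 256), seed=3)
        p = gmrf_estimate(field, order=2)
        assert np.all(np.abs(p.theta - theta0) < 0.03)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gmrf_estimate(np.full((16, 16), 5.0))

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="7x7"):
            gmrf_estimate(np.random.default_rng(0).standard_normal((6, 9)))

    def test_order1_has_two_coefficients(self, rng):
        p = gmrf_estimate(rng.standard_normal((32, 32)), order=1)
        assert p.theta.shape == (2,)
        fv = p.as_feature_vector()
        assert len(fv) == 3

    def test_matches_naive_normal_equations(self, rng):
        img = rng.standard_normal((12, 12))
        p = gmrf_estimate(img, order=2)
        theta_o, nu_o = gmrf_normal_equations_oracle(img, order=2)
        np.testing.assert_allclose(p.theta, theta_o, atol=1e-8)
        assert p.nu == pytest.approx(nu_o, abs=1e-8)

    def test_bias_shrinks_with_image_size(self):
        theta0 = np.array([0.15, 0.15, 0.02, 0.02])
        errs = {}
        for size in (64, 256):
            e = []
            for seed in range(10):
                f = gmrf_synthesize(theta0, 1.0, (size, size), seed=seed)
                e.append(np.abs(gmrf_estimate(f).theta - theta0).max())
            errs[size] = np.mean(e)
        assert errs[256] < errs[64]


class TestGMRFSynthesize:
    def test_theta_zero_is_white_noise(self):
        f = gmrf_synthesize([0, 0, 0, 0], nu=2.0, shape=(256, 256), seed=0)
        assert f.var() == pytest.approx(2.0, rel=0.1)
        assert abs(f.mean()) < 1e-10  # DC removed: exactly zero-mean

    def test_deterministic_given_seed(self):
        a = gmrf_synthesize([0.1, 0.1, 0, 0], 1.0, (64, 64), seed=5)
        b = gmrf_synthesize([0.1, 0.1, 0, 0], 1.0, (64, 64), seed=5)
        assert np.array_equal(a, b)

    def test_unstable_theta_names_frequency(self):
        with pytest.raises(ValueError, match="frequency"):
            gmrf_synthesize([0.3, 0.3, 0, 0], 1.0, (32, 32))

    def test_autocorrelation_monotone_in_theta(self):
        def lag01_corr(f):
            a, b = f[:, :-1].ravel(), f[:, 1:].ravel()
            return np.corrcoef(a, b)[0, 1]

        corrs = []
        for t in (0.0, 0.1, 0.2):
            vals = [
                lag01_corr(gmrf_synthesize([t, 0.1, 0, 0], 1.0, (128, 128), seed=s))
                for s in range(5)
            ]
            corrs.append(np.mean(vals))
        assert corrs[0] < corrs[1] < corrs[2]
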