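import numpy as np
import pytest

import charmkit as ck
from charmkit.features import (
    HARALICK_ANGLES_DEG,
    HARALICK_STAT_NAMES,
    N_FEATURES,
    assemble_feature_vector,
    chebyshev_fourier_statistics,
    chebyshev_statistics,
    edge_statistics,
    feature_names,
    gabor_features,
    haralick_features,
    moments,
    multiscale_histograms,
    pixel_statistics,
    quantize_gray,
    tamura_features,
)
from charmkit.io import RawImage
from charmkit.synthetic import ClassSpec
from charmkit.synthetic import make_class_image


class TestPixelStatistics:
    def test_constant_image_degenerate_distribution(self):
        s = pixel_statistics(np.full((8, 8), 0.5))
        mean, mx, var, pmin, pmax = s[0], s[1], s[2], s[3], s[4]
        assert (mean, mx, var) == (0.5, 0.5, 0.0)
        assert pmin == 1.0 and pmax == 1.0

    def test_hand_computed_two_valued_image(self):
        # 3 pixels at 0, 1 pixel at 1; Otsu separates the two values
        M = np.array([[0.0, 0.0], [0.0, 1.0]])
        s = pixel_statistics(M)
        assert s[0] == pytest.approx(0.25)      # mean
        assert s[1] == 1.0                      # max
        assert s[5] == pytest.approx(1.0)       # total intensity
        assert s[14] == 1.0                     # pixels above Otsu threshold

    def test_linear_ramp_symmetry(self):
        v = np.linspace(0, 1, 256).reshape(16, 16)
        s = pixel_statistics(v)
        assert s[6] == pytest.approx(s[0], abs=1e-2)   # median ~ mean
        assert abs(s[9]) < 1e-10                        # skewness ~ 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            pixel_statistics(np.zeros((0, 0)))


class TestMoments:
    def test_constant_image_convention(self):
        assert np.allclose(moments(np.full((8, 8), 0.3)), [0.3, 0, 0, 0])

    def test_symmetric_two_point_distribution(self):
        M = np.concatenate([np.zeros(32), np.ones(32)]).reshape(8, 8)
        m = moments(M)
        assert m[0] == pytest.approx(0.5)
        assert m[1] == pytest.approx(0.25)
        assert m[2] == pytest.approx(0.0, abs=1e-12)
        assert m[3] == pytest.approx(-2.0)

    def test_permutation_invariance(self, rng):
        M = rng.random((16, 16))
        assert np.allclose(moments(M), moments(M[::-1, ::-1]))


class TestMultiscaleHistograms:
    def test_constant_zero_image_fills_first_bins(self):
        h = multiscale_histograms(np.zeros((8, 8)))
        offsets = np.cumsum([0, 3, 5, 7])
        for off in offsets:
            assert h[off] == 1.0

    def test_each_histogram_sums_to_one(self, rng):
        h = multiscale_histograms(rng.random((16, 16)))
        start = 0
        for nbins in (3, 5, 7, 9):
            assert h[start:start + nbins].sum() == pytest.approx(1.0, abs=1e-12)
            start += nbins

    def test_uniform_ramp_is_flat(self):
        M = np.linspace(0, 1 - 1e-9, 4096).reshape(64, 64)
        h = multiscale_histograms(M)
        start = 0
        for nbins in (3, 5, 7, 9):
            assert np.allclose(h[start:start + nbins], 1 / nbins, atol=1 / 4096 + 1e-9)
            start += nbins


class TestEdgeStatistics:
    def test_constant_image_has_no_edges(self):
        assert np.allclose(edge_statistics(np.full((16, 16), 0.4)), 0.0)

    def test_step_edge_pixels_confined_to_strip(self):
        M = np.zeros((16, 16))
        j = 8
        M[:, j:] = 1.0
        e = edge_statistics(M)
        assert e[3] > 0
        # gradient is confined to columns j-1..j: recompute support directly
        from scipy import ndimage

        G = np.hypot(
            ndimage.sobel(M, axis=1, mode="reflect"),
            ndimage.sobel(M, axis=0, mode="reflect"),
        )
        cols = np.unique(np.argwhere(G > 0)[:, 1])
        assert set(cols.tolist()) <= {j - 1, j, j + 1}

    def test_transpose_leaves_magnitude_statistics_unchanged(self, rng):
        M = rng.random((16, 16))
        a, b = edge_statistics(M), edge_statistics(M.T)
        assert np.allclose(a[:3], b[:3])


class TestGaborFeatures:
    def test_constant_image_rejected_by_bandpass(self):
        g = gabor_features(np.full((32, 32), 0.5))
        assert g[0] < 0.01 and g[1] < 1e-4

    def test_stripes_more_anisotropic_than_noise(self):
        aniso_noise = []
        for seed in range(10):
            noise = np.random.default_rng(seed).random((32, 32))
            aniso_noise.append(gabor_features(noise)[1])
        x = np.arange(32)
        stripes = np.tile(0.5 + 0.5 * np.cos(2 * np.pi * 0.25 * x), (32, 1))
        assert gabor_features(stripes)[1] > max(aniso_noise)

    def test_90_degree_rotation_invariance(self, rng):
        M = rng.random((32, 32))
        assert np.allclose(gabor_features(M), gabor_features(np.rot90(M)), atol=1e-8)


def glcm_pair_oracle(q, dr, dc, levels):
    """Brute-force symmetric co-occurrence counts for one offset."""
    h, w = q.shape
    C = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                C[q[r, c], q[r2, c2]] += 1
                C[q[r2, c2], q[r, c]] += 1
    return C / C.sum()


def haralick_oracle_stats(P):
    """The 13 statistics computed directly from their definitions."""
    G = P.shape[0]
    idx = np.arange(G)
    i, j = np.meshgrid(idx, idx, indexing="ij")
    px, py = P.sum(1), P.sum(0)
    mux, muy = (idx * px).sum(), (idx * py).sum()
    sx = np.sqrt(((idx - mux) ** 2 * px).sum())
    sy = np.sqrt(((idx - muy) ** 2 * py).sum())

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    psum = np.array([P[i + j == k].sum() for k in range(2 * G - 1)])
    pdiff = np.array([P[np.abs(i - j) == k].sum() for k in range(G)])
    sa = (np.arange(2 * G - 1) * psum).sum()
    dm = (np.arange(G) * pdiff).sum()
    hxy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    pxpy = np.outer(px, py)
    mask = pxpy > 0
    hxy1 = float(-(P[mask] * np.log(pxpy[mask])).sum())
    hxy2 = ent(pxpy.ravel())
    return np.array(
        [
            (P**2).sum(),
            (((i - j) ** 2) * P).sum(),
            ((i * j * P).sum() - mux * muy) / (sx * sy) if sx * sy > 0 else 0.0,
            (((i - mux) ** 2) * P).sum(),
            (P / (1 + (i - j) ** 2)).sum(),
            sa,
            ((np.arange(2 * G - 1) - sa) ** 2 * psum).sum(),
            ent(psum),
            hxy,
            ((np.arange(G) - dm) ** 2 * pdiff).sum(),
            ent(pdiff),
            (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
            np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy)))),
        ]
    )


# skimage's angle convention: offset = (round(d sin a), round(d cos a))
ANGLE_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


class TestHaralickFeatures:
    def test_constant_image_has_unit_asm_zero_contrast(self):
        f = haralick_features(np.full((8, 8), 0.5))
        for block in range(8):
            stats = f[block * 13:(block + 1) * 13]
            assert stats[0] == pytest.approx(1.0)   # angular second moment
            assert stats[1] == 0.0                  # contrast

    def test_matches_pair_enumeration_oracle(self, rng):
        M = rng.integers(0, 8, (6, 6)).astype(np.float64) / 8 + 1 / 16
        f = haralick_features(M)
        q = quantize_gray(M)
        for d_i, d in enumerate((1, 2)):
            for a_i, a in enumerate(HARALICK_ANGLES_DEG):
                dr, dc = ANGLE_OFFSETS[a]
                P = glcm_pair_oracle(q, d * dr, d * dc, 8)
                expect = haralick_oracle_stats(P)
                block = f[(d_i * 4 + a_i) * 13:(d_i * 4 + a_i + 1) * 13]
                assert np.allclose(block, expect, atol=1e-10)

    def test_transpose_swaps_0_and_90_degree_blocks(self, rng):
        M = rng.random((12, 12))
        f, ft = haralick_features(M), haralick_features(M.T)
        for d_i in range(2):
            b0 = slice((d_i * 4 + 0) * 13, (d_i * 4 + 1) * 13)
            b90 = slice((d_i * 4 + 2) * 13, (d_i * 4 + 3) * 13)
            assert np.allclose(f[b0], ft[b90], atol=1e-12)
            assert np.allclose(f[b90], ft[b0], atol=1e-12)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            haralick_features(np.zeros((2, 2)))


class TestTamuraFeatures:
    def test_constant_image_conventions(self):
        t = tamura_features(np.full((32, 32), 0.5))
        assert t[0] == 0.0                       # contrast 0/0 -> 0
        assert np.count_nonzero(t[3:6]) == 1     # coarseness hist degenerate
        assert t[3] == 1.0

    def test_coarser_checkerboard_scores_higher(self):
        y, x = np.mgrid[0:64, 0:64]
        fine = ((x // 1 + y // 1) % 2).astype(float)
        coarse = ((x // 8 + y // 8) % 2).astype(float)
        assert tamura_features(coarse)[1] > tamura_features(fine)[1]

    def test_stripes_more_directional_than_noise(self):
        x = np.arange(64)
        stripes = np.tile((x // 4 % 2).astype(float), (64, 1))
        d_stripes = tamura_features(stripes)[2]
        for seed in range(10):
            noise = np.random.default_rng(seed).random((64, 64))
            assert d_stripes > tamura_features(noise)[2]


class TestChebyshevStatistics:
    @pytest.mark.parametrize("fn", [chebyshev_statistics, chebyshev_fourier_statistics])
    def test_histogram_sums_to_one(self, fn, rng):
        assert fn(rng.random((32, 32))).sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_concentrates(self):
        h = chebyshev_statistics(np.full((32, 32), 0.5))
        # 399 of 400 coefficients are ~0, one is the DC extreme
        assert h[0] == pytest.approx(399 / 400)
        assert h[-1] == pytest.approx(1 / 400)

    def test_constant_image_chebyshev_fourier_flat_spectrum(self):
        h = chebyshev_fourier_statistics(np.full((32, 32), 0.5))
        # spectrum of a single-spike coefficient matrix is flat -> one bin
        assert h.max() == pytest.approx(1.0)

    def test_matches_independent_binning_oracle(self, rng):
        from charmkit.transforms import chebyshev_transform

        M = rng.random((32, 32))
        C = chebyshev_transform(M)
        r = (C - C.min()) / (C.max() - C.min())
        counts, _ = np.histogram(r.ravel(), bins=32, range=(0, 1))
        assert np.allclose(chebyshev_statistics(M), counts / 400)

        FM = np.abs(np.fft.fft2(C))
        r = (FM - FM.min()) / (FM.max() - FM.min())
        counts, _ = np.histogram(r.ravel(), bins=32, range=(0, 1))
        assert np.allclose(chebyshev_fourier_statistics(M), counts / 400)


@pytest.fixture(scope="module")
def img():
    return make_class_image(
        ClassSpec("s", kind="stripes", scale=8, contrast=0.5),
        seed=1, size=64, noise_sd=0.05,
    )


class TestAssembly:

    def test_vector_has_953_elements(self, img):
        fv = assemble_feature_vector(img)
        assert fv.values.size == N_FEATURES == 953
        assert len(set(fv.names)) == 953

    def test_extraction_is_deterministic(self, img):
        a = assemble_feature_vector(img)
        b = assemble_feature_vector(img)
        assert np.array_equal(a.values, b.values)

    def test_two_channel_sample_concatenates(self, img, rng):
        img2 = RawImage(pixels=rng.random((64, 64)), channel_id="ch1",
                        sample_id=img.sample_id)
        fm = ck.feature_matrix({"s0": [img, img2]})
        assert fm.X.shape == (1, 1906)
        assert fm.X.columns[0].startswith("ch0:")
        assert fm.X.columns[-1].startswith("ch1:")

    def test_histogram_blocks_sum_to_one(self, img):
        fv = assemble_feature_vector(img)
        by_name = dict(zip(fv.names, fv.values))
        for level in ("IM", "W", "C", "F", "WF", "CF"):
            for nbins in (3, 5, 7, 9):
                s = sum(by_name[f"mshist.h{nbins}_b{b}@{level}"] for b in range(nbins))
                assert s == pytest.approx(1.0, abs=1e-12)
        assert sum(by_name[f"chebstat.b{b}@IM"] for b in range(32)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_group_ablation_accounting(self, img):
        # dropping a starred group removes 6 x group size features
        for group, size in [("gabor", 2), ("moments", 4), ("tamura", 6)]:
            fv = assemble_feature_vector(img, exclude_groups=(group,))
            assert fv.values.size == 953 - 6 * size

    def test_feature_name_layout_is_stable(self):
        names = feature_names()
        assert names[0] == "pixstat.mean@IM"
        assert names[146] == "pixstat.mean@W"
        assert names[-1] == "chebfourier.b31@IM"
        assert names.count("gabor.energy@CF") == 1
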