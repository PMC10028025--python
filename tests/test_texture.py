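"""Texture banks against brute-force oracles, plus structural contracts."""

import numpy as np
import pytest

from brushcyto import texture as tx
from brushcyto.texture import (
    HARALICK_NAMES,
    LAWS_VECTORS,
    TextureConfig,
    collage_maps,
    dominant_orientations,
    five_statistics,
    gabor_bank,
    haralick_maps,
    laws_bank,
    laws_kernels,
    quantize,
    response_maps,
    summarize,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def glcm_stats_oracle(q, window, n_levels):
    """Brute-force windowed co-occurrence statistics.

    Enumerates every ordered pixel pair (4 offsets, symmetric) whose
    endpoints both fall inside the clipped window, normalizes to a joint
    probability table, and evaluates the 13 statistics from their general
    definitions (HXY1/HXY2 from the raw marginals, no symmetry shortcuts).
    """
    H, W = q.shape
    half = window // 2
    offs = [(0, 1), (1, 0), (1, 1), (1, -1)]
    out = np.zeros((13, H, W))
    for y in range(H):
        for x in range(W):
            y0, y1 = max(y - half, 0), min(y + half, H - 1)
            x0, x1 = max(x - half, 0), min(x + half, W - 1)
            counts = {}
            for dy, dx in offs:
                for wy in range(y0, y1 + 1):
                    for wx in range(x0, x1 + 1):
                        ny, nx = wy + dy, wx + dx
                        if y0 <= ny <= y1 and x0 <= nx <= x1:
                            a, b = int(q[wy, wx]), int(q[ny, nx])
                            counts[(a, b)] = counts.get((a, b), 0) + 1
                            counts[(b, a)] = counts.get((b, a), 0) + 1
            total = sum(counts.values())
            if total == 0:
                continue
            p = {k: v / total for k, v in counts.items()}
            px = np.zeros(n_levels)
            py = np.zeros(n_levels)
            for (a, b), v in p.items():
                px[a] += v
                py[b] += v
            psum = np.zeros(2 * n_levels - 1)
            pdiff = np.zeros(n_levels)
            for (a, b), v in p.items():
                psum[a + b] += v
                pdiff[abs(a - b)] += v
            energy = sum(v * v for v in p.values())
            contrast = sum(v * (a - b) ** 2 for (a, b), v in p.items())
            mux = float(sum(i * px[i] for i in range(n_levels)))
            muy = float(sum(i * py[i] for i in range(n_levels)))
            sx = np.sqrt(sum((i - mux) ** 2 * px[i] for i in range(n_levels)))
            sy = np.sqrt(sum((i - muy) ** 2 * py[i] for i in range(n_levels)))
            if sx * sy > 1e-12:
                corr = (sum(a * b * v for (a, b), v in p.items())
                        - mux * muy) / (sx * sy)
            else:
                corr = 0.0
            var = sum((a - mux) ** 2 * v for (a, b), v in p.items())
            idm = sum(v / (1 + (a - b) ** 2) for (a, b), v in p.items())
            sum_avg = float(sum(k * psum[k] for k in range(len(psum))))
            sum_var = float(sum((k - sum_avg) ** 2 * psum[k]
                                for k in range(len(psum))))
            sum_ent = -float(sum(v * np.log(v) for v in psum if v > 0))
            entropy = -sum(v * np.log(v) for v in p.values())
            mud = float(sum(k * pdiff[k] for k in range(n_levels)))
            diff_var = float(sum((k - mud) ** 2 * pdiff[k]
                                 for k in range(n_levels)))
            diff_ent = -float(sum(v * np.log(v) for v in pdiff if v > 0))
            hx = -float(sum(v * np.log(v) for v in px if v > 0))
            hy = -float(sum(v * np.log(v) for v in py if v > 0))
            hxy1 = -sum(v * np.log(px[a] * py[b])
                        for (a, b), v in p.items() if px[a] * py[b] > 0)
            hxy2 = -float(sum(
                px[i] * py[j] * np.log(px[i] * py[j])
                for i in range(n_levels) for j in range(n_levels)
                if px[i] * py[j] > 0
            ))
            imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 1e-12 else 0
            imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - entropy))))
            out[:, y, x] = (energy, contrast, corr, var, idm, sum_avg,
                            sum_var, sum_ent, entropy, diff_var, diff_ent,
                            imc1, imc2)
    return out


def svd_orientation_oracle(image, window):
    """Dominant gradient orientation by explicit per-window SVD."""
    gy, gx = np.gradient(np.asarray(image, float))
    H, W = image.shape
    half = window // 2
    theta = np.full((H, W), np.nan)
    for y in range(half, H - half):
        for x in range(half, W - half):
            G = np.stack(
                [gx[y - half:y + half + 1, x - half:x + half + 1].ravel(),
                 gy[y - half:y + half + 1, x - half:x + half + 1].ravel()],
                axis=1,
            )
            if np.allclose(G, 0):
                theta[y, x] = 0.0
                continue
            _, _, vt = np.linalg.svd(G, full_matrices=False)
            vx, vy = vt[0]
            theta[y, x] = np.mod(np.arctan2(vy, vx), np.pi)
    return theta


def dense_correlate_oracle(image, kernel):
    """Direct sliding dot product with symmetric (reflect) padding."""
    kh, kw = kernel.shape
    pad = np.pad(image, ((kh // 2,), (kw // 2,)), mode="symmetric")
    H, W = image.shape
    out = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            out[y, x] = float(
                (pad[y:y + kh, x:x + kw] * kernel).sum()
            )
    return out


# ---------------------------------------------------------------------------
# Haralick
# ---------------------------------------------------------------------------

class TestHaralick:
    def test_constant_image(self):
        img = np.full((12, 12), 5.0)
        maps = haralick_maps(img, np.ones((12, 12), bool))
        by_name = {m.descriptor_name: m.values for m in maps}
        assert np.allclose(by_name["contrast"], 0.0)
        assert np.allclose(by_name["energy"], 1.0)

    def test_checkerboard_matches_bruteforce(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 10.0
        fg = np.ones((8, 8), bool)
        cfg = TextureConfig()
        maps = haralick_maps(img, fg, cfg)
        q = quantize(img, fg, cfg.gray_levels)
        oracle = glcm_stats_oracle(q, cfg.haralick_window, cfg.gray_levels)
        for i, m in enumerate(maps):
            assert np.max(np.abs(m.values - oracle[i])) <= 1e-10, \
                m.descriptor_name

    def test_random_image_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(9, 9)) * 30
        fg = np.ones((9, 9), bool)
        cfg = TextureConfig(gray_levels=8)
        maps = haralick_maps(img, fg, cfg)
        q = quantize(img, fg, 8)
        oracle = glcm_stats_oracle(q, 5, 8)
        for i, m in enumerate(maps):
            assert np.max(np.abs(m.values - oracle[i])) <= 1e-10

    def test_thirteen_maps(self):
        img = np.zeros((8, 8))
        assert len(haralick_maps(img, np.ones((8, 8), bool))) == 13


# ---------------------------------------------------------------------------
# CoLlAGe
# ---------------------------------------------------------------------------

class TestCollage:
    def test_ramp_has_constant_orientation(self):
        img = np.tile(np.arange(20, dtype=float), (20, 1))  # d/dx only
        theta = dominant_orientations(img, window=5)
        interior = theta[3:-3, 3:-3]
        assert np.allclose(interior, interior[0, 0])
        maps = collage_maps(img, np.ones((20, 20), bool))
        ent = {m.descriptor_name: m.values for m in maps}["entropy"]
        assert np.allclose(ent[4:-4, 4:-4], 0.0, atol=1e-12)

    def test_orientations_match_svd_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.normal(size=(9, 9)) * 20
        theta = dominant_orientations(img, window=5)
        oracle = svd_orientation_oracle(img, 5)
        sel = ~np.isnan(oracle)
        d = np.abs(theta[sel] - oracle[sel])
        d = np.minimum(d, np.pi - d)  # orientations live mod pi
        assert d.max() <= 1e-8

    def test_thirteen_maps(self):
        img = np.random.default_rng(0).normal(size=(10, 10))
        assert len(collage_maps(img, np.ones((10, 10), bool))) == 13


# ---------------------------------------------------------------------------
# Gabor
# ---------------------------------------------------------------------------

class TestGabor:
    def test_zero_image_zero_response(self):
        maps = gabor_bank(np.zeros((32, 32)))
        assert len(maps) == 48
        for m in maps:
            assert np.allclose(m.values, 0.0, atol=1e-10)

    def test_grating_maximizes_matching_filter(self):
        cfg = TextureConfig()
        f = cfg.gabor_frequencies[2]
        t = cfg.gabor_orientations[2]  # 45 degrees
        yy, xx = np.mgrid[:64, :64].astype(float)
        grating = np.cos(2 * np.pi * f * (xx * np.cos(t) + yy * np.sin(t)))
        maps = gabor_bank(grating, cfg)
        means = [m.values[8:-8, 8:-8].mean() for m in maps]
        best = maps[int(np.argmax(means))]
        deg = int(round(np.degrees(t)))
        assert best.descriptor_name == f"f{f:.3f}_t{deg:03d}"

    def test_rotating_image_permutes_orientations(self):
        cfg = TextureConfig()
        f = cfg.gabor_frequencies[3]
        t = cfg.gabor_orientations[1]
        yy, xx = np.mgrid[:64, :64].astype(float)
        grating = np.cos(2 * np.pi * f * (xx * np.cos(t) + yy * np.sin(t)))
        rotated = np.rot90(grating)
        means = [m.values[8:-8, 8:-8].mean() for m in gabor_bank(rotated, cfg)]
        best = np.argmax(means)
        # rotating the input by 90 deg moves the peak to theta + 90 (mod 180)
        expect_t = np.mod(t + np.pi / 2, np.pi)
        i_f, i_t = divmod(int(best), len(cfg.gabor_orientations))
        assert np.isclose(cfg.gabor_frequencies[i_f], f)
        assert np.isclose(cfg.gabor_orientations[i_t], expect_t)

    def test_frequency_above_nyquist_rejected(self):
        cfg = TextureConfig(gabor_frequencies=(0.1,) * 5 + (0.6,))
        with pytest.raises(ValueError):
            gabor_bank(np.zeros((16, 16)), cfg)


# ---------------------------------------------------------------------------
# Law's
# ---------------------------------------------------------------------------

class TestLaws:
    def test_kernel_outer_product_identity(self):
        kerns = laws_kernels()
        L5, E5 = LAWS_VECTORS["L5"], LAWS_VECTORS["E5"]
        for i in range(5):
            for j in range(5):
                assert kerns["L5E5"][i, j] == L5[i] * E5[j]

    def test_constant_image_zero_unless_L5L5(self):
        img = np.full((16, 16), 7.0)
        for m in laws_bank(img):
            if m.descriptor_name == "L5L5":
                assert np.allclose(m.values, 7.0 * 256)
            else:
                assert np.allclose(m.values, 0.0, atol=1e-9)

    def test_matches_dense_convolution_oracle(self):
        rng = np.random.default_rng(6)
        img = rng.normal(size=(7, 7)) * 10
        kerns = laws_kernels()
        for m in laws_bank(img):
            oracle = dense_correlate_oracle(img, kerns[m.descriptor_name])
            assert np.allclose(m.values, oracle, atol=1e-9)

    def test_twentyfive_maps(self):
        assert len(laws_bank(np.zeros((8, 8)))) == 25


# ---------------------------------------------------------------------------
# summarization and global contracts
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_hand_arithmetic(self):
        stats = five_statistics(np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.isclose(stats[0], 2.5)
        assert np.isclose(stats[1], 2.5)
        assert np.isclose(stats[2], np.sqrt(1.25))  # population sd
        assert np.isclose(stats[3], 0.0)

    def test_constant_map_convention(self):
        from brushcyto.texture import ResponseMap

        m = ResponseMap(np.full((5, 5), 3.0), "laws", "L5L5")
        with pytest.warns(UserWarning):
            vec = summarize([m], np.ones((5, 5), bool))
        s = dict(zip(vec.names, vec.values))
        assert s["laws.L5L5.mean"] == 3.0
        assert s["laws.L5L5.std"] == 0.0
        assert s["laws.L5L5.skewness"] == 0.0
        assert s["laws.L5L5.kurtosis"] == 0.0

    def test_gaussian_kurtosis_near_three(self):
        rng = np.random.default_rng(8)
        stats = five_statistics(rng.normal(size=200_000))
        assert abs(stats[4] - 3.0) < 0.05

    def test_too_few_pixels_rejected(self):
        from brushcyto.texture import ResponseMap

        m = ResponseMap(np.ones((2, 2)), "laws", "L5L5")
        fg = np.zeros((2, 2), bool)
        fg[0, 0] = True
        with pytest.raises(ValueError):
            summarize([m], fg)

    def test_full_bank_yields_495(self):
        rng = np.random.default_rng(9)
        img = rng.normal(size=(24, 24)) * 20
        fg = np.ones((24, 24), bool)
        maps = response_maps(img, fg)
        assert len(maps) == 99
        vec = summarize(maps, fg)
        assert len(vec) == 495
        assert len(set(vec.names)) == 495  # naming is bijective


class TestInvariances:
    def test_rotation_90_preserves_haralick_summaries(self):
        rng = np.random.default_rng(10)
        img = rng.normal(size=(24, 24)) * 20
        fg = np.ones((24, 24), bool)
        a = summarize(haralick_maps(img, fg), fg)
        b = summarize(haralick_maps(np.rot90(img), np.rot90(fg)), np.rot90(fg))
        rel = np.abs(a.values - b.values) / np.maximum(np.abs(a.values), 1e-6)
        assert rel.max() <= 0.01

    def test_translation_equivariance(self):
        rng = np.random.default_rng(11)
        pattern = rng.normal(size=(10, 10)) * 15
        big1 = np.zeros((30, 30))
        big2 = np.zeros((30, 30))
        big1[5:15, 5:15] = pattern
        big2[12:22, 9:19] = pattern
        fg = np.ones((30, 30), bool)
        m1 = haralick_maps(big1, fg)[1].values  # contrast
        m2 = haralick_maps(big2, fg)[1].values
        # compare matching interiors of the embedded pattern
        assert np.allclose(m1[8:12, 8:12], m2[15:19, 12:16], atol=1e-10)

    def test_extraction_is_deterministic(self, preprocessed_benign):
        from brushcyto.texture import texture_features

        a = texture_features(preprocessed_benign)
        b = texture_features(preprocessed_benign)
        assert np.array_equal(a.values, b.values)


def test_config_validation():
    with pytest.raises(ValueError):
        TextureConfig(gabor_frequencies=(0.1, 0.2)).validate()
    with pytest.raises(ValueError):
        TextureConfig(haralick_window=4).validate()
    bad_laws = dict(LAWS_VECTORS)
    bad_laws["E5"] = np.array([1.0, 1, 1, 1, 1])
    with pytest.raises(ValueError):
        TextureConfig(laws_vectors=bad_laws).validate()
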