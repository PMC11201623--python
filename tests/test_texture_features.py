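"""Texture banks: counts, analytic responses, and brute-force co-occurrence
oracles."""

import math
from itertools import product

import numpy as np
import pytest

from mbrisk.synthetic_data import make_sphere_mask, make_textured_region
from mbrisk.texture_features import (
    DEFAULT_TEXTURE_CONFIG,
    GRADIENT_NAMES,
    HARALICK_STAT_NAMES,
    LAWS_KERNELS,
    STAT_NAMES,
    TextureBankConfig,
    aggregate_stats,
    compute_collage_maps,
    compute_gabor_maps,
    compute_gradient_maps,
    compute_haralick_maps,
    compute_laws_maps,
    extract_texture_vector,
)


# ---------------------------------------------------------------------------
# independent brute-force co-occurrence oracle
# ---------------------------------------------------------------------------

def brute_force_glcm_stats(levels, n_levels, offsets):
    """Haralick statistics from explicit pair enumeration over a full patch.

    Written independently of the production kernel: dict-of-pairs counting
    and direct sums over the normalized matrix.
    """
    counts = {}
    shape = levels.shape
    for pos in product(*[range(s) for s in shape]):
        for off in offsets:
            nb = tuple(p + o for p, o in zip(pos, off))
            if all(0 <= c < s for c, s in zip(nb, shape)):
                a, b = int(levels[pos]), int(levels[nb])
                counts[(a, b)] = counts.get((a, b), 0) + 1
                counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}

    def log2(x):
        return math.log(x, 2)

    px = [sum(p.get((i, j), 0.0) for j in range(n_levels)) for i in range(n_levels)]
    psum = [sum(p.get((i, j), 0.0) for i in range(n_levels)
                for j in range(n_levels) if i + j == k)
            for k in range(2 * n_levels - 1)]
    pdiff = [sum(p.get((i, j), 0.0) for i in range(n_levels)
                 for j in range(n_levels) if abs(i - j) == k)
             for k in range(n_levels)]

    energy = sum(v * v for v in p.values())
    contrast = sum((i - j) ** 2 * v for (i, j), v in p.items())
    mu = sum(i * px[i] for i in range(n_levels))
    var = sum((i - mu) ** 2 * px[i] for i in range(n_levels))
    corr_num = sum(i * j * v for (i, j), v in p.items()) - mu * mu
    correlation = corr_num / var if var > 1e-12 else 0.0
    idm = sum(v / (1.0 + (i - j) ** 2) for (i, j), v in p.items())
    sum_avg = sum(k * q for k, q in enumerate(psum))
    sum_var = sum((k - sum_avg) ** 2 * q for k, q in enumerate(psum))
    sum_ent = -sum(q * log2(q) for q in psum if q > 0)
    entropy = -sum(v * log2(v) for v in p.values() if v > 0)
    diff_avg = sum(k * q for k, q in enumerate(pdiff))
    diff_var = sum((k - diff_avg) ** 2 * q for k, q in enumerate(pdiff))
    diff_ent = -sum(q * log2(q) for q in pdiff if q > 0)
    hx = -sum(q * log2(q) for q in px if q > 0)
    hxy1 = -sum(v * log2(px[i] * px[j]) for (i, j), v in p.items()
                if px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * log2(px[i] * px[j])
                for i in range(n_levels) for j in range(n_levels)
                if px[i] * px[j] > 0)
    imc1 = (entropy - hxy1) / hx if hx > 1e-12 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - entropy))
    imc2 = math.sqrt(arg) if arg > 0 else 0.0
    return {
        "energy": energy, "contrast": contrast, "correlation": correlation,
        "variance": var, "inverse_difference_moment": idm,
        "sum_average": sum_avg, "sum_variance": sum_var,
        "sum_entropy": sum_ent, "entropy": entropy,
        "difference_variance": diff_var, "difference_entropy": diff_ent,
        "imc1": imc1, "imc2": imc2,
    }


class TestBankEnumeration:
    def test_family_sizes_and_total(self):
        names = DEFAULT_TEXTURE_CONFIG.family_feature_names()
        assert {k: len(v) for k, v in names.items()} == {
            "gradient": 13, "haralick": 13, "laws": 125, "gabor": 50,
            "collage": 13}
        assert DEFAULT_TEXTURE_CONFIG.n_definitions == 214

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            TextureBankConfig(haralick_window=4)


class TestGradientMaps:
    def test_constant_volume(self):
        m = make_sphere_mask(6, (12, 12, 12), (24, 24, 24))
        maps = compute_gradient_maps(np.full((24, 24, 24), 7.0), m)
        assert list(maps) == list(GRADIENT_NAMES)
        for name in ("dx", "dy", "dz", "gradient_magnitude", "laplacian",
                     "local_std", "local_range", "directional_max",
                     "sobel_x", "sobel_y", "sobel_z", "sobel_magnitude"):
            assert np.allclose(maps[name], 0.0), name
        assert np.allclose(maps["local_mean"], 7.0)

    def test_x_ramp_has_unit_gradient(self):
        vol = np.indices((24, 24, 24))[0].astype(float)
        inner = make_sphere_mask(4, (12, 12, 12), (24, 24, 24))
        maps = compute_gradient_maps(vol, inner)
        assert np.allclose(maps["dx"], 1.0)
        assert np.allclose(maps["dy"], 0.0)
        assert np.allclose(maps["dz"], 0.0)
        assert np.allclose(maps["gradient_magnitude"], 1.0)


class TestHaralickMaps:
    def test_constant_region_degenerate_glcm(self):
        m = make_sphere_mask(5, (8, 8, 8), (16, 16, 16))
        maps = compute_haralick_maps(np.full((16, 16, 16), 3.0), m)
        assert np.allclose(maps["energy"], 1.0)
        assert np.allclose(maps["entropy"], 0.0)
        assert np.allclose(maps["contrast"], 0.0)

    def test_toy_patch_matches_brute_force(self):
        """All 13 statistics on a 4x4x1 two-level patch, window covering the
        patch, equal explicit pair enumeration to 1e-10."""
        rng = np.random.default_rng(0)
        patch = rng.integers(0, 2, size=(4, 4, 1)).astype(float)
        mask = np.ones((4, 4, 1), dtype=bool)
        cfg = TextureBankConfig(n_gray_levels=2, haralick_window=9)
        maps = compute_haralick_maps(patch, mask, cfg)
        offsets = [d for d in product((-1, 0, 1), repeat=3)
                   if d != (0, 0, 0) and d > (0, 0, 0)]
        oracle = brute_force_glcm_stats(patch.astype(int), 2, offsets)
        for i, name in enumerate(HARALICK_STAT_NAMES):
            got = maps[name]
            assert np.allclose(got, oracle[name], atol=1e-10), name

    def test_checkerboard_contrast_is_one_for_axial_offset(self):
        """With a single (1,0,0) offset every co-occurring pair differs by
        exactly one level, so contrast = 1 exactly."""
        from mbrisk._cooccurrence import per_voxel_glcm_stats_3d
        from mbrisk.texture_features import _quantize

        cb = (np.indices((8, 8, 1)).sum(axis=0) % 2).astype(float)
        mask = np.ones((8, 8, 1), dtype=bool)
        cfg = TextureBankConfig(n_gray_levels=2)
        q = _quantize(cb, mask, cfg)
        coords = np.argwhere(mask).astype(np.int32)
        res = per_voxel_glcm_stats_3d(
            q, mask.astype(np.uint8), coords, 2, 2,
            np.array([[1, 0, 0]], dtype=np.int32))
        contrast = res[:, HARALICK_STAT_NAMES.index("contrast")]
        assert np.allclose(contrast, 1.0)


class TestLawsMaps:
    def test_zero_sum_kernels_kill_constant_input(self):
        m = make_sphere_mask(6, (12, 12, 12), (24, 24, 24))
        maps = compute_laws_maps(np.full((24, 24, 24), 9.0), m)
        assert len(maps) == 125
        for name, vals in maps.items():
            if any(k in name for k in ("E5", "S5", "R5", "W5")):
                assert np.allclose(vals, 0.0, atol=1e-8), name
            else:  # L5L5L5 is the only all-smoothing combo
                assert np.all(vals > 0)

    @pytest.mark.parametrize("combo", ["L5E5S5", "R5W5L5", "E5E5E5"])
    def test_impulse_response_is_separable_outer_product(self, combo):
        """Raw filter response to a unit impulse equals the separable outer
        product of the three 1D kernels."""
        from scipy import ndimage

        vol = np.zeros((11, 11, 11))
        vol[5, 5, 5] = 1.0
        ka, kb, kc = (LAWS_KERNELS[combo[i:i + 2]] for i in (0, 2, 4))
        resp = vol.copy()
        for axis, k in enumerate((ka, kb, kc)):
            resp = ndimage.convolve1d(resp, k, axis=axis, mode="nearest")
        expected = np.einsum("i,j,k->ijk", ka, kb, kc)
        assert np.allclose(resp[3:8, 3:8, 3:8], expected)


class TestGaborMaps:
    def test_constant_image_zero_response(self):
        m = make_sphere_mask(6, (12, 12, 12), (24, 24, 24))
        maps = compute_gabor_maps(np.full((24, 24, 24), 7.0), m)
        assert len(maps) == 50
        assert max(np.abs(v).max() for v in maps.values()) < 1e-9

    def test_grating_peaks_at_matching_filter(self):
        """A sinusoid of wavelength 8 varying along the second in-plane axis
        is strongest under the (wavelength 8, orientation pi/2) filter."""
        idx = np.indices((40, 40, 8))
        img = np.sin(2 * np.pi * idx[1] / 8.0)
        mask = np.zeros((40, 40, 8), dtype=bool)
        mask[8:32, 8:32, 2:6] = True
        maps = compute_gabor_maps(img, mask)
        means = {k: v.mean() for k, v in maps.items()}
        assert max(means, key=means.get) == "lam8_theta5"


class TestCollageMaps:
    def test_linear_ramp_entropy_zero(self):
        vol = np.indices((24, 24, 24))[0].astype(float)
        m = make_sphere_mask(6, (12, 12, 12), (24, 24, 24))
        maps = compute_collage_maps(vol, m)
        assert len(maps) == 13
        assert "imc1" in maps and "imc2" in maps
        assert np.allclose(maps["entropy"], 0.0)

    def test_noise_patch_matches_independent_cooccurrence(self):
        """Orientation co-occurrence entropy at the central pixel of a noise
        slice equals an explicit loop-based computation on the same
        quantized orientation field."""
        rng = np.random.default_rng(8)
        vol = rng.uniform(0, 1, (9, 9, 1))
        mask = np.ones((9, 9, 1), dtype=bool)
        cfg = DEFAULT_TEXTURE_CONFIG
        maps = compute_collage_maps(vol, mask, cfg)
        ent = maps["entropy"].reshape(9, 9)

        from mbrisk.texture_features import _dominant_orientation

        theta = _dominant_orientation(vol[:, :, 0], cfg.collage_gradient_window)
        bins = np.minimum((theta / np.pi * 64).astype(int), 63)
        # explicit window pair enumeration at the central pixel (4, 4)
        counts = {}
        rad = cfg.collage_window // 2
        for x in range(4 - rad, 4 + rad + 1):
            for y in range(4 - rad, 4 + rad + 1):
                for dx, dy in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    nx, ny = x + dx, y + dy
                    if 4 - rad <= nx <= 4 + rad and 4 - rad <= ny <= 4 + rad:
                        a, b = int(bins[x, y]), int(bins[nx, ny])
                        counts[(a, b)] = counts.get((a, b), 0) + 1
                        counts[(b, a)] = counts.get((b, a), 0) + 1
        total = sum(counts.values())
        expected = -sum((v / total) * math.log2(v / total)
                        for v in counts.values())
        assert ent[4, 4] == pytest.approx(expected, abs=1e-10)
        # disorder strictly exceeds the ramp's zero entropy
        assert ent[4, 4] > 0


class TestAggregateStats:
    def test_constant_convention(self):
        assert aggregate_stats(np.full(7, 7.0)) == (7.0, 7.0, 0.0, 0.0, 0.0)

    def test_matches_direct_moment_formulas(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        mean, med, std, skew, kurt = aggregate_stats(vals)
        n = len(vals)
        d = vals - vals.mean()
        m2, m3, m4 = (np.mean(d**k) for k in (2, 3, 4))
        assert mean == pytest.approx(4.0)
        assert med == pytest.approx(3.0)
        assert std == pytest.approx(np.sqrt(m2 * n / (n - 1)))
        assert skew == pytest.approx(m3 / m2**1.5)
        assert kurt == pytest.approx(m4 / m2**2 - 3.0)

    def test_symmetric_sample_has_zero_skew(self):
        assert aggregate_stats(np.array([-3.0, 0.0, 3.0]))[3] == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_stats(np.array([]))


class TestTextureVector:
    @pytest.fixture(scope="class")
    @staticmethod
    def textured():
        mask = make_sphere_mask(6, (12, 12, 12), (24, 24, 24))
        vol = make_textured_region(mask, 100.0, 5.0, 2.0, seed=3)
        return vol, mask

    def test_vector_length_and_name_order(self, textured):
        vol, mask = textured
        vec = extract_texture_vector(vol, mask, region="habitat")
        assert len(vec) == 1070
        assert vec.index[0] == "habitat__gradient__dx__mean"
        assert vec.index[-1] == "habitat__collage__imc2__kurtosis"
        # family -> feature -> statistic ordering
        stats_cycle = [n.rsplit("__", 1)[1] for n in vec.index[:5]]
        assert stats_cycle == list(STAT_NAMES)

    def test_constant_region_zeroes_signal_families(self):
        mask = make_sphere_mask(6, (12, 12, 12), (24, 24, 24))
        vec = extract_texture_vector(np.full((24, 24, 24), 5.0), mask)
        assert vec["gradient__gradient_magnitude__mean"] == 0.0
        assert vec["laws__E5S5R5__mean"] == 0.0
        assert vec["gabor__lam4_theta0__mean"] == pytest.approx(0.0, abs=1e-9)

    def test_intensity_shift_invariance_of_differential_families(self, textured):
        vol, mask = textured
        a = extract_texture_vector(vol, mask)
        b = extract_texture_vector(vol.data + 250.0, mask)
        for name in ("gradient__gradient_magnitude__mean",
                     "laws__E5E5E5__mean", "gabor__lam8_theta3__mean",
                     "haralick__entropy__mean", "collage__entropy__mean"):
            assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_disorder_monotonicity_of_haralick_entropy(self):
        """Raising the disorder amplitude never lowers mean GLCM entropy
        (seeded replicates)."""
        mask = make_sphere_mask(7, (12, 12, 12), (24, 24, 24))
        for seed in (0, 1, 2):
            ents = []
            for disorder in (0.5, 5.0):
                vol = make_textured_region(mask, 100.0, disorder, 2.0, seed=seed)
                vec = extract_texture_vector(vol, mask)
                ents.append(vec["haralick__entropy__mean"])
            assert ents[1] >= ents[0]
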