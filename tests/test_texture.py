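"""Texture features vs an independent brute-force oracle, plus map behavior."""

import numpy as np
import pytest
from texture_oracle import brute_all_features, brute_glcm

from usradiomics.rf_core import RegionMasks
from usradiomics.texture import (
    FEATURE_MANIFEST,
    TextureSpec,
    denoise,
    glcm_matrix,
    quantize_window,
    texture_features,
    texture_maps,
)

# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def test_manifest_has_40_features():
    assert len(FEATURE_MANIFEST) == 40
    assert len(set(FEATURE_MANIFEST)) == 40
    for name in ("glcm_CON", "glcm_COR", "glcm_HOM", "glcm_VAR", "glrlm_LRLGE",
                 "glrlm_SRE", "glrlm_RLV", "glszm_SZLGE", "glszm_LZLGE",
                 "glszm_LZHGE", "glszm_ZSV", "ngtdm_BUS", "ngtdm_CRS"):
        assert name in FEATURE_MANIFEST


def test_all_windows_of_16x16_fixture_match_brute_force(rng):
    """Every 9x9 window of a random 16 x 16 image: all 40 features match the
    independent loop-based implementation exactly."""
    img = rng.integers(0, 200, (16, 16)).astype(float)
    levels = 8
    for i in range(16 - 9 + 1):
        for j in range(16 - 9 + 1):
            q = quantize_window(img[i : i + 9, j : j + 9], levels)
            got, _ = texture_features(q, levels)
            want = brute_all_features(q, levels)
            for name in FEATURE_MANIFEST:
                assert got[name] == pytest.approx(want[name], rel=1e-10, abs=1e-12), name


def test_glcm_counts_match_pair_enumeration():
    """Hand-checkable 4x4 image: co-occurrence counts equal exhaustive pairs."""
    q = np.array([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]])
    P = glcm_matrix(q, 4)
    B = brute_glcm(q, 4)
    assert np.allclose(P, B)
    assert np.allclose(P, P.T)
    assert np.isclose(P.sum(), 1.0)


def test_checkerboard_extremizes_contrast():
    """Among all 2-level 3x3 images, the checkerboard maximizes GLCM contrast
    and minimizes homogeneity (exhaustive search over 2^9 images)."""
    best_con, best_hom = -1.0, 2.0
    checker = np.indices((3, 3)).sum(axis=0) % 2 + 1
    con_checker = texture_features(checker, 2)[0]["glcm_CON"]
    hom_checker = texture_features(checker, 2)[0]["glcm_HOM"]
    # exhaustive over all binary 3x3 images
    for bits in range(1 << 9):
        q = (np.array([(bits >> k) & 1 for k in range(9)]).reshape(3, 3) + 1)
        f, _ = texture_features(q, 2)
        best_con = max(best_con, f["glcm_CON"])
        if q.min() != q.max():
            best_hom = min(best_hom, f["glcm_HOM"])
    assert con_checker == pytest.approx(best_con)
    assert hom_checker == pytest.approx(best_hom)


def test_constant_window_degenerate_values():
    q = np.ones((9, 9), dtype=int)
    f, degenerate = texture_features(q, 64)
    assert degenerate
    assert f["glcm_CON"] == 0.0
    assert f["glcm_HOM"] == 1.0
    assert f["glcm_ENE"] == 1.0
    assert f["glcm_COR"] == 0.0  # emitted as 0 with the degenerate flag


def test_window_too_small_rejected():
    with pytest.raises(ValueError):
        texture_features(np.ones((2, 2), int), 4)


class TestQuantize:
    def test_identity_mapping(self):
        w = np.arange(64.0).reshape(8, 8)
        q = quantize_window(w, 64)
        assert np.array_equal(q, np.arange(1, 65).reshape(8, 8))

    def test_constant_maps_to_one(self):
        assert np.all(quantize_window(np.full((5, 5), 3.7), 64) == 1)

    def test_monotone_on_ramp(self):
        ramp = np.linspace(0, 1, 81).reshape(9, 9)
        q = quantize_window(ramp, 16)
        assert np.all(np.diff(q.ravel()) >= 0)

    def test_affine_invariance(self, rng):
        w = rng.normal(size=(9, 9))
        assert np.array_equal(quantize_window(w, 32), quantize_window(5 * w + 3, 32))


class TestDenoise:
    def test_zero_iterations_identity(self, rng):
        img = rng.normal(size=(30, 30))
        out = denoise(img, TextureSpec(diffusion_iterations=0))
        assert np.array_equal(out, img)

    def test_constant_unchanged(self):
        img = np.full((20, 20), 7.0)
        assert np.allclose(denoise(img), img)

    def test_edge_preserved_noise_reduced(self, rng):
        img = np.zeros((40, 40))
        img[:, 20:] = 10.0
        noisy = img + rng.normal(0, 0.5, img.shape)
        out = denoise(noisy, TextureSpec(diffusion_iterations=10,
                                         diffusion_kappa=2.0))
        # within-region variance decreases
        assert out[:, :18].var() < noisy[:, :18].var()
        assert out[:, 22:].var() < noisy[:, 22:].var()
        # edge stays within 1 px: the strongest gradient column is 19 or 20
        grad_col = np.abs(np.diff(out, axis=1)).mean(axis=0).argmax()
        assert grad_col in (18, 19, 20)


class TestTextureMaps:
    def test_step_arithmetic(self):
        assert TextureSpec(window=9, overlap=0.8).step == 2

    def test_forty_maps_from_one_image(self, rng):
        img = rng.normal(size=(40, 40))
        maps = texture_maps(img, None, TextureSpec())
        assert len(maps) == 40
        assert all(m.shape == img.shape for m in maps.values())

    def test_masked_centers_skipped(self, rng):
        img = rng.normal(size=(40, 40))
        tumor = np.zeros((40, 40), bool)
        tumor[10:20, 10:20] = True
        ring = np.zeros((40, 40), bool)
        ring[5:25, 5:25] = True
        ring &= ~tumor
        masks = RegionMasks(tumor=tumor, peri_tumor=ring)
        maps = texture_maps(img, masks, TextureSpec())
        con = maps["glcm_CON"]
        assert np.isnan(con[~masks.union]).all()
        assert np.isfinite(con[masks.union]).any()

    def test_two_texture_phantom_increases_spatial_variance(self, rng):
        quiet = rng.normal(0, 1, (40, 40))
        mixed = quiet.copy()
        mixed[:, 20:] = rng.normal(0, 1, (40, 20)) * 8 + 20
        spec = TextureSpec(diffusion_iterations=0)
        v_quiet = np.nanvar(texture_maps(quiet, None, spec)["glcm_VAR"])
        v_mixed = np.nanvar(texture_maps(mixed, None, spec)["glcm_VAR"])
        assert v_mixed > v_quiet

    def test_empty_mask_intersection_rejected(self, rng):
        img = rng.normal(size=(40, 40))
        tumor = np.zeros((40, 40), bool)
        tumor[0, 0] = True  # no valid window center at the corner with step 2
        ring = np.zeros((40, 40), bool)
        ring[0, 1] = True
        masks = RegionMasks(tumor=tumor, peri_tumor=ring)
        with pytest.raises(ValueError):
            texture_maps(img, masks, TextureSpec())
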