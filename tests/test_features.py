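"""Feature engine: registry closure, preprocessing contracts, matrix-level
oracles for every texture family, and analytic shape limits."""

import numpy as np
import pytest
import scipy.stats

import perturbomics as p
from perturbomics.features import ALL_FEATURE_CLASSES, feature_names
from perturbomics.features._texture import (
    _glcm_single,
    _glrlm_single,
    discretize,
    gldm_features,
    glszm_features,
    ngtdm_features,
)


def test_registry_closure_107():
    names = feature_names()
    assert len(names) == 107
    by_class = {c: [n for n in names if n.startswith(c + "_")] for c in ALL_FEATURE_CLASSES}
    assert len(by_class["shape"]) == 14
    assert len(by_class["firstorder"]) == 18
    texture = sum(len(by_class[c]) for c in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"))
    assert texture == 75
    assert len(set(names)) == 107  # no duplicates across classes


def test_subset_registry_is_order_preserving():
    sub = feature_names(("firstorder", "glcm"))
    full = feature_names()
    assert sub == [n for n in full if n in set(sub)]


# ------------------------------------------------------------ preprocessing


def _vol(data, spacing=(1.0, 1.0, 1.0), modality="CT"):
    return p.ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing, modality=modality)


def test_constant_image_survives_denoising():
    img = _vol(np.full((8, 16, 16), 42.0))
    mask = p.RoiMask(data=np.ones((8, 16, 16), dtype=np.uint8), spacing=(1, 1, 1))
    out_img, out_mask = p.preprocess(img, mask, p.ExtractionConfig())
    assert np.allclose(out_img.data, 42.0, atol=1e-6)
    assert out_img.spacing == (2.0, 2.0, 2.0)


def test_already_isotropic_grid_unchanged():
    img = _vol(np.random.default_rng(0).normal(size=(10, 12, 12)), spacing=(2.0, 2.0, 2.0))
    mask_data = np.zeros((10, 12, 12), dtype=np.uint8)
    mask_data[3:7, 3:9, 3:9] = 1
    mask = p.RoiMask(data=mask_data, spacing=(2.0, 2.0, 2.0))
    out_img, out_mask = p.preprocess(img, mask, p.ExtractionConfig())
    assert out_img.shape == img.shape
    assert out_mask.shape == mask.shape


def test_mr_zscore_standardization():
    rng = np.random.default_rng(1)
    img = _vol(rng.normal(500, 80, (8, 20, 20)), modality="MR")
    mask = p.RoiMask(data=np.ones((8, 20, 20), dtype=np.uint8), spacing=(1, 1, 1))
    out_img, _ = p.preprocess(img, mask, p.ExtractionConfig())
    assert abs(out_img.data.mean()) < 0.1
    assert abs(out_img.data.std() - 1.0) < 0.1


def test_mask_empty_after_resampling_names_patient():
    img = _vol(np.zeros((4, 8, 8)))
    mask_data = np.zeros((4, 8, 8), dtype=np.uint8)
    mask_data[1, 1, 1] = 1  # odd-index voxel: never sampled on the 2 mm grid
    mask = p.RoiMask(data=mask_data, spacing=(1, 1, 1))
    with pytest.raises(ValueError, match="P99"):
        p.preprocess(img, mask, p.ExtractionConfig(), name="P99")


# ------------------------------------------------------------- extraction


def test_vector_length_107_on_phantom(small_cohort):
    rec = small_cohort[0]
    feats = p.extract_features(rec.image, rec.mask, p.ExtractionConfig())
    assert len(feats) == 107
    assert list(feats) == feature_names()
    assert all(np.isfinite(v) for v in feats.values())


def test_determinism_bit_identical(small_cohort):
    rec = small_cohort[3]
    cfg = p.ExtractionConfig()
    a = p.extract_features(rec.image, rec.mask, cfg)
    b = p.extract_features(rec.image, rec.mask, cfg)
    assert a == b


def test_translation_invariance_on_constant_image():
    """Intensity and texture features ignore where a constant field is
    sampled; only shape position changes under translation."""
    img = _vol(np.full((6, 40, 40), 55.0), spacing=(2.0, 2.0, 2.0))
    data = np.zeros((6, 40, 40), dtype=np.uint8)
    data[2:5, 12:24, 10:26] = 1
    mask = p.RoiMask(data=data, spacing=(2.0, 2.0, 2.0))
    shifted = p.translate_mask(mask, 0.30, "x", 1)
    cfg = p.ExtractionConfig(feature_classes=("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm"))
    a = p.extract_features(img, mask, cfg, preprocessed=True)
    b = p.extract_features(img, shifted, cfg, preprocessed=True)
    assert a == b


def test_sphere_sphericity_near_one():
    m = p.generate_ellipsoid_mask((26, 26, 26), (1, 1, 1), (12.5, 12.5, 12.5), (10, 10, 10))
    img = _vol(np.zeros((26, 26, 26)))
    feats = p.extract_features(
        img, m, p.ExtractionConfig(feature_classes=("shape",)), preprocessed=True
    )
    assert abs(feats["shape_Sphericity"] - 1.0) <= 0.02
    assert feats["shape_Elongation"] == pytest.approx(1.0, abs=0.02)


def test_firstorder_against_scipy_oracle():
    rng = np.random.default_rng(5)
    vals = rng.normal(100, 30, 500)
    from perturbomics.features._firstorder import firstorder_features

    f = firstorder_features(vals, voxel_volume_mm3=8.0, bin_width=25.0)
    assert f["Mean"] == pytest.approx(vals.mean())
    assert f["Variance"] == pytest.approx(vals.var())
    assert f["Skewness"] == pytest.approx(scipy.stats.skew(vals))
    assert f["Kurtosis"] == pytest.approx(scipy.stats.kurtosis(vals, fisher=False))
    assert f["Median"] == pytest.approx(np.median(vals))
    assert f["TotalEnergy"] == pytest.approx(8.0 * np.sum(vals**2))
    assert f["RootMeanSquared"] == pytest.approx(np.sqrt(np.mean(vals**2)))


# --------------------------------------------- texture matrix hand oracles


def test_discretization_fixed_bin_width():
    x = np.array([0.0, 24.9, 25.0, 51.0, 99.0])
    lv = discretize(x, 25.0)
    assert lv.tolist() == [1, 1, 2, 3, 4]


def test_glcm_matrix_hand_case():
    levels = np.array([[[1, 1, 2, 2]]])
    mask = np.ones_like(levels, dtype=bool)
    P = _glcm_single(levels, mask, ng=2, d=(0, 0, 1))
    assert np.array_equal(P, np.array([[2.0, 1.0], [1.0, 2.0]]))


def test_glrlm_matrix_hand_case():
    levels = np.array([[[1, 1, 2, 2, 2, 1]]])
    mask = np.ones_like(levels, dtype=bool)
    P = _glrlm_single(levels, mask, ng=2, d=(0, 0, 1))
    # runs: level1 x2, level2 x3, level1 x1
    expected = np.zeros((2, 3))
    expected[0, 1] = 1  # level 1, length 2
    expected[1, 2] = 1  # level 2, length 3
    expected[0, 0] = 1  # level 1, length 1
    assert np.array_equal(P, expected)


def test_glszm_zone_inventory_hand_case():
    levels = np.array([[[1, 1, 2], [2, 1, 2]]])
    mask = np.ones_like(levels, dtype=bool)
    f = glszm_features(levels, mask)
    # zones: (level1,size3), (level2,size2), (level2,size1) -> 3 zones, 6 voxels
    assert f["ZonePercentage"] == pytest.approx(3 / 6)
    # small-area emphasis: (1/9 + 1/4 + 1/1)/3
    assert f["SmallAreaEmphasis"] == pytest.approx((1 / 9 + 1 / 4 + 1) / 3)
    assert f["GrayLevelNonUniformity"] == pytest.approx((1**2 + 2**2) / 3)


def test_gldm_dependence_hand_case():
    levels = np.array([[[1, 1, 2], [2, 1, 2]]])
    mask = np.ones_like(levels, dtype=bool)
    f = gldm_features(levels, mask)
    # dependence sizes: level1 -> {3,3,3}; level2 -> {2,1,2}
    # SDE = (3/9 + 2/4 + 1/1)/6
    assert f["SmallDependenceEmphasis"] == pytest.approx((3 / 9 + 2 / 4 + 1) / 6)
    assert f["LargeDependenceEmphasis"] == pytest.approx((3 * 9 + 2 * 4 + 1) / 6)
    assert f["GrayLevelNonUniformity"] == pytest.approx((3**2 + 3**2) / 6)


def test_ngtdm_hand_case():
    levels = np.array([[[1, 1, 2], [2, 1, 2]]])
    mask = np.ones_like(levels, dtype=bool)
    f = ngtdm_features(levels, mask)
    s1 = abs(1 - 4 / 3) + 2 * abs(1 - 8 / 5)
    s2 = abs(2 - 4 / 3) + abs(2 - 1) + abs(2 - 4 / 3)
    assert f["Coarseness"] == pytest.approx(1.0 / (0.5 * s1 + 0.5 * s2))


def test_constant_roi_texture_degenerates_gracefully():
    levels = np.ones((2, 4, 4), dtype=np.int64)
    mask = np.ones_like(levels, dtype=bool)
    from perturbomics.features._texture import glcm_features, glrlm_features

    g = glcm_features(levels, mask)
    assert g["Contrast"] == 0.0
    assert g["MaximumProbability"] == 1.0
    r = glrlm_features(levels, mask)
    assert r["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)


# ------------------------------------------------------------ feature table


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = p.PhantomConfig(
        n_per_class=2,
        grid_shape=(8, 48, 48),
        spacing_mm=(2.0, 1.0, 1.0),
        roi_axes_mm=((4.0, 6.0), (6.0, 9.0), (6.0, 9.0)),
        seed=2,
    )
    return p.generate_cohort(cfg)


def test_feature_table_rows_and_labels(tiny_cohort, fast_config):
    table = p.build_feature_table(tiny_cohort, None, fast_config)
    assert len(table) == 4
    assert set(table["variant"]) == {"original"}
    variants = {
        rec.patient_id: p.make_augmentation_set(rec.image, rec.mask, seed=1)
        for rec in tiny_cohort
    }
    table4 = p.build_feature_table(tiny_cohort, variants, fast_config)
    assert len(table4) == 16
    for rec in tiny_cohort:
        rows = table4[table4["patient_id"] == rec.patient_id]
        assert set(rows["label"]) == {rec.label}


def test_feature_table_duplicate_variant_rejected(tiny_cohort, fast_config):
    variants = {tiny_cohort[0].patient_id: {"original": tiny_cohort[0].mask}}
    with pytest.raises(ValueError, match="duplicate"):
        p.build_feature_table(tiny_cohort, variants, fast_config)
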