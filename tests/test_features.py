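"""Region features, GLCM/Haralick texture and trajectory geometry."""

import math

import numpy as np
import pytest

from mitotrack.features import (GLCM, angular_features, compute_glcm,
                                compute_region_features, haralick_features,
                                haralick_from_patch, haralick_statistics,
                                quantize, second_channel_features,
                                sister_distance, wrap_axial)


def disk_mask(size, radius, center=None):
    cy, cx = center or (size // 2, size // 2)
    yy, xx = np.mgrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


# ---------------------------------------------------------------------------
# region features
# ---------------------------------------------------------------------------

def test_disk_area_circularity_and_axes():
    mask = disk_mask(64, 10)
    rf = compute_region_features(np.ones((64, 64)), mask, pixel_size=1.0)
    assert rf.area == pytest.approx(100 * np.pi, rel=0.05)
    assert 0.9 <= rf.circularity <= 1.1
    assert rf.minor_axis / rf.major_axis == pytest.approx(1.0, rel=0.05)


def moment_oracle(mask):
    """Independent second-moment ellipse computation (literal sums)."""
    ys, xs = np.nonzero(mask)
    n = len(ys)
    cy, cx = ys.sum() / n, xs.sum() / n
    mu_rr = sum((y - cy) ** 2 for y in ys) / n + 1 / 12
    mu_cc = sum((x - cx) ** 2 for x in xs) / n + 1 / 12
    mu_rc = sum((y - cy) * (x - cx) for y, x in zip(ys, xs)) / n
    common = math.sqrt((mu_rr - mu_cc) ** 2 + 4 * mu_rc ** 2)
    major = 4 * math.sqrt((mu_rr + mu_cc + common) / 2)
    minor = 4 * math.sqrt((mu_rr + mu_cc - common) / 2)
    theta = 0.5 * math.degrees(math.atan2(2 * mu_rc, mu_cc - mu_rr))
    return major, minor, theta


def test_rectangle_orientation_and_axes_match_moment_oracle():
    mask = np.zeros((40, 40), bool)
    mask[18:22, 10:30] = True           # 20 x 4, long axis along x
    rf = compute_region_features(np.ones((40, 40)), mask)
    major, minor, theta = moment_oracle(mask)
    assert rf.orientation == pytest.approx(0.0, abs=1e-9)
    assert rf.major_axis == pytest.approx(major, rel=1e-12)
    assert rf.minor_axis == pytest.approx(minor, rel=1e-12)
    assert rf.major_axis / rf.minor_axis == pytest.approx(major / minor,
                                                          rel=1e-12)


def test_uniform_intensity_statistics():
    mask = disk_mask(32, 8)
    rf = compute_region_features(np.full((32, 32), 100.0), mask)
    assert rf.mean_int == 100.0
    assert rf.std_int == 0.0


def test_empty_mask_flagged_missing():
    rf = compute_region_features(np.ones((16, 16)), np.zeros((16, 16), bool))
    assert rf.missing
    assert math.isnan(rf.area)


def test_area_scales_with_pixel_size():
    mask = disk_mask(32, 8)
    a1 = compute_region_features(np.ones((32, 32)), mask, pixel_size=1.0)
    a2 = compute_region_features(np.ones((32, 32)), mask, pixel_size=0.5)
    assert a2.area == pytest.approx(a1.area / 4)
    assert a2.major_axis == pytest.approx(a1.major_axis / 2)


def test_features_invariant_to_translation():
    rng = np.random.default_rng(2)
    patch = rng.uniform(0, 255, (48, 48))
    mask = disk_mask(48, 9, center=(20, 20))
    rf1 = compute_region_features(patch, mask)
    rf2 = compute_region_features(np.roll(patch, (5, 3), (0, 1)),
                                  np.roll(mask, (5, 3), (0, 1)))
    for attr in ("area", "major_axis", "minor_axis", "circularity",
                 "mean_int", "std_int"):
        assert getattr(rf1, attr) == pytest.approx(getattr(rf2, attr),
                                                   rel=1e-12)
    h1 = haralick_from_patch(patch, mask)
    h2 = haralick_from_patch(np.roll(patch, (5, 3), (0, 1)),
                             np.roll(mask, (5, 3), (0, 1)))
    for name in h1:
        assert h1[name] == pytest.approx(h2[name], abs=1e-9)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def test_glcm_hand_enumerated_two_by_two():
    patch = np.array([[0, 0], [63, 63]])
    glcm = compute_glcm(patch, np.ones((2, 2), bool), offset=(0, 1),
                        prequantized=True)
    expected = np.zeros((64, 64))
    expected[0, 0] = 1
    expected[63, 63] = 1
    assert np.array_equal(glcm.matrix, expected)


def test_glcm_constant_patch_single_diagonal_entry():
    glcm = compute_glcm(np.full((5, 5), 7.0), np.ones((5, 5), bool),
                        offset=(0, 1))
    nz = np.argwhere(glcm.matrix)
    assert len(nz) == 1 and nz[0][0] == nz[0][1]
    assert glcm.matrix.sum() == 5 * 4


def glcm_pair_oracle(q, mask, offset, levels=64):
    """Exhaustive pair enumeration with both-inside-mask semantics."""
    out = np.zeros((levels, levels), np.int64)
    h, w = q.shape
    dy, dx = offset
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                out[q[y, x], q[y2, x2]] += 1
    return out


@pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1), (-1, 1)])
def test_glcm_masked_counts_match_pair_enumeration(offset):
    rng = np.random.default_rng(8)
    patch = rng.integers(0, 256, (12, 12)).astype(float)
    mask = np.ones((12, 12), bool)
    mask[:, 5] = False                  # excluded column removes its pairs
    q = quantize(patch, 64)
    glcm = compute_glcm(patch, mask, offset=offset)
    assert np.array_equal(glcm.matrix, glcm_pair_oracle(q, mask, offset))


def test_glcm_tiny_mask_rejected():
    with pytest.raises(ValueError):
        compute_glcm(np.zeros((4, 4)), np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# Haralick
# ---------------------------------------------------------------------------

def test_uniform_glcm_closed_forms():
    uniform = GLCM(np.ones((64, 64), np.int64), (0, 1))
    stats = haralick_statistics(uniform)
    assert stats["entropy"] == pytest.approx(12.0, abs=1e-9)   # log2(64^2)
    assert stats["asm"] == pytest.approx(64.0 ** -2, abs=1e-15)


def test_diagonal_glcm_zero_contrast():
    diag = GLCM(np.eye(64, dtype=np.int64), (0, 1))
    stats = haralick_statistics(diag)
    assert stats["contrast"] == 0.0
    assert stats["idm"] == pytest.approx(1.0, abs=1e-12)


def test_degenerate_glcm_flags_correlation_only():
    single = np.zeros((64, 64), np.int64)
    single[5, 5] = 10
    stats = haralick_statistics(GLCM(single, (0, 1)))
    assert math.isnan(stats["correlation"])
    assert stats["asm"] == pytest.approx(1.0)


def test_haralick_average_invariant_to_offset_order():
    rng = np.random.default_rng(3)
    patch = rng.integers(0, 200, (16, 16)).astype(float)
    mask = np.ones((16, 16), bool)
    offsets = [(0, 1), (1, 0), (1, 1), (-1, 1)]
    glcms = [compute_glcm(patch, mask, offset=o) for o in offsets]
    fwd = haralick_features(glcms)
    rev = haralick_features(glcms[::-1])
    for name in fwd:
        assert fwd[name] == pytest.approx(rev[name], abs=1e-12)


# ---------------------------------------------------------------------------
# second channel
# ---------------------------------------------------------------------------

def test_radius_zero_dilated_equals_mask_statistics():
    rng = np.random.default_rng(9)
    patch2 = rng.uniform(0, 100, (48, 48))
    mask = disk_mask(48, 10)
    sc = second_channel_features(patch2, mask, radius=0, region="dilated")
    assert sc.mean_int == pytest.approx(patch2[mask].mean(), rel=1e-12)
    assert sc.max_int == pytest.approx(patch2[mask].max(), rel=1e-12)


def test_max_displacement_by_construction():
    patch2 = np.zeros((64, 64))
    mask = disk_mask(64, 8)
    patch2[32, 42] = 50.0               # 10 px right of the mask centroid
    sc = second_channel_features(patch2, mask, radius=15, region="dilated")
    assert sc.max_int_displacement == pytest.approx(10.0, abs=0.1)


def test_toroid_area_is_set_difference():
    from scipy import ndimage as ndi
    from skimage.morphology import disk as disk_fp

    mask = disk_mask(80, 12)
    fp = disk_fp(7)
    dil = ndi.binary_dilation(mask, structure=fp)
    ero = ndi.binary_erosion(mask, structure=fp)
    toroid = dil & ~ero
    assert toroid.sum() == dil.sum() - ero.sum()
    patch2 = np.arange(80 * 80, dtype=float).reshape(80, 80)
    sc = second_channel_features(patch2, mask, radius=7, region="toroid")
    assert sc.mean_int == pytest.approx(patch2[toroid].mean(), rel=1e-12)


def test_eroded_region_empty_flagged():
    mask = disk_mask(48, 4)
    sc = second_channel_features(np.ones((48, 48)), mask, radius=15,
                                 region="eroded")
    assert sc.missing


# ---------------------------------------------------------------------------
# trajectory geometry
# ---------------------------------------------------------------------------

def test_sister_distance_three_four_five():
    a = np.array([[0.0, 0.0]])
    b = np.array([[3.0, 4.0]])
    assert sister_distance(a, b, pixel_size=1.0)[0] == 5.0
    assert sister_distance(a, b, pixel_size=0.5)[0] == 2.5


def test_sister_distance_zero_before_division():
    a = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 6.0]])
    b = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 12.0]])
    d = sister_distance(a, b, division_index=2)
    assert d[0] == 0.0 and d[1] == 0.0 and d[2] == 6.0


def test_angular_sum_of_constant_orientation_is_zero():
    theta = np.full(12, 33.0)
    s, m = angular_features(theta, 0, 12, reference_axis_deg=33.0)
    assert s == 0.0 and m == 0.0


def test_angular_sum_of_linear_rotation():
    theta = np.arange(11) * 5.0         # 10 steps of 5 degrees
    s, _ = angular_features(theta, 0, 11, reference_axis_deg=0.0)
    assert s == pytest.approx(50.0)


def test_angular_wrap_counts_short_way():
    theta = np.array([88.0, -88.0])     # axial wrap: |delta| = 4, not 176
    s, _ = angular_features(theta, 0, 2, reference_axis_deg=88.0)
    assert s == pytest.approx(4.0)
    assert wrap_axial(-176.0) == pytest.approx(4.0)


def test_angular_too_short_window_is_nan():
    s, m = angular_features(np.array([1.0, 2.0]), 0, 1, 0.0)
    assert math.isnan(s) and math.isnan(m)
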