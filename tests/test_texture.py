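"""Texture feature stack: quantization, histogram, GLCM, GLRLM, direction mean.

The GLCM and GLRLM implementations are checked against independent
brute-force oracles (exhaustive pair enumeration and explicit line scanning)
on small random volumes, in all 13 directions.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodtex.phantom import CTVolume
from nodtex.texture import (
    DIRECTIONS_13,
    FEATURE_NAMES,
    GRAY_LEVELS,
    DegenerateMatrixError,
    EmptyROIError,
    compute_glcm,
    compute_glrlm,
    extract_features,
    glcm_features,
    glrlm_features,
    histogram_features,
    quantize,
)

from conftest import make_roi


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def glcm_oracle(gray: np.ndarray, offset, distance: int = 1) -> np.ndarray:
    """Exhaustive enumeration of ordered in-mask voxel pairs (-1 = unmasked)."""
    out = np.zeros((GRAY_LEVELS, GRAY_LEVELS), dtype=np.int64)
    dz, dy, dx = (d * distance for d in offset)
    nz, ny, nx = gray.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if gray[z, y, x] < 0:
                    continue
                z2, y2, x2 = z + dz, y + dy, x + dx
                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and gray[z2, y2, x2] >= 0:
                    out[gray[z, y, x], gray[z2, y2, x2]] += 1
    return out


def glrlm_oracle(gray: np.ndarray, offset) -> dict[tuple[int, int], int]:
    """Explicit line scan: walk every maximal line parallel to the offset,
    split it at unmasked voxels, and count maximal equal-gray runs."""
    counts: dict[tuple[int, int], int] = {}
    shape = gray.shape

    def inside(p):
        return all(0 <= c < s for c, s in zip(p, shape))

    starts = [
        (z, y, x)
        for z in range(shape[0])
        for y in range(shape[1])
        for x in range(shape[2])
        if not inside((z - offset[0], y - offset[1], x - offset[2]))
    ]
    for start in starts:
        line = []
        p = start
        while inside(p):
            line.append(gray[p])
            p = (p[0] + offset[0], p[1] + offset[1], p[2] + offset[2])
        i = 0
        while i < len(line):
            if line[i] < 0:
                i += 1
                continue
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            key = (int(line[i]), j - i + 1)
            counts[key] = counts.get(key, 0) + 1
            i = j + 1
    return counts


def moments_oracle(sample):
    """Direct population moments of a small sample."""
    v = np.asarray(sample, float)
    m = v.mean()
    var = ((v - m) ** 2).mean()
    skew = ((v - m) ** 3).mean() / var**1.5 if var > 0 else 0.0
    kurt = ((v - m) ** 4).mean() / var**2 - 3.0 if var > 0 else 0.0
    return m, var, skew, kurt


# ---------------------------------------------------------------------------
# Direction set
# ---------------------------------------------------------------------------

def test_direction_set_covers_26_neighbourhood():
    assert len(DIRECTIONS_13) == 13
    assert len(set(DIRECTIONS_13)) == 13
    neg = {tuple(-c for c in d) for d in DIRECTIONS_13}
    assert not neg & set(DIRECTIONS_13)
    all26 = {
        (z, y, x)
        for z in (-1, 0, 1)
        for y in (-1, 0, 1)
        for x in (-1, 0, 1)
        if (z, y, x) != (0, 0, 0)
    }
    assert set(DIRECTIONS_13) | neg == all26


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def test_quantize_window_boundaries_and_uniform_ramp():
    # full ramp over all 4096 integer HU levels: 256 levels x 16 inputs each
    hu = np.arange(-1024, 3072, dtype=float).reshape(1, 64, 64)
    vol = CTVolume(hu, spacing_mm=(1, 1, 1))
    roi = quantize(vol, np.ones_like(hu, bool))
    g = roi.gray
    assert g.min() == 0 and g.max() == 255
    values, counts = np.unique(g, return_counts=True)
    assert len(values) == 256
    assert np.all(counts == 16)
    # boundary values explicitly
    assert roi.gray_volume[0, 0, 0] == 0      # HU -1024
    assert roi.gray_volume[0, 63, 63] == 255  # HU 3071


def test_quantize_empty_mask_raises():
    vol = CTVolume(np.zeros((2, 2, 2)), spacing_mm=(1, 1, 1))
    with pytest.raises(EmptyROIError):
        quantize(vol, np.zeros((2, 2, 2), bool))


# ---------------------------------------------------------------------------
# Histogram features
# ---------------------------------------------------------------------------

def test_histogram_degenerate_sample():
    f = histogram_features(np.full(50, 7.0))
    assert f["hist_mean"] == 7.0
    assert f["hist_variance"] == 0.0 == f["hist_stddev"]
    assert f["hist_skewness"] == 0.0 == f["hist_kurtosis"]
    assert f["hist_energy"] == 1.0
    assert f["hist_entropy"] == 0.0


def test_histogram_uniform_over_256_bins():
    f = histogram_features(np.arange(256, dtype=float))
    assert f["hist_entropy"] == pytest.approx(8.0)
    assert f["hist_energy"] == pytest.approx(1.0 / 256)


def test_histogram_moments_match_brute_force():
    sample = np.array([0, 0, 0, 1], dtype=float)  # g = {0,0,0,1}
    f = histogram_features(sample)
    m, var, skew, kurt = moments_oracle(sample)
    assert f["hist_mean"] == pytest.approx(0.25)
    assert f["hist_variance"] == pytest.approx(0.1875)
    assert f["hist_skewness"] == pytest.approx(skew)
    assert f["hist_kurtosis"] == pytest.approx(kurt)
    rng = np.random.default_rng(5)
    sample = rng.integers(0, 256, 200).astype(float)
    f = histogram_features(sample)
    m, var, skew, kurt = moments_oracle(sample)
    assert f["hist_mean"] == pytest.approx(m)
    assert f["hist_variance"] == pytest.approx(var)
    assert f["hist_skewness"] == pytest.approx(skew)
    assert f["hist_kurtosis"] == pytest.approx(kurt)


def test_variance_equals_stddev_squared():
    rng = np.random.default_rng(11)
    f = histogram_features(rng.integers(0, 256, 500).astype(float))
    assert f["hist_variance"] == pytest.approx(f["hist_stddev"] ** 2, abs=1e-9)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def test_glcm_constant_line():
    g = np.full((1, 1, 4), 5, dtype=np.int16)
    roi = make_roi(g)
    m = compute_glcm(roi, (0, 0, 1))
    assert m.counts[5, 5] == 3
    assert m.total == 3


@pytest.mark.parametrize("seed", range(20))
def test_glcm_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 8, (4, 4, 4)).astype(np.int16)
    mask = rng.random((4, 4, 4)) > 0.25
    roi = make_roi(g, mask)
    for offset in DIRECTIONS_13:
        ours = compute_glcm(roi, offset).counts
        ref = glcm_oracle(roi.gray_volume, offset)
        np.testing.assert_array_equal(ours, ref)


def test_glcm_symmetric_flag_adds_transpose():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 6, (3, 3, 3)).astype(np.int16)
    roi = make_roi(g)
    asym = compute_glcm(roi, (0, 1, 0)).counts
    sym = compute_glcm(roi, (0, 1, 0), symmetric=True).counts
    np.testing.assert_array_equal(sym, asym + asym.T)


def test_glcm_probability_normalization():
    rng = np.random.default_rng(9)
    g = rng.integers(0, 16, (5, 5, 5)).astype(np.int16)
    roi = make_roi(g, rng.random((5, 5, 5)) > 0.3)
    for offset in DIRECTIONS_13:
        m = compute_glcm(roi, offset)
        if m.total > 0:
            assert m.probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_glcm_features_single_cell_distribution():
    g = np.full((1, 1, 4), 5, dtype=np.int16)
    f = glcm_features(compute_glcm(make_roi(g), (0, 0, 1)))
    assert f["glcm_contrast"] == 0.0
    assert f["glcm_dissimilarity"] == 0.0
    assert f["glcm_homogeneity"] == 1.0
    assert f["glcm_asm"] == 1.0
    assert f["glcm_energy"] == 1.0
    assert f["glcm_probability_max"] == 1.0
    assert f["glcm_entropy"] == 0.0
    assert f["glcm_correlation"] == 1.0  # degenerate marginals


def test_glcm_features_alternating_line():
    a, b = 3, 9
    g = np.array([[[a, b, a, b, a, b]]], dtype=np.int16)
    f = glcm_features(compute_glcm(make_roi(g), (0, 0, 1)))
    assert f["glcm_contrast"] == pytest.approx((a - b) ** 2)
    assert f["glcm_dissimilarity"] == pytest.approx(abs(a - b))


def test_glcm_energy_squared_is_asm():
    rng = np.random.default_rng(21)
    g = rng.integers(0, 32, (4, 4, 4)).astype(np.int16)
    f = glcm_features(compute_glcm(make_roi(g), (1, 0, 0)))
    assert f["glcm_energy"] ** 2 == pytest.approx(f["glcm_asm"], abs=1e-12)


def test_glcm_degenerate_direction_raises():
    g = np.array([[[4]]], dtype=np.int16)  # single voxel: no pairs anywhere
    m = compute_glcm(make_roi(g), (0, 0, 1))
    assert m.total == 0
    with pytest.raises(DegenerateMatrixError):
        glcm_features(m)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def test_glrlm_two_maximal_runs():
    g = np.array([[[1, 1, 2, 2, 2]]], dtype=np.int16)
    m = compute_glrlm(make_roi(g), (0, 0, 1))
    assert m.counts[1, 1] == 1  # run of gray 1, length 2
    assert m.counts[2, 2] == 1  # run of gray 2, length 3
    assert m.total_runs == 2


@pytest.mark.parametrize("seed", range(20))
def test_glrlm_matches_line_scanning_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    g = rng.integers(0, 4, (4, 4, 4)).astype(np.int16)
    mask = rng.random((4, 4, 4)) > 0.3
    if not mask.any():
        mask[0, 0, 0] = True
    roi = make_roi(g, mask)
    for offset in DIRECTIONS_13:
        m = compute_glrlm(roi, offset)
        ref = glrlm_oracle(roi.gray_volume, offset)
        got = {
            (i, j + 1): int(m.counts[i, j])
            for i, j in zip(*np.nonzero(m.counts))
        }
        assert got == ref
        # voxel conservation: every masked voxel is in exactly one run
        lengths = np.arange(1, m.counts.shape[1] + 1)
        assert int((m.counts * lengths).sum()) == roi.voxel_count


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_glrlm_voxel_conservation_random_masks(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(1, 7, 3))
    g = rng.integers(0, 5, shape).astype(np.int16)
    mask = rng.random(shape) > rng.uniform(0.1, 0.8)
    if not mask.any():
        mask.flat[0] = True
    roi = make_roi(g, mask)
    for offset in DIRECTIONS_13:
        m = compute_glrlm(roi, offset)
        lengths = np.arange(1, m.counts.shape[1] + 1)
        assert int((m.counts * lengths).sum()) == roi.voxel_count


def test_glrlm_features_single_run():
    g = np.zeros((1, 1, 4), dtype=np.int16)  # one run: gray 0, length 4
    f = glrlm_features(compute_glrlm(make_roi(g), (0, 0, 1)))
    assert f["glrlm_lre"] == pytest.approx(16.0)
    assert f["glrlm_gln"] == pytest.approx(1.0)
    assert f["glrlm_rln"] == pytest.approx(1.0)
    assert f["glrlm_lgre"] == pytest.approx(1.0)  # i' = 1
    assert f["glrlm_hgre"] == pytest.approx(1.0)


def test_glrlm_features_two_run_hand_evaluation():
    # runs: (gray 0, len 1) and (gray 1, len 3)
    g = np.array([[[0, 1, 1, 1]]], dtype=np.int16)
    f = glrlm_features(compute_glrlm(make_roi(g), (0, 0, 1)))
    assert f["glrlm_lre"] == pytest.approx((1 + 9) / 2)
    assert f["glrlm_hgre"] == pytest.approx((1 + 4) / 2)


def test_glrlm_features_normalization_invariance():
    from nodtex.texture import RunLengthMatrix

    rng = np.random.default_rng(17)
    counts = rng.integers(0, 5, (GRAY_LEVELS, 6)).astype(np.int64)
    f1 = glrlm_features(RunLengthMatrix(counts, (0, 0, 1)))
    f2 = glrlm_features(RunLengthMatrix(counts * 7, (0, 0, 1)))
    for k in f1:
        assert f1[k] == pytest.approx(f2[k], rel=1e-12)


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

def _ball_mask(n=9, r=3.4):
    zz, yy, xx = np.mgrid[:n, :n, :n] - n // 2
    return zz**2 + yy**2 + xx**2 <= r**2


def test_extract_has_exactly_20_features():
    rng = np.random.default_rng(2)
    vol = CTVolume(rng.uniform(-200, 400, (6, 6, 6)), spacing_mm=(1, 1, 1))
    f = extract_features(vol, np.ones((6, 6, 6), bool))
    assert set(f) == set(FEATURE_NAMES)
    assert len(f) == 20


def test_isotropic_constant_roi_direction_mean_is_any_direction():
    vol = CTVolume(np.full((9, 9, 9), 100.0), spacing_mm=(1, 1, 1))
    mask = _ball_mask()
    f = extract_features(vol, mask)
    roi = make_roi(np.where(mask, 70, -1))  # g(100 HU) = 70
    single = glcm_features(compute_glcm(roi, DIRECTIONS_13[0]))
    for k, v in single.items():
        assert f[k] == pytest.approx(v)


def test_direction_mean_equals_mean_of_oracle_directions():
    rng = np.random.default_rng(31)
    hu = rng.uniform(-1024, 3071, (4, 4, 4))
    vol = CTVolume(hu, spacing_mm=(1, 1, 1))
    mask = np.ones((4, 4, 4), bool)
    f = extract_features(vol, mask)
    roi = quantize(vol, mask)
    per_dir = [glcm_features(compute_glcm(roi, off)) for off in DIRECTIONS_13]
    for name in ("glcm_contrast", "glcm_entropy", "glcm_correlation"):
        assert f[name] == pytest.approx(np.mean([d[name] for d in per_dir]))
    per_dir_rl = [glrlm_features(compute_glrlm(roi, off)) for off in DIRECTIONS_13]
    for name in ("glrlm_lre", "glrlm_gln", "glrlm_hgre"):
        assert f[name] == pytest.approx(np.mean([d[name] for d in per_dir_rl]))


def test_translation_invariance():
    rng = np.random.default_rng(41)
    base = rng.uniform(-500, 500, (5, 5, 5))
    big = np.full((12, 12, 12), -1000.0)
    mask_small = rng.random((5, 5, 5)) > 0.3
    f_ref = None
    for shift in [(0, 0, 0), (3, 2, 5), (6, 1, 0)]:
        vol = big.copy()
        mask = np.zeros_like(big, bool)
        sl = tuple(slice(s, s + 5) for s in shift)
        vol[sl] = base
        mask[sl] = mask_small
        f = extract_features(CTVolume(vol, spacing_mm=(1, 1, 1)), mask)
        if f_ref is None:
            f_ref = f
        else:
            for k in FEATURE_NAMES:
                assert f[k] == pytest.approx(f_ref[k], rel=1e-12)


def test_gray_level_permutation_sensitivity():
    """g -> 255-g preserves |i-j|-based features but flips gray-weighted ones."""
    rng = np.random.default_rng(51)
    g = rng.integers(10, 60, (5, 5, 5)).astype(np.int16)
    roi = make_roi(g)
    roi_flip = make_roi(255 - g)
    off = (0, 0, 1)
    f = glcm_features(compute_glcm(roi, off))
    ff = glcm_features(compute_glcm(roi_flip, off))
    assert f["glcm_contrast"] == pytest.approx(ff["glcm_contrast"])
    assert f["glcm_dissimilarity"] == pytest.approx(ff["glcm_dissimilarity"])
    r = glrlm_features(compute_glrlm(roi, off))
    rf = glrlm_features(compute_glrlm(roi_flip, off))
    assert r["glrlm_hgre"] != pytest.approx(rf["glrlm_hgre"])
    assert r["glrlm_lgre"] != pytest.approx(rf["glrlm_lgre"])
    # flipping to high gray levels raises HGRE and lowers LGRE
    assert rf["glrlm_hgre"] > r["glrlm_hgre"]
    assert rf["glrlm_lgre"] < r["glrlm_lgre"]
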