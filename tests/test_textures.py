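"""Texture descriptor unit and property tests with independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import mammotex as mx
import mammotex.textures as tx


def small_image_strategy(max_side=8, n_levels=4):
    return arrays(
        np.int64,
        st.tuples(st.integers(2, max_side), st.integers(2, max_side)),
        elements=st.integers(0, n_levels - 1),
    ).map(lambda a: mx.GrayImage(a, n_levels))


# ---------------------------------------------------------------------------
# quantize
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values, in_levels, n_levels, expected",
    [
        ([[0, 64], [128, 192]], 256, 4, [[0, 1], [2, 3]]),
        ([[0, 255], [255, 0]], 256, 32, [[0, 31], [31, 0]]),
        ([[7, 7], [7, 7]], 256, 16, [[0, 0], [0, 0]]),
    ],
)
def test_quantize_arithmetic(values, in_levels, n_levels, expected):
    img = mx.GrayImage(np.array(values), in_levels)
    out = mx.quantize(img, n_levels)
    assert out.n_levels == n_levels
    np.testing.assert_array_equal(out.pixels, expected)


def test_quantize_monotone(rng):
    img = mx.GrayImage.from_array(rng.integers(0, 256, (16, 16)).astype(np.uint8))
    q = mx.quantize(img, 32)
    flat_in = img.pixels.ravel()
    flat_out = q.pixels.ravel()
    order = np.argsort(flat_in)
    assert (np.diff(flat_out[order]) >= 0).all()
    assert q.pixels.min() >= 0 and q.pixels.max() <= 31


def test_quantize_rejects_degenerate():
    img = mx.GrayImage(np.zeros((4, 4), dtype=int), 256)
    with pytest.raises(ValueError):
        mx.quantize(img, 1)
    with pytest.raises(ValueError):
        mx.GrayImage(np.zeros((0, 4), dtype=int), 256)


# ---------------------------------------------------------------------------
# GLCM construction
# ---------------------------------------------------------------------------


def glcm_brute_force(img: mx.GrayImage, offset, symmetric):
    """Independent oracle: explicit pixel-pair enumeration."""
    dr, dc = offset
    n = img.n_levels
    counts = np.zeros((n, n))
    rows, cols = img.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                counts[img.pixels[r, c], img.pixels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def test_glcm_hand_enumeration():
    img = mx.GrayImage(np.array([[0, 0], [1, 1]]), 2)
    m = mx.glcm(img, (0, 1), symmetric=True, normalized=True)
    np.testing.assert_allclose(m.counts, [[0.5, 0], [0, 0.5]])


def test_glcm_constant_image():
    img = mx.GrayImage(np.zeros((5, 5), dtype=int), 4)
    m = mx.glcm(img, (0, 1))
    assert m.counts[0, 0] == pytest.approx(1.0)
    assert m.counts.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("direction", [0, 45, 90, 135])
@pytest.mark.parametrize("symmetric", [True, False])
def test_glcm_matches_brute_force(direction, symmetric, rng):
    """Counts equal exhaustive pair enumeration on small random images."""
    offset = tx.DIRECTION_OFFSETS[direction]
    for _ in range(5):
        shape = rng.integers(2, 9, size=2)
        img = mx.GrayImage(rng.integers(0, 4, shape), 4)
        ours = mx.glcm(img, offset, symmetric=symmetric, normalized=False)
        np.testing.assert_array_equal(
            ours.counts, glcm_brute_force(img, offset, symmetric)
        )


def test_glcm_matches_skimage(rng):
    """Cross-check against the scikit-image reference implementation."""
    from skimage.feature import graycomatrix

    img = rng.integers(0, 8, (16, 16)).astype(np.uint8)
    ref = graycomatrix(img, [1], [0], levels=8, symmetric=True, normed=True)
    ours = mx.glcm(mx.GrayImage(img.astype(int), 8), (0, 1))
    np.testing.assert_allclose(ours.counts, ref[:, :, 0, 0], atol=1e-12)


def test_glcm_offset_out_of_bounds():
    img = mx.GrayImage(np.zeros((3, 3), dtype=int), 2)
    with pytest.raises(ValueError):
        mx.glcm(img, (0, 5))
    with pytest.raises(ValueError):
        mx.glcm(img, (0, 0))


@settings(max_examples=30, deadline=None)
@given(small_image_strategy())
def test_glcm_normalization_and_symmetry(img):
    m = mx.glcm(img, (0, 1), symmetric=True, normalized=True)
    assert abs(m.counts.sum() - 1.0) < 1e-12
    np.testing.assert_allclose(m.counts, m.counts.T, atol=1e-12)


# ---------------------------------------------------------------------------
# GLCM statistics
# ---------------------------------------------------------------------------


def _features_dict(m):
    return dict(zip(tx.GLCM_FEATURE_NAMES, mx.glcm_features(m)))


def test_glcm_features_constant_matrix():
    counts = np.zeros((4, 4))
    counts[0, 0] = 1.0
    d = _features_dict(mx.CooccurrenceMatrix(counts, (0, 1), True, True))
    assert d["energy"] == pytest.approx(1.0)
    assert d["entropy"] == pytest.approx(0.0)
    assert d["contrast"] == pytest.approx(0.0)


def test_glcm_features_two_cell_closed_form():
    counts = np.array([[0.5, 0], [0, 0.5]])
    d = _features_dict(mx.CooccurrenceMatrix(counts, (0, 1), True, True))
    assert d["energy"] == pytest.approx(0.5)
    assert d["entropy"] == pytest.approx(1.0)  # one bit
    assert d["contrast"] == pytest.approx(0.0)
    assert d["maximum_probability"] == pytest.approx(0.5)
    assert d["correlation"] == pytest.approx(1.0)


def test_glcm_features_requires_normalized():
    m = mx.CooccurrenceMatrix(np.ones((2, 2)), (0, 1), normalized=False, symmetric=True)
    with pytest.raises(ValueError):
        mx.glcm_features(m)


def test_glcm_feature_count_and_bounds(rng):
    assert len(tx.GLCM_FEATURE_NAMES) == 22
    for _ in range(10):
        img = mx.GrayImage(rng.integers(0, 8, (12, 12)), 8)
        d = _features_dict(mx.glcm(img, (0, 1)))
        assert 0 < d["energy"] <= 1
        assert 0 < d["homogeneity"] <= 1
        assert d["entropy"] >= 0
        assert d["contrast"] >= 0
        assert np.isfinite(list(d.values())).all()


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------


def test_lbp_constant_image_ties_to_one():
    img = mx.GrayImage(np.full((6, 6), 9), 16)
    codes = mx.lbp_image(img)
    assert (codes.pixels == 255).all()


def test_lbp_bright_center_is_zero():
    a = np.ones((3, 3), dtype=int)
    a[1, 1] = 9
    assert mx.lbp_image(mx.GrayImage(a, 10)).pixels[0, 0] == 0


def test_lbp_single_dim_neighbor_clears_one_bit():
    # north-west neighbor below the center clears exactly bit 3
    # (counterclockwise-from-east ordering)
    a = np.full((3, 3), 5)
    a[0, 0] = 1
    code = mx.lbp_image(mx.GrayImage(a, 6)).pixels[0, 0]
    assert code == 255 - 2**3


def test_lbp_too_small():
    with pytest.raises(ValueError):
        mx.lbp_image(mx.GrayImage(np.zeros((2, 2), dtype=int), 2))


def uniform_bin_brute_force(code):
    """Oracle: classify a code by explicit circular transition count."""
    bits = [(code >> p) & 1 for p in range(8)]
    transitions = sum(bits[p] != bits[(p + 1) % 8] for p in range(8))
    return sum(bits) if transitions <= 2 else 9


def test_uniform_mapping_matches_brute_force():
    table = tx._uniform_bin_table()
    for code in range(256):
        assert table[code] == uniform_bin_brute_force(code)


def test_lbp_histogram_constant_and_checkerboard():
    const = mx.GrayImage(np.full((8, 8), 3), 8)
    h = mx.lbp_histogram(mx.lbp_image(const))
    assert h[8] == pytest.approx(1.0)

    board = mx.GrayImage(np.indices((9, 9)).sum(axis=0) % 2, 2)
    codes = mx.lbp_image(board)
    h = mx.lbp_histogram(codes)
    assert h.sum() == pytest.approx(1.0)
    # every interior code's bin must agree with brute-force classification
    for code in np.unique(codes.pixels):
        assert tx._uniform_bin_table()[code] == uniform_bin_brute_force(code)


def test_lbp_rotation_invariance(textured_image):
    """90-degree rotation leaves the rotation-invariant histogram unchanged."""
    h0 = mx.lbp_histogram(mx.lbp_image(textured_image))
    rot = mx.GrayImage(np.rot90(textured_image.pixels).copy(), textured_image.n_levels)
    h1 = mx.lbp_histogram(mx.lbp_image(rot))
    np.testing.assert_allclose(h0, h1, atol=0.02)


@settings(max_examples=25, deadline=None)
@given(small_image_strategy(max_side=8))
def test_lbp_code_range_and_histogram_sum(img):
    if img.shape[0] < 3 or img.shape[1] < 3:
        return
    codes = mx.lbp_image(img)
    assert codes.pixels.min() >= 0 and codes.pixels.max() <= 255
    h = mx.lbp_histogram(codes)
    assert abs(h.sum() - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# LBGLCM
# ---------------------------------------------------------------------------


def test_lbglcm_constant_image():
    img = mx.GrayImage(np.full((8, 8), 5), 16)
    d = dict(zip(tx.GLCM_FEATURE_NAMES, mx.lbglcm_features(img)))
    assert d["energy"] == pytest.approx(1.0)
    assert d["entropy"] == pytest.approx(0.0)


def test_lbglcm_equals_manual_composition(random_image):
    ours = mx.lbglcm_features(random_image)
    codes = mx.lbp_image(random_image)
    manual = mx.glcm_features_averaged(mx.quantize(codes, 32))
    np.testing.assert_allclose(ours, manual, rtol=1e-12)


def test_lbglcm_differs_from_plain_glcm(textured_image):
    plain = mx.glcm_features_averaged(mx.quantize(textured_image, 32))
    composed = mx.lbglcm_features(textured_image)
    assert not np.allclose(plain, composed)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def runs_brute_force(img: mx.GrayImage, direction):
    """Oracle: walk every line of the direction and split runs explicitly."""
    steps = {0: (0, 1), 90: (1, 0), 45: (-1, 1), 135: (1, 1)}
    dr, dc = steps[direction]
    rows, cols = img.shape
    starts = []
    for r in range(rows):
        for c in range(cols):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < rows and 0 <= pc < cols):
                starts.append((r, c))
    counts = {}
    for r, c in starts:
        line = []
        while 0 <= r < rows and 0 <= c < cols:
            line.append(img.pixels[r, c])
            r += dr
            c += dc
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            counts[(line[i], j - i)] = counts.get((line[i], j - i), 0) + 1
            i = j
    return counts


def test_glrlm_constant_image_horizontal():
    img = mx.GrayImage(np.zeros((4, 4), dtype=int), 2)
    rlm = mx.glrlm(img, 0)
    assert rlm.counts[0, 3] == 4
    assert rlm.n_runs == 4


def test_glrlm_alternating_row():
    img = mx.GrayImage(np.tile([0, 1], (4, 2)), 2)
    rlm = mx.glrlm(img, 0)
    assert (rlm.counts[:, 1:] == 0).all()
    assert rlm.n_runs == img.pixels.size


@pytest.mark.parametrize("direction", [0, 45, 90, 135])
def test_glrlm_matches_brute_force(direction, rng):
    for _ in range(5):
        shape = rng.integers(2, 9, size=2)
        img = mx.GrayImage(rng.integers(0, 3, shape), 3)
        rlm = mx.glrlm(img, direction)
        expected = runs_brute_force(img, direction)
        for (level, length), n in expected.items():
            assert rlm.counts[level, length - 1] == n
        assert rlm.counts.sum() == sum(expected.values())


@settings(max_examples=25, deadline=None)
@given(small_image_strategy(), st.sampled_from([0, 45, 90, 135]))
def test_glrlm_run_conservation(img, direction):
    rlm = mx.glrlm(img, direction)
    j = np.arange(1, rlm.counts.shape[1] + 1)
    assert (rlm.counts * j).sum() == img.pixels.size
    assert rlm.counts.sum() == rlm.n_runs


def test_glrlm_invalid_direction():
    with pytest.raises(ValueError):
        mx.glrlm(mx.GrayImage(np.zeros((3, 3), dtype=int), 2), 30)


def test_glrlm_features_constant_image():
    rlm = mx.glrlm(mx.GrayImage(np.zeros((4, 4), dtype=int), 2), 0)
    sre, lre, gln, rln, rp, lgre, hgre = mx.glrlm_features(rlm)
    assert sre == pytest.approx(0.0625)
    assert lre == pytest.approx(16.0)
    assert rp == pytest.approx(0.25)


def test_glrlm_features_unit_runs_and_bounds(rng):
    img = mx.GrayImage(np.tile([0, 1], (4, 2)), 2)
    sre, lre, *_, rp, _, _ = mx.glrlm_features(mx.glrlm(img, 0))
    assert sre == pytest.approx(1.0)
    assert lre == pytest.approx(1.0)
    assert rp == pytest.approx(1.0)
    for _ in range(5):
        img = mx.GrayImage(rng.integers(0, 4, (10, 10)), 4)
        f = mx.glrlm_features(mx.glrlm(img, 0))
        assert f[0] <= 1 <= f[1]
        assert 0 < f[4] <= 1


# ---------------------------------------------------------------------------
# Multi-level Otsu
# ---------------------------------------------------------------------------


def otsu_exhaustive(img: mx.GrayImage):
    """Oracle for nt=1: scan every cut point for max between-class variance."""
    hist = np.bincount(img.pixels.ravel(), minlength=img.n_levels).astype(float)
    total = hist.sum()
    best_t, best_var = None, -1.0
    for t in range(img.n_levels - 1):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, img.n_levels) * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-9:
            best_var, best_t = var, t
    return best_t


def test_otsu_bimodal_separates_modes():
    img = mx.GrayImage(np.repeat([0, 255], 50).reshape(10, 10), 256)
    (t,) = mx.otsu_multilevel(img, 1)
    assert (img.pixels <= t).sum() == 50  # all zeros below, all 255s above


def test_otsu_single_level_matches_exhaustive(rng):
    for _ in range(10):
        img = mx.GrayImage(rng.integers(0, 32, (12, 12)), 32)
        (t,) = mx.otsu_multilevel(img, 1)
        assert t == otsu_exhaustive(img)


def test_otsu_matches_skimage_multiotsu(rng):
    from skimage.filters import threshold_multiotsu

    img = rng.integers(0, 256, (48, 48)).astype(np.uint8)
    ref = threshold_multiotsu(img, classes=4, nbins=256)
    ours = mx.otsu_multilevel(mx.GrayImage.from_array(img), 3)
    # conventions differ by at most the bin edge
    assert np.abs(np.sort(ref) - np.sort(ours)).max() <= 1


def test_otsu_thresholds_strictly_increasing(random_image):
    t = mx.otsu_multilevel(random_image, 5)
    assert (np.diff(t) > 0).all()


def test_otsu_too_few_levels():
    img = mx.GrayImage(np.tile([0, 1], (4, 2)), 4)
    with pytest.raises(mx.DegenerateImageError):
        mx.otsu_multilevel(img, 2)


# ---------------------------------------------------------------------------
# Box counting and SFTA
# ---------------------------------------------------------------------------


def test_box_counting_degenerate_sets():
    assert mx.box_counting_dimension(np.zeros((32, 32), bool)) == 0.0
    single = np.zeros((32, 32), bool)
    single[5, 7] = True
    assert mx.box_counting_dimension(single) == pytest.approx(0.0)


def test_box_counting_full_plane_and_line():
    assert mx.box_counting_dimension(np.ones((64, 64), bool)) == pytest.approx(2.0, abs=0.1)
    line = np.zeros((64, 64), bool)
    line[32, :] = True
    assert mx.box_counting_dimension(line) == pytest.approx(1.0, abs=0.1)


def test_halfplane_border_dimension_near_one():
    half = np.zeros((64, 64), bool)
    half[32:, :] = True
    dim = mx.box_counting_dimension(mx.region_border(half))
    assert 0.85 <= dim <= 1.15


def test_sfta_decomposition_structure(random_image):
    nt = 5
    d = mx.sfta_decompose(random_image, nt)
    assert len(d.pair_set) == nt - 1
    assert len(d.upper_set) == nt
    assert len(d.binary_images) == 2 * nt - 1
    assert (np.diff(d.thresholds) > 0).all()


def test_sfta_vector_contract(random_image):
    v = mx.sfta(random_image, 5)
    assert len(v) == 27
    assert np.isfinite(v).all()
    # size features are exact foreground counts
    d = mx.sfta_decompose(random_image, 5)
    for k, b in enumerate(d.binary_images):
        assert v[3 * k + 2] == b.sum()
    # TB sizes (pixels above threshold) nonincreasing in threshold index
    tb_sizes = [v[3 * k + 2] for k in range(4, 9)]
    assert (np.diff(tb_sizes) <= 0).all()


def test_sfta_empty_band_is_zero():
    # two-mode image: the middle band between the two occupied bands is empty
    a = np.repeat([0, 10, 200, 210], 64).reshape(16, 16)
    img = mx.GrayImage(a, 256)
    v = mx.sfta(img, 2)
    assert len(v) == 9
    assert np.isfinite(v).all()


# ---------------------------------------------------------------------------
# extract_features
# ---------------------------------------------------------------------------


def test_extract_features_length_and_names(random_image):
    fv = mx.extract_features(random_image)
    assert len(fv) == 88
    assert np.isfinite(fv.values).all()
    assert fv.names[:1] == ("glcm.autocorrelation",)
    assert len(set(fv.names)) == 88


def test_extract_features_constant_image_finite():
    img = mx.GrayImage(np.full((64, 64), 7), 256)
    fv = mx.extract_features(img)
    assert np.isfinite(fv.values).all()


def test_extract_features_deterministic(random_image):
    a = mx.extract_features(random_image)
    b = mx.extract_features(random_image)
    np.testing.assert_array_equal(a.values, b.values)


def test_extract_features_descriptor_permutation(random_image):
    cfg = mx.FeatureConfig(descriptors=("sfta", "lbp", "glrlm", "lbglcm", "glcm"))
    fv = mx.extract_features(random_image, cfg)
    default = mx.extract_features(random_image)
    assert sorted(fv.names) == sorted(default.names)
    lookup = dict(zip(default.names, default.values))
    for name, value in zip(fv.names, fv.values):
        assert value == lookup[name]
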