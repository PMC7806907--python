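"""GLCM quantisation, matrices, statistics, maps and object features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from crownmap.texture import (DEFAULT_OFFSETS, GLCMMatrix, TEXTURE_NAMES,
                              compute_glcm, kernel_sweep_select,
                              object_feature_vector,
                              quantize_grey, rgb_to_grey, texture_maps,
                              texture_stats)


def brute_glcm(window, n_levels, offsets=DEFAULT_OFFSETS, symmetric=True):
    """Pair-enumeration oracle: walk every pixel and offset explicitly."""
    counts = np.zeros((n_levels, n_levels))
    rows, cols = window.shape
    for dr, dc in offsets:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[window[r, c], window[r2, c2]] += 1
                    if symmetric:
                        counts[window[r2, c2], window[r, c]] += 1
    return counts / counts.sum()


def brute_stats(P):
    """Direct double-loop evaluation of the five texture statistics."""
    n = P.shape[0]
    asm = contrast = dissim = entropy = homog = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            asm += p * p
            contrast += p * (i - j) ** 2
            dissim += p * abs(i - j)
            homog += p / (1 + (i - j) ** 2)
            if p > 0:
                entropy -= p * np.log(p)
    return np.array([asm, contrast, dissim, entropy, homog])


class TestQuantize:
    @pytest.mark.parametrize("value,bits,level", [
        (0, 5, 0), (255, 5, 31), (8, 5, 1), (7, 5, 0), (255, 8, 255),
        (128, 1, 1),
    ])
    def test_levels(self, value, bits, level):
        assert quantize_grey(np.array([value]), bits)[0] == level

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            quantize_grey(np.array([300]), 5)

    def test_output_range(self):
        out = quantize_grey(np.arange(256), 5)
        assert out.min() == 0 and out.max() == 31

    def test_grey_conversion_luminance(self):
        rgb = np.zeros((3, 1, 1))
        rgb[1] = 100.0
        assert rgb_to_grey(rgb)[0, 0] == round(0.587 * 100)


class TestGLCM:
    def test_constant_window_single_entry(self):
        P = compute_glcm(np.full((4, 4), 3), 8).P
        assert P[3, 3] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_two_pixel_symmetric_pair(self):
        P = compute_glcm(np.array([[0, 1]]), 2, offsets=((0, 1),),
                         symmetric=True).P
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        win = rng.integers(0, 4, (5, 5))
        got = compute_glcm(win, 4).P
        want = brute_glcm(win, 4)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_matches_skimage_single_offset(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(1)
        win = rng.integers(0, 8, (9, 9)).astype(np.uint8)
        mine = compute_glcm(win, 8, offsets=((0, 1),), symmetric=True).P
        theirs = graycomatrix(win, [1], [0], levels=8, symmetric=True,
                              normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(mine, theirs, atol=1e-12)

    def test_window_too_small_raises(self):
        with pytest.raises(ValueError):
            compute_glcm(np.array([[0]]), 2)

    def test_levels_above_range_raise(self):
        with pytest.raises(ValueError):
            compute_glcm(np.array([[5, 1]]), 4)


class TestStats:
    def test_degenerate_distribution(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        tv = texture_stats(GLCMMatrix(P, 4))
        assert tv.asm == pytest.approx(1.0)
        assert tv.contrast == 0.0
        assert tv.dissimilarity == 0.0
        assert tv.entropy == pytest.approx(0.0)
        assert tv.homogeneity == pytest.approx(1.0)

    def test_uniform_distribution_asm(self):
        n = 8
        P = np.full((n, n), 1.0 / n ** 2)
        tv = texture_stats(GLCMMatrix(P, n))
        assert tv.asm == pytest.approx(1.0 / n ** 2)
        assert tv.entropy == pytest.approx(np.log(n ** 2))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((4, 4))
        P /= P.sum()
        tv = texture_stats(GLCMMatrix(P, 4))
        np.testing.assert_allclose(tv.as_array(), brute_stats(P), atol=1e-12)

    def test_unnormalized_raises(self):
        with pytest.raises(ValueError):
            texture_stats(GLCMMatrix(np.full((2, 2), 1.0), 2))


class TestMaps:
    def test_constant_image(self):
        maps = texture_maps(np.full((10, 10), 5), 3, n_levels=8)
        inner = slice(1, 9)
        assert np.allclose(maps["contrast"][inner, inner], 0.0)
        assert np.allclose(maps["homogeneity"][inner, inner], 1.0)
        assert np.allclose(maps["asm"][inner, inner], 1.0)

    def test_margin_footprint(self):
        maps = texture_maps(np.zeros((12, 15), dtype=int), 5, n_levels=2)
        valid = ~np.isnan(maps["asm"])
        assert valid.sum() == (12 - 4) * (15 - 4)
        assert not valid[0].any() and not valid[:, 0].any()

    def test_even_kernel_raises(self):
        with pytest.raises(ValueError):
            texture_maps(np.zeros((8, 8), dtype=int), 4)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 4, (12, 12))
        k = 5
        maps = texture_maps(img, k, n_levels=4)
        m = k // 2
        for r in range(m, 12 - m):
            for c in range(m, 12 - m):
                win = img[r - m:r + m + 1, c - m:c + m + 1]
                tv = texture_stats(compute_glcm(win, 4))
                for name, val in zip(TEXTURE_NAMES, tv.as_array()):
                    assert maps[name][r, c] == pytest.approx(val, abs=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 8, (16, 16))
        maps = texture_maps(img, 3, n_levels=8)
        shifted = texture_maps(np.roll(img, 2, axis=1), 3, n_levels=8)
        # interior columns away from the wrap-around agree after shifting
        a = maps["contrast"][1:-1, 3:10]
        b = shifted["contrast"][1:-1, 5:12]
        np.testing.assert_allclose(a, b, atol=1e-12)


@settings(deadline=None, max_examples=30)
@given(arrays(np.int64, (6, 6), elements=st.integers(0, 7)))
def test_glcm_invariants_and_constant_biconditional(window):
    """Normalization/symmetry hold; ASM=1 and contrast=0 iff constant."""
    g = compute_glcm(window, 8)
    assert g.P.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(g.P, g.P.T)
    tv = texture_stats(g)
    constant = len(np.unique(window)) == 1
    assert (tv.asm == pytest.approx(1.0)) == constant
    assert (tv.homogeneity == pytest.approx(1.0)) == constant
    if constant:
        assert tv.contrast == 0 and tv.entropy == pytest.approx(0.0)
    else:
        assert tv.entropy > 0


class _Obj:
    def __init__(self, oid, rgb, mask, label):
        self.id, self.rgb, self.mask, self.label = oid, rgb, mask, label


class TestObjectFeatures:
    def test_width_is_16(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 255, (3, 20, 20)).astype(float)
        mask = np.ones((20, 20), dtype=bool)
        maps = texture_maps(quantize_grey(rgb_to_grey(rgb)), 3)
        row = object_feature_vector(mask, rgb, maps)
        assert row.shape == (16,)

    def test_constant_object_band_sd_zero(self):
        rgb = np.full((3, 10, 10), 80.0)
        mask = np.ones((10, 10), dtype=bool)
        maps = texture_maps(quantize_grey(rgb_to_grey(rgb)), 3)
        row = object_feature_vector(mask, rgb, maps)
        assert row[1] == row[3] == row[5] == 0.0       # band SDs
        assert row[6] == pytest.approx(1.0)            # ASM mean
        assert row[8] == pytest.approx(0.0)            # contrast mean

    def test_two_pixel_band_arithmetic(self):
        rgb = np.zeros((3, 5, 5))
        rgb[:, 2, 2] = 0.0
        rgb[:, 2, 3] = 248.0
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = mask[2, 3] = True
        maps = texture_maps(quantize_grey(rgb_to_grey(rgb)), 3)
        row = object_feature_vector(mask, rgb, maps)
        assert row[0] == pytest.approx(124.0)   # R mean of {0, 248}
        assert row[1] == pytest.approx(124.0)   # population SD

    def test_object_inside_margin_raises(self):
        rgb = np.zeros((3, 8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True  # inside the margin for kernel 5
        maps = texture_maps(quantize_grey(rgb_to_grey(rgb)), 5)
        with pytest.raises(ValueError):
            object_feature_vector(mask, rgb, maps)


def _toy_objects(seed=0, n_per_class=8, size=40):
    """Two texture classes: same colour, different spatial frequency."""
    rng = np.random.default_rng(seed)
    objs = []
    oid = 0
    for cls, freq in ((1, 0.05), (2, 0.25)):
        for _ in range(n_per_class):
            white = rng.standard_normal((size, size))
            fy = np.fft.fftfreq(size)[:, None]
            fx = np.fft.fftfreq(size)[None, :]
            r = np.hypot(fy, fx)
            band = np.exp(-0.5 * ((r - freq) / 0.02) ** 2)
            tex = np.fft.ifft2(np.fft.fft2(white) * band).real
            tex *= 30 / tex.std()
            rgb = np.clip(128 + np.stack([tex] * 3), 0, 255)
            objs.append(_Obj(oid, rgb, np.ones((size, size), bool), cls))
            oid += 1
    return objs


class TestKernelSweep:
    def test_single_candidate_returned(self):
        objs = _toy_objects()
        best, table = kernel_sweep_select(objs, sizes=(11,), seed=0)
        assert best == 11
        assert len(table) == 1

    def test_table_rows_ascending_and_best_is_argmax(self):
        objs = _toy_objects()
        best, table = kernel_sweep_select(objs, sizes=(19, 3, 11), seed=0)
        assert list(table["kernel_size"]) == [3, 11, 19]
        top = table["val_accuracy"].max()
        assert table.loc[table["kernel_size"] == best,
                         "val_accuracy"].iloc[0] == top
        # ties resolve to the smallest size
        tied = table[table["val_accuracy"].round(12) == round(top, 12)]
        assert best == int(tied["kernel_size"].min())

    def test_single_class_raises(self):
        objs = [o for o in _toy_objects() if o.label == 1]
        with pytest.raises(ValueError):
            kernel_sweep_select(objs, sizes=(3,), seed=0)
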