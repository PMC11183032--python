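"""Texture-matrix constructions and the 75-feature bank."""

import numpy as np
import pytest

from rfmap import texture_bank as tb

from oracles import naive_features_75

GRID_3X3 = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=float)


def _qw(grid, n_levels=None):
    g = np.asarray(grid, dtype=np.int64)
    return tb.QuantizedWindow(g, int(n_levels or g.max()))


class TestQuantize:
    def test_constant_input_maps_to_single_level(self):
        q = tb.quantize(np.full((7, 7), 5.0), n_bins=16)
        assert q.n_levels == 1
        assert (q.levels == 1).all()

    def test_two_point_range(self):
        patch = np.array([[0.0, 255.0], [255.0, 0.0]])
        q = tb.quantize(patch, n_bins=2)
        assert q.levels[0, 0] == 1 and q.levels[0, 1] == 2

    def test_ramp_equal_width_groups(self):
        q = tb.quantize(np.arange(16.0).reshape(4, 4), n_bins=4)
        expected = np.repeat([1, 2, 3, 4], 4).reshape(4, 4)
        np.testing.assert_array_equal(q.levels, expected)

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            tb.quantize(np.empty((0, 0)))

    def test_shift_invariance_with_shifted_endpoints(self, rng):
        patch = rng.normal(size=(9, 9))
        lo, hi = patch.min(), patch.max()
        q1 = tb.quantize(patch, 16, intensity_range=(lo, hi))
        q2 = tb.quantize(patch + 10.0, 16, intensity_range=(lo + 10.0, hi + 10.0))
        np.testing.assert_array_equal(q1.levels, q2.levels)


class TestGLCM:
    def test_hand_counted_horizontal_symmetric(self):
        # forward pairs: row0 (1,1),(1,2); row1 (1,2),(2,2); row2 (2,2),(2,2)
        # -> counts (1,1):1, (1,2):2, (2,2):3; symmetric doubles to total 12
        w = _qw(GRID_3X3 + 1)
        P, levels = tb.build_glcm(w, distance=1, directions=[(0, 1)], symmetric=True)
        np.testing.assert_allclose(
            P, np.array([[2, 2], [2, 6]]) / 12.0, atol=1e-12)

    def test_contrast_from_hand_counts(self):
        # sum p(i,j)(i-j)^2 = (2/12 + 2/12) * 1 = 1/3
        w = _qw(GRID_3X3 + 1)
        P, lv = tb.build_glcm(w, 1, [(0, 1)], True)
        contrast = tb.glcm_features(P, lv)["Contrast"]
        assert contrast == pytest.approx(1 / 3)

    def test_normalization_and_symmetry(self, rng):
        w = tb.quantize(rng.normal(size=(7, 7)), 8)
        P, _ = tb.build_glcm(w)
        assert P.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(P, P.T, atol=1e-12)

    def test_constant_window_degenerate_values(self):
        f = tb.glcm_features(*tb.build_glcm(_qw(np.ones((5, 5)))))
        assert f["Contrast"] == 0
        assert f["JointEntropy"] == 0
        assert f["MaximumProbability"] == 1

    def test_transpose_invariance_all_directions(self, rng):
        patch = rng.normal(size=(7, 7))
        w1 = tb.quantize(patch, 8)
        w2 = tb.quantize(patch.T, 8)
        f1 = tb.glcm_features(*tb.build_glcm(w1))
        f2 = tb.glcm_features(*tb.build_glcm(w2))
        for k, v in f1.items():
            assert f2[k] == pytest.approx(v, rel=1e-9), k

    def test_window_smaller_than_offset_errors(self):
        with pytest.raises(ValueError):
            tb.build_glcm(_qw([[1, 2]]), distance=5, directions=[(0, 1)])


class TestGLRLM:
    def test_hand_enumerated_horizontal_runs(self):
        w = _qw(GRID_3X3 + 1)
        P, levels, nd = tb.build_glrlm(w, directions=[(0, 1)])
        # runs: (lvl1,len2):1, (lvl1,len1):1, (lvl2,len1):1, (lvl2,len2):1, (lvl2,len3):1
        assert P[0, 1] == 1 and P[0, 0] == 1
        assert P[1, 0] == 1 and P[1, 1] == 1 and P[1, 2] == 1
        assert P.sum() == 5

    def test_constant_window_run_percentage(self):
        n = 5
        w = _qw(np.ones((n, n)))
        P, lv, nd = tb.build_glrlm(w, directions=[(0, 1)])
        f = tb.glrlm_features(P, lv, n * n, nd)
        assert f["RunPercentage"] == pytest.approx(1 / n)

    def test_checkerboard_short_run_emphasis(self):
        board = np.indices((6, 6)).sum(axis=0) % 2 + 1
        P, lv, nd = tb.build_glrlm(_qw(board), directions=[(0, 1)])
        f = tb.glrlm_features(P, lv, board.size, nd)
        assert f["ShortRunEmphasis"] == pytest.approx(1.0)


class TestGLSZM:
    def test_single_zone_large_area_emphasis(self):
        w = _qw(np.ones((7, 7)))
        P, lv = tb.build_glszm(w)
        f = tb.glszm_features(P, lv, 49)
        assert f["LargeAreaEmphasis"] == pytest.approx(49 ** 2)

    def test_checkerboard_4conn_all_singletons(self):
        board = np.indices((6, 6)).sum(axis=0) % 2 + 1
        P, lv = tb.build_glszm(_qw(board), connectivity=4)
        f = tb.glszm_features(P, lv, board.size)
        assert f["SmallAreaEmphasis"] == pytest.approx(1.0)

    def test_hand_flood_fill_8conn(self):
        P, lv = tb.build_glszm(_qw(GRID_3X3 + 1), connectivity=8)
        assert P[0, 2] == 1  # level 1, size 3
        assert P[1, 5] == 1  # level 2, size 6

    def test_pixel_conservation_property(self, rng):
        for _ in range(20):
            w = tb.quantize(rng.normal(size=(7, 7)), int(rng.integers(2, 10)))
            P, _ = tb.build_glszm(w)
            sizes = np.arange(1, P.shape[1] + 1)
            assert (P * sizes).sum() == w.levels.size


class TestGLDM:
    def test_constant_window_neighbor_counts(self):
        P, lv = tb.build_gldm(_qw(np.ones((3, 3))), alpha=0, distance=1)
        # dependences: center 8, edges 5, corners 3 -> columns 9, 6, 4
        assert P[0, 8] == 1 and P[0, 5] == 4 and P[0, 3] == 4

    def test_all_distinct_levels_small_dependence_emphasis_maximal(self):
        # no two pixels share a level, so every dependence is 0 and the
        # (dependence + 1) size index is 1 everywhere -> SDE = 1
        grid = np.arange(1, 17).reshape(4, 4)
        P, lv = tb.build_gldm(_qw(grid), alpha=0)
        f = tb.gldm_features(P, lv)
        assert f["SmallDependenceEmphasis"] == pytest.approx(1.0)

    def test_checkerboard_dependences_follow_chebyshev_neighbors(self):
        # diagonal neighbors share the level on a checkerboard, so interior
        # pixels have dependence 4 (column index 5 under the j = dep+1 rule)
        board = np.indices((5, 5)).sum(axis=0) % 2 + 1
        P, lv = tb.build_gldm(_qw(board), alpha=0)
        assert P[:, 4].sum() == 9  # the 3x3 interior block


class TestNGTDM:
    def test_constant_window_coarseness_capped(self):
        tri = tb.build_ngtdm(_qw(np.ones((5, 5))))
        f = tb.ngtdm_features(tri)
        assert f["Coarseness"] == tb.COARSENESS_CAP

    def test_contrast_increases_with_level_gap(self):
        base = np.ones((5, 5))
        vals = []
        for gap in (2, 5):
            g = base.copy()
            g[2, 2] = gap
            tri = tb.build_ngtdm(_qw(g, n_levels=gap))
            vals.append(tb.ngtdm_features(tri)["Contrast"])
        assert 0 < vals[0] < vals[1]


class TestFeatures75:
    def test_cardinality_and_family_counts(self, rng):
        fv = tb.features_75(tb.quantize(rng.normal(size=(7, 7)), 16))
        assert len(fv.values) == 75
        assert fv.names == tb.FEATURE_NAMES
        for fam, count in tb.FAMILY_COUNTS.items():
            assert sum(n.startswith(fam + "_") for n in fv.names) == count

    def test_values_finite_on_random_and_degenerate_windows(self, rng):
        windows = [rng.normal(size=(7, 7)), np.ones((7, 7)),
                   np.eye(7), np.zeros((7, 7))]
        for wdat in windows:
            fv = tb.features_75(tb.quantize(wdat, 16))
            assert np.isfinite(fv.values).all()

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            w = tb.quantize(rng.normal(size=(7, 7)), int(rng.integers(2, 17)))
            ref = naive_features_75(w.levels)
            mine = tb.features_75(w).as_dict()
            for name in tb.FEATURE_NAMES:
                assert mine[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name

    def test_intensity_shift_invariance(self, rng):
        patch = rng.normal(size=(7, 7))
        lo, hi = patch.min(), patch.max()
        f1 = tb.features_75(tb.quantize(patch, 16, intensity_range=(lo, hi)))
        f2 = tb.features_75(tb.quantize(patch + 3.0, 16,
                                        intensity_range=(lo + 3.0, hi + 3.0)))
        np.testing.assert_allclose(f1.values, f2.values, rtol=1e-12)

    def test_unknown_feature_name_rejected(self, rng):
        w = tb.quantize(rng.normal(size=(7, 7)), 8)
        with pytest.raises(KeyError):
            tb.compute_features(w, names=["glcm_NotAFeature"])
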