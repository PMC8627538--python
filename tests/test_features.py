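"""Radiomic extractor: discretization, first-order/shape, and the four
texture-matrix families against brute-force enumeration oracles."""

import math

import numpy as np
import pytest

from petsil.errors import DegenerateVOIError, TextureUndefinedError
from petsil.features import (DEFAULT_ROSTER, DIRECTIONS_13, ExtractionConfig,
                             discretize, extract, first_order, glcm,
                             glcm_features, glrlm, glrlm_features, glzlm,
                             glzlm_features, ngldm_features, resample, shape)

AXIS_DIRECTIONS = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


def make_voi(levels_3d, n_bins=None, mask=None):
    """DiscretizedVOI straight from an integer level grid (levels are also
    used as the raw intensities)."""
    arr = np.asarray(levels_3d)
    while arr.ndim < 3:
        arr = arr[..., None]
    m = (arr > 0) if mask is None else np.asarray(mask, bool)
    cfg = ExtractionConfig(n_bins=n_bins or max(2, int(arr.max())))
    voi = discretize(arr.astype(float), m, cfg, spacing_mm=1.0)
    voi.levels = np.where(m, arr, 0).astype(int)  # identity level map
    return voi


def brute_glcm(levels, mask, directions):
    """Exhaustive pair enumeration over +/- offsets."""
    n = int(levels.max())
    counts = np.zeros((n, n))
    pts = np.argwhere(mask)
    for d in directions:
        for sign in (1, -1):
            off = np.array(d) * sign
            for p in pts:
                q = p + off
                if (0 <= q).all() and (q < levels.shape).all() and mask[tuple(q)]:
                    counts[levels[tuple(p)] - 1, levels[tuple(q)] - 1] += 1
    return counts / counts.sum()


class TestPreprocessing:
    def test_resample_identity_at_target_spacing(self):
        vol = np.random.default_rng(0).random((5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        out_v, out_m, sp = resample(vol, mask, 2.0, 2.0)
        assert out_v is vol and sp == 2.0

    def test_resample_constant_stays_constant(self):
        vol = np.full((6, 6, 6), 3.5)
        mask = np.ones((6, 6, 6), bool)
        out_v, out_m, _ = resample(vol, mask, 1.0, 1.5)
        assert np.allclose(out_v, 3.5)
        assert out_m.any()

    def test_resample_matches_trilinear_oracle(self):
        rng = np.random.default_rng(1)
        vol = rng.random((4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        out_v, _, _ = resample(vol, mask, 1.0, 2.0)

        def trilinear(v, x, y, z):
            x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
            out = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        xi = min(x0 + dx, v.shape[0] - 1)
                        yi = min(y0 + dy, v.shape[1] - 1)
                        zi = min(z0 + dz, v.shape[2] - 1)
                        w = ((1 - abs(x - (x0 + dx)))
                             * (1 - abs(y - (y0 + dy)))
                             * (1 - abs(z - (z0 + dz))))
                        out += max(w, 0) * v[xi, yi, zi]
            return out

        for i in range(out_v.shape[0]):
            for j in range(out_v.shape[1]):
                for k in range(out_v.shape[2]):
                    assert out_v[i, j, k] == pytest.approx(
                        trilinear(vol, 2 * i, 2 * j, 2 * k), abs=1e-12)

    def test_resample_empty_mask_raises(self):
        with pytest.raises(DegenerateVOIError):
            resample(np.ones((4, 4, 4)), np.zeros((4, 4, 4), bool), 1.0, 2.0)

    @pytest.mark.parametrize("values,mode,bounds,n_bins,expected", [
        ([4.0, 4.0, 4.0], "RELATIVE_MINMAX", None, 8, [1, 1, 1]),
        ([0.0, 1.0, 2.0, 3.0], "RELATIVE_MINMAX", None, 4, [1, 2, 3, 4]),
        ([0.0, 5.0, 10.0], "ABSOLUTE_BOUNDS", (0.0, 20.0), 4, [1, 2, 3]),
    ])
    def test_discretize_examples(self, values, mode, bounds, n_bins, expected):
        vol = np.array(values)[:, None, None]
        mask = np.ones(vol.shape, bool)
        cfg = ExtractionConfig(n_bins=n_bins, discretization_mode=mode,
                               absolute_bounds=bounds or (0.0, 25.0))
        voi = discretize(vol, mask, cfg)
        assert list(voi.in_mask_levels) == expected

    def test_discretize_monotone_in_intensity(self):
        rng = np.random.default_rng(2)
        cfg = ExtractionConfig(n_bins=16)
        for _ in range(25):
            vol = rng.random((4, 4, 4)) * 10
            mask = rng.random((4, 4, 4)) > 0.3
            if mask.sum() < 2:
                continue
            before = discretize(vol, mask, cfg)
            idx = tuple(np.argwhere(mask)[rng.integers(mask.sum())])
            bumped = vol.copy()
            bumped[idx] += rng.random() * 5
            after = discretize(bumped, mask, cfg)
            assert after.levels[idx] >= before.levels[idx]


class TestFirstOrderShape:
    def test_constant_voi(self):
        voi = make_voi(np.ones((3, 3, 3), int), n_bins=8)
        voi.raw = np.full((3, 3, 3), 4.0)
        vals, degenerate = first_order(voi)
        assert degenerate
        assert vals["SUV_min"] == vals["SUV_mean"] == vals["SUV_max"] == 4.0
        assert vals["SUV_std"] == 0 and vals["Skewness"] == 0
        assert vals["Entropy"] == 0 and vals["Energy"] == 1
        assert vals["Uniformity"] == 1

    def test_two_equal_bins(self):
        vol = np.array([1.0, 1.0, 2.0, 2.0])[:, None, None]
        voi = discretize(vol, np.ones(vol.shape, bool),
                         ExtractionConfig(n_bins=2))
        vals, _ = first_order(voi)
        assert vals["Entropy"] == pytest.approx(1.0)
        assert vals["Uniformity"] == pytest.approx(0.5)

    def test_moments_match_brute_force(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        vol = x[:, None, None]
        voi = discretize(vol, np.ones(vol.shape, bool), ExtractionConfig())
        vals, _ = first_order(voi)
        mean = x.sum() / 5
        std = math.sqrt(((x - mean) ** 2).sum() / 5)
        assert vals["SUV_mean"] == pytest.approx(mean, abs=1e-12)
        assert vals["SUV_std"] == pytest.approx(std, abs=1e-12)
        assert vals["Skewness"] == pytest.approx(
            (((x - mean) / std) ** 3).sum() / 5, abs=1e-12)
        assert vals["Kurtosis"] == pytest.approx(
            (((x - mean) / std) ** 4).sum() / 5, abs=1e-12)

    def test_cube_volume_and_closed_form_sphericity(self):
        cube = np.zeros((22, 22, 22), bool)
        cube[1:21, 1:21, 1:21] = True
        vals = shape(cube, 1.0)
        assert vals["Volume_mL"] == pytest.approx(8.0)
        closed = math.pi ** (1 / 3) * (6 * 8000) ** (2 / 3) / 2400
        assert vals["Sphericity"] == pytest.approx(closed, rel=0.05)

    def test_ball_sphericity_near_one(self):
        idx = np.indices((25, 25, 25)) - 12
        ball = (idx ** 2).sum(axis=0) <= 100
        assert shape(ball, 1.0)["Sphericity"] >= 0.95

    def test_ten_cube_volume_is_one_ml(self):
        cube = np.ones((10, 10, 10), bool)
        assert shape(cube, 1.0)["Volume_mL"] == pytest.approx(1.0)


class TestGLCM:
    def test_constant_voi(self):
        voi = make_voi(np.ones((4, 4, 4), int), n_bins=6)
        vals = glcm_features(glcm(voi))
        assert vals["GLCM_Contrast"] == 0 and vals["GLCM_Dissimilarity"] == 0
        assert vals["GLCM_Homogeneity"] == 1 and vals["GLCM_Energy"] == 1
        assert vals["GLCM_Entropy"] == 0

    def test_2x2_grid_matches_hand_enumeration(self):
        voi = make_voi(np.array([[1, 2], [1, 2]]), n_bins=2)
        P = glcm(voi)
        expected = np.array([[2, 4], [4, 2]]) / 12
        assert np.allclose(P, expected)
        vals = glcm_features(P)
        assert vals["GLCM_Contrast"] == pytest.approx(2 / 3)
        assert vals["GLCM_Dissimilarity"] == pytest.approx(2 / 3)
        assert vals["GLCM_Homogeneity"] == pytest.approx(2 / 3)
        assert vals["GLCM_Energy"] == pytest.approx(5 / 18)
        assert vals["GLCM_Correlation"] == pytest.approx(-1 / 3)
        ent = -(2 * (1 / 6) * math.log2(1 / 6) + 2 * (1 / 3) * math.log2(1 / 3))
        assert vals["GLCM_Entropy"] == pytest.approx(ent)

    def test_matrix_matches_brute_enumeration_on_random_vois(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            levels = rng.integers(1, 5, size=(4, 5, 3))
            mask = rng.random((4, 5, 3)) > 0.25
            if mask.sum() < 4:
                continue
            voi = make_voi(np.where(mask, levels, 0), n_bins=4, mask=mask)
            assert np.allclose(glcm(voi),
                               brute_glcm(voi.levels, mask, DIRECTIONS_13))

    def test_matrix_symmetric_normalized(self):
        rng = np.random.default_rng(4)
        levels = rng.integers(1, 7, size=(6, 6, 6))
        voi = make_voi(levels, n_bins=6)
        P = glcm(voi)
        assert np.allclose(P, P.T)
        assert (P >= 0).all()
        assert P.sum() == pytest.approx(1.0, abs=1e-9)

    def test_checkerboard_contrast_maximal_axis_aligned(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        board = 1 + (idx % 2)
        voi = make_voi(board, n_bins=2)
        c_board = glcm_features(glcm(voi, directions=AXIS_DIRECTIONS))
        assert c_board["GLCM_Contrast"] == pytest.approx(1.0)  # every pair differs
        rng = np.random.default_rng(5)
        for _ in range(5):
            other = make_voi(rng.integers(1, 3, size=(4, 4, 4)), n_bins=2)
            c_other = glcm_features(glcm(other, directions=AXIS_DIRECTIONS))
            assert c_other["GLCM_Contrast"] <= c_board["GLCM_Contrast"] + 1e-12

    def test_single_voxel_raises(self):
        m = np.zeros((3, 3, 3), int)
        m[1, 1, 1] = 1
        with pytest.raises(TextureUndefinedError):
            glcm(make_voi(m, n_bins=2))


class TestGLRLM:
    def test_single_run_closed_form(self):
        seg = np.full((5, 1, 1), 2)
        voi = make_voi(seg, n_bins=2)
        vals = glrlm_features(voi, directions=[(1, 0, 0)])
        assert vals["GLRLM_SRE"] == pytest.approx(1 / 25)
        assert vals["GLRLM_LRE"] == pytest.approx(25)
        assert vals["GLRLM_RP"] == pytest.approx(1 / 5)

    def test_alternating_levels_unit_runs(self):
        seg = np.array([1, 2, 1, 2])[:, None, None]
        voi = make_voi(seg, n_bins=2)
        vals = glrlm_features(voi, directions=[(1, 0, 0)])
        assert vals["GLRLM_SRE"] == pytest.approx(1.0)
        assert vals["GLRLM_LRE"] == pytest.approx(1.0)
        assert vals["GLRLM_RP"] == pytest.approx(1.0)

    def test_run_partition_conservation(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            levels = rng.integers(1, 4, size=(5, 4, 4))
            mask = rng.random((5, 4, 4)) > 0.3
            if not mask.any():
                continue
            voi = make_voi(np.where(mask, levels, 0), n_bins=3, mask=mask)
            for d in [(1, 0, 0), (0, 1, 1), (1, -1, 1)]:
                R = glrlm(voi, directions=[d])
                lengths = np.arange(1, R.shape[1] + 1)
                assert (R * lengths[None, :]).sum() == mask.sum()
            R13 = glrlm(voi)
            lengths = np.arange(1, R13.shape[1] + 1)
            assert (R13 * lengths[None, :]).sum() == 13 * mask.sum()


class TestNGLDM:
    def test_constant_voi(self):
        voi = make_voi(np.ones((3, 3, 3), int), n_bins=4)
        vals = ngldm_features(voi)
        assert vals["NGLDM_Contrast"] == 0
        assert vals["NGLDM_Busyness"] == 0
        assert np.isfinite(vals["NGLDM_Coarseness"])

    def test_two_voxel_hand_enumeration(self):
        seg = np.zeros((3, 4, 3), int)
        seg[1, 1, 1], seg[1, 2, 1] = 1, 2
        voi = make_voi(seg, n_bins=2)
        vals = ngldm_features(voi)
        # both voxels: |level - neighbour mean| = 1; p = (1/2, 1/2)
        assert vals["NGLDM_Coarseness"] == pytest.approx(1.0)
        assert vals["NGLDM_Contrast"] == pytest.approx(0.25)
        assert vals["NGLDM_Busyness"] == pytest.approx(1.0)

    def test_n_bins_irrelevant_for_constant_voi(self):
        a = ngldm_features(make_voi(np.ones((3, 3, 3), int), n_bins=4))
        b = ngldm_features(make_voi(np.ones((3, 3, 3), int), n_bins=64))
        assert a == b

    def test_isolated_voxels_raise(self):
        seg = np.zeros((5, 5, 5), int)
        seg[0, 0, 0], seg[4, 4, 4] = 1, 2
        with pytest.raises(TextureUndefinedError):
            ngldm_features(make_voi(seg, n_bins=2))


class TestGLZLM:
    def test_single_zone_closed_form(self):
        voi = make_voi(np.full((3, 3, 3), 2), n_bins=2)
        vals = glzlm_features(voi)
        v = 27
        assert vals["GLZLM_SZE"] == pytest.approx(1 / v ** 2)
        assert vals["GLZLM_LZE"] == pytest.approx(v ** 2)
        assert vals["GLZLM_ZP"] == pytest.approx(1 / v)

    def test_two_disjoint_single_voxel_zones(self):
        seg = np.zeros((5, 5, 5), int)
        seg[0, 0, 0], seg[4, 4, 4] = 1, 1
        Z = glzlm(make_voi(seg, n_bins=2))
        assert Z.sum() == 2 and Z[0, 0] == 2
        vals = glzlm_features(make_voi(seg, n_bins=2))
        assert vals["GLZLM_SZE"] == pytest.approx(1.0)

    def test_zone_partition_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            levels = rng.integers(1, 4, size=(5, 5, 4))
            mask = rng.random((5, 5, 4)) > 0.3
            if not mask.any():
                continue
            voi = make_voi(np.where(mask, levels, 0), n_bins=3, mask=mask)
            Z = glzlm(voi)
            sizes = np.arange(1, Z.shape[1] + 1)
            assert (Z * sizes[None, :]).sum() == mask.sum()


class TestExtract:
    def test_vector_has_42_features(self):
        rng = np.random.default_rng(8)
        vol = rng.random((8, 8, 8)) * 5 + 2
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        fv = extract(vol, mask, 2.0)
        assert len(fv.values) == 42
        assert len(DEFAULT_ROSTER) == 42

    def test_constant_ball_entropy_energy(self):
        idx = np.indices((11, 11, 11)) - 5
        mask = (idx ** 2).sum(axis=0) <= 16
        vol = np.where(mask, 4.0, 0.0)
        fv = extract(vol, mask, 2.0)
        d = dict(zip(fv.names, fv.values))
        assert d["Entropy"] == 0 and d["GLCM_Entropy"] == 0
        assert d["Energy"] == 1 and d["GLCM_Energy"] == 1
        assert d["GLCM_Contrast"] == 0
        assert fv.suv_max == pytest.approx(4.0)

    def test_roster_permutation_permutes_output(self):
        rng = np.random.default_rng(9)
        vol = rng.random((8, 8, 8)) * 5
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        roster = list(DEFAULT_ROSTER)[::-1]
        fv_default = extract(vol, mask, 2.0)
        fv_rev = extract(vol, mask, 2.0,
                         ExtractionConfig(feature_roster=roster))
        assert np.allclose(fv_rev.values, fv_default.values[::-1])

    def test_family_error_carries_lesion_id(self):
        vol = np.ones((4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        with pytest.raises(DegenerateVOIError, match="L99"):
            extract(vol, mask, 2.0, lesion_id="L99")

    def test_all_features_finite_on_random_vois(self):
        rng = np.random.default_rng(10)
        for k in range(8):
            vol = rng.lognormal(1.0, 0.5, size=(9, 9, 9))
            idx = np.indices((9, 9, 9)) - 4
            mask = (idx ** 2).sum(axis=0) <= rng.integers(6, 17)
            fv = extract(vol, mask, 2.0)
            assert np.isfinite(fv.values).all()

    def test_rotation_invariance_of_aggregated_textures(self):
        rng = np.random.default_rng(11)
        vol = rng.random((7, 7, 7)) * 10
        mask = np.zeros((7, 7, 7), bool)
        mask[1:6, 1:6, 1:6] = rng.random((5, 5, 5)) > 0.2
        cfg = ExtractionConfig(n_bins=8, target_spacing_mm=1.0)
        voi = discretize(vol, mask, cfg, 1.0)
        rvol = np.rot90(vol, k=1, axes=(0, 1)).copy()
        rmask = np.rot90(mask, k=1, axes=(0, 1)).copy()
        rvoi = discretize(rvol, rmask, cfg, 1.0)
        for fn in (lambda v: glcm_features(glcm(v)), glrlm_features,
                   glzlm_features, ngldm_features):
            a, b = fn(voi), fn(rvoi)
            for key in a:
                assert a[key] == pytest.approx(b[key], abs=1e-10), key
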