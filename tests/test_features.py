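import numpy as np
import pytest
from hypothesis import given, strategies as st

from radstab.core import ImageVolume, RoiMask
from radstab.features import FAMILIES, FEATURE_NAMES, extract_all
from radstab.features.firstorder import first_order_features
from radstab.features.matrices import (
    DIRECTIONS_13,
    build_glcm,
    build_gldm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    discretize,
)
from radstab.features.texture import glcm_features


def _vol(vox, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(vox, float), spacing)


def _full_mask(shape):
    return RoiMask(np.ones(shape, dtype=np.int16))


class TestDiscretize:
    def test_hand_example(self):
        d = discretize(np.array([-10.0, 0.0, 24.0, 25.0, 60.0]), 25.0)
        assert list(d.levels) == [1, 2, 2, 3, 4]
        assert d.n_levels == 4

    def test_constant_roi_single_level(self):
        d = discretize(np.full(9, 42.0))
        assert set(d.levels) == {1} and d.n_levels == 1

    @given(st.lists(st.floats(-1000, 800), min_size=1, max_size=40))
    def test_min_level_is_one(self, values):
        d = discretize(np.array(values), 25.0)
        assert d.levels.min() == 1
        assert d.n_levels == d.levels.max()

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.array([]))


class TestFirstOrder:
    def test_hand_arithmetic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        f = first_order_features(x, discretize(x, 25.0), 1.0)
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Variance"] == pytest.approx(1.25)  # population
        assert f["Range"] == pytest.approx(3.0)

    def test_two_level_histogram_entropy_one_bit(self):
        x = np.array([0.0, 0.0, 25.0, 25.0])
        f = first_order_features(x, discretize(x, 25.0), 1.0)
        assert f["Entropy"] == pytest.approx(1.0)
        assert f["Uniformity"] == pytest.approx(0.5)

    def test_constant_roi_degenerate_conventions(self):
        x = np.full(20, 7.0)
        f = first_order_features(x, discretize(x, 25.0), 2.0)
        assert f["Mean"] == f["Median"] == f["Minimum"] == f["Maximum"] == 7.0
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0 and f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0
        assert f["TotalEnergy"] == pytest.approx(2.0 * 20 * 49.0)


class TestGlcm:
    def test_two_by_two_slab_single_direction(self):
        lev = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        valid = np.ones_like(lev, bool)
        mats = build_glcm(lev, valid, 2)
        a = DIRECTIONS_13.index((0, 1, 0))
        P = mats[:, :, a] / mats[:, :, a].sum()
        assert P[0, 0] == pytest.approx(0.5)
        assert P[0, 1] == pytest.approx(0.25)
        assert P[1, 0] == pytest.approx(0.25)
        assert np.sum(P**2) == pytest.approx(0.375)  # JointEnergy

    def test_constant_roi_single_cell(self):
        lev = np.ones((3, 3, 3), dtype=np.int64)
        f = glcm_features(build_glcm(lev, np.ones_like(lev, bool), 1))
        assert f["MaximumProbability"] == pytest.approx(1.0)
        assert f["JointEntropy"] == pytest.approx(0.0)
        assert f["Correlation"] == pytest.approx(1.0)

    def test_symmetry_on_random_roi(self):
        rng = np.random.default_rng(2)
        lev = rng.integers(1, 5, (5, 4, 3))
        valid = rng.random((5, 4, 3)) < 0.8
        mats = build_glcm(lev, valid, 4)
        for a in range(13):
            np.testing.assert_array_equal(mats[:, :, a], mats[:, :, a].T)


class TestGlrlm:
    def test_single_run_long_run_emphasis(self):
        lev = np.array([1, 1, 1]).reshape(3, 1, 1)
        valid = np.ones_like(lev, bool)
        R = build_glrlm(lev, valid, 1)
        a = DIRECTIONS_13.index((1, 0, 0))
        assert R[0, 2, a] == 1  # one run of length 3
        assert R[:, :, a].sum() == 1
        lre = np.sum(R[:, :, a] * np.arange(1, R.shape[1] + 1) ** 2) / R[:, :, a].sum()
        assert lre == pytest.approx(9.0)

    def test_run_mass_conserves_voxel_count(self):
        rng = np.random.default_rng(7)
        lev = rng.integers(1, 4, (6, 5, 4))
        valid = rng.random((6, 5, 4)) < 0.7
        lev = np.where(valid, lev, 0)
        R = build_glrlm(lev, valid, 3)
        l = np.arange(1, R.shape[1] + 1)
        for a in range(13):
            assert np.sum(R[:, :, a] * l[None, :]) == valid.sum()


class TestGlszm:
    def test_constant_cube_single_zone(self):
        lev = np.ones((3, 3, 3), dtype=np.int64)
        Z = build_glszm(lev, np.ones_like(lev, bool), 1)
        assert Z.shape == (1, 27)
        assert Z[0, 26] == 1 and Z.sum() == 1

    def test_two_disjoint_islands(self):
        lev = np.ones((5, 5, 1), dtype=np.int64)
        lev[0, 0, 0] = 2
        lev[4, 4, 0] = 2
        Z = build_glszm(lev, np.ones_like(lev, bool), 2)
        assert Z[1, 0] == 2  # Z(level 2, size 1) = 2

    def test_zone_mass_conserves_voxel_count(self):
        rng = np.random.default_rng(9)
        lev = rng.integers(1, 4, (5, 5, 3))
        valid = rng.random((5, 5, 3)) < 0.8
        lev = np.where(valid, lev, 0)
        Z = build_glszm(lev, valid, 3)
        s = np.arange(1, Z.shape[1] + 1)
        assert np.sum(Z * s[None, :]) == valid.sum()


class TestGldm:
    def test_constant_cube_center_dependence(self):
        lev = np.ones((3, 3, 3), dtype=np.int64)
        D = build_gldm(lev, np.ones_like(lev, bool), 1)
        assert D[0, 26] == 1  # center voxel has all 26 neighbors equal
        assert D.sum() == 27

    def test_single_voxel_roi(self):
        lev = np.array([[[1]]], dtype=np.int64)
        D = build_gldm(lev, np.ones_like(lev, bool), 1)
        assert D.shape == (1, 1) and D[0, 0] == 1

    def test_mass_conserves_voxel_count(self):
        rng = np.random.default_rng(13)
        lev = rng.integers(1, 5, (5, 4, 4))
        valid = rng.random((5, 4, 4)) < 0.75
        lev = np.where(valid, lev, 0)
        D = build_gldm(lev, valid, 4)
        assert D.sum() == valid.sum()


class TestNgtdm:
    def test_constant_roi_zero_differences(self):
        lev = np.ones((4, 4, 2), dtype=np.int64)
        n_i, s_i = build_ngtdm(lev, np.ones_like(lev, bool), 1)
        assert s_i[0] == 0.0 and n_i[0] == 32

    def test_checkerboard_both_levels_nonzero(self):
        ix, iy = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        lev = (1 + (ix + iy) % 2).astype(np.int64).reshape(6, 6, 1)
        n_i, s_i = build_ngtdm(lev, np.ones_like(lev, bool), 2)
        assert s_i[0] > 0 and s_i[1] > 0
        p = n_i / n_i.sum()
        assert p.sum() == pytest.approx(1.0)


class TestExtractAll:
    def test_91_finite_features(self, tiny_scan):
        vol, mask, _ = tiny_scan
        fv = extract_all(vol, mask, 1)
        assert list(fv.values.keys()) == FEATURE_NAMES
        assert len(fv.values) == 91
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_constant_roi_yields_91_finite(self):
        fv = extract_all(
            _vol(np.full((5, 5, 3), -400.0)), _full_mask((5, 5, 3)), 1
        )
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_family_sizes(self):
        sizes = {f: len(v) for f, v in FAMILIES.items()}
        assert sizes == {
            "firstorder": 18, "glcm": 22, "glrlm": 16,
            "glszm": 16, "gldm": 14, "ngtdm": 5,
        }

    def test_translation_invariance(self):
        rng = np.random.default_rng(21)
        patch = rng.normal(0, 100, (4, 4, 3))
        big = np.full((12, 12, 8), -1000.0)
        m1 = np.zeros((12, 12, 8), dtype=np.int16)
        m2 = np.zeros((12, 12, 8), dtype=np.int16)
        v1 = big.copy(); v1[1:5, 1:5, 1:4] = patch; m1[1:5, 1:5, 1:4] = 1
        v2 = big.copy(); v2[6:10, 7:11, 4:7] = patch; m2[6:10, 7:11, 4:7] = 1
        f1 = extract_all(_vol(v1), RoiMask(m1), 1)
        f2 = extract_all(_vol(v2), RoiMask(m2), 1)
        for k in FEATURE_NAMES:
            assert f1.values[k] == pytest.approx(f2.values[k], rel=1e-12), k

    def test_intensity_shift_moves_location_only(self):
        rng = np.random.default_rng(22)
        vox = rng.normal(0, 100, (6, 6, 4))
        mask = _full_mask((6, 6, 4))
        c = 250.0  # multiple of the bin width: level structure unchanged
        f0 = extract_all(_vol(vox), mask, 1)
        f1 = extract_all(_vol(vox + c), mask, 1)
        for name in ("Mean", "Median", "Minimum", "Maximum"):
            assert f1.values[f"firstorder_{name}"] == pytest.approx(
                f0.values[f"firstorder_{name}"] + c
            )
        for fam in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
            for k in FAMILIES[fam]:
                assert f1.values[f"{fam}_{k}"] == pytest.approx(
                    f0.values[f"{fam}_{k}"], rel=1e-10
                ), f"{fam}_{k}"

    def test_empty_roi_rejected(self, tiny_scan):
        vol, mask, _ = tiny_scan
        with pytest.raises(ValueError):
            extract_all(vol, mask, 99)
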