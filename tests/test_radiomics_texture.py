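"""Texture matrices: hand-counted examples, oracle equivalence, symmetries."""

import numpy as np
import pytest

from frfx.radiomics import (
    DIRECTIONS_3D,
    glcm_features,
    glcm_matrix,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    texture_features,
)
from frfx.radiomics.texture import GLCM_NAMES, TEXTURE_NAMES

from oracles import naive_glcm_matrix, naive_glcm_features


def _random_region(seed, size=5, n_levels=4):
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, n_levels + 1, size=(size, size, size))
    mask = rng.uniform(size=(size, size, size)) < 0.7
    mask.ravel()[0] = True  # never empty
    return levels, mask, n_levels


class TestGlcm:
    def test_alternating_line_hand_counted(self):
        """1-D pattern 121212 along axis 0: P has only (1,2)/(2,1) pairs,
        so contrast = 1 and joint entropy = 1 bit for the axial offset."""
        levels = np.ones((6, 3, 3), dtype=np.int64)
        mask = np.zeros((6, 3, 3), dtype=bool)
        levels[:, 1, 1] = [1, 2, 1, 2, 1, 2]
        mask[:, 1, 1] = True
        f = glcm_features(levels, mask, n_levels=2, directions=[(1, 0, 0)])
        assert f["glcm_Contrast"] == pytest.approx(1.0)
        assert f["glcm_JointEntropy"] == pytest.approx(1.0)
        assert f["glcm_MaximumProbability"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("direction", [(1, 0, 0), (0, 1, 0), (1, -1, 1)])
    def test_matrix_matches_naive_counting(self, seed, direction):
        levels, mask, n = _random_region(seed)
        ours = glcm_matrix(levels, mask, direction, n)
        ref = naive_glcm_matrix(levels, mask, direction, n)
        assert np.allclose(ours, ref, atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_features_match_naive_oracle(self, seed):
        levels, mask, n = _random_region(seed, size=6)
        P = glcm_matrix(levels, mask, (1, 0, 0), n)
        if P.sum() == 0:
            pytest.skip("no axial pairs in this draw")
        ours = glcm_features(levels, mask, n, directions=[(1, 0, 0)])
        ref = naive_glcm_features(P)
        for name in GLCM_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-9), name

    def test_direction_order_irrelevant(self):
        levels, mask, n = _random_region(42)
        a = glcm_features(levels, mask, n, directions=DIRECTIONS_3D)
        b = glcm_features(levels, mask, n, directions=list(DIRECTIONS_3D)[::-1])
        for name in GLCM_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-12)

    def test_constant_region_degenerate_constants(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        mask = np.ones((4, 4, 4), dtype=bool)
        f = glcm_features(levels, mask, n_levels=1)
        assert f["glcm_Contrast"] == 0.0
        assert f["glcm_Correlation"] == 1.0
        assert f["glcm_JointEntropy"] == 0.0
        assert f["glcm_MaximumProbability"] == 1.0


class TestGlrlm:
    def test_single_line_runs(self):
        """Line 1 1 2 2 2 1 along x: runs (1,2),(2,3),(1,1) axially."""
        levels = np.ones((6, 3, 3), dtype=np.int64)
        mask = np.zeros((6, 3, 3), dtype=bool)
        levels[:, 0, 0] = [1, 1, 2, 2, 2, 1]
        mask[:, 0, 0] = True
        f = glrlm_features(levels, mask, n_levels=2, directions=[(1, 0, 0)])
        # N_runs=3; SRE = (1/4 + 1/9 + 1)/3; LRE = (4 + 9 + 1)/3; RP = 3/6
        assert f["glrlm_ShortRunEmphasis"] == pytest.approx((0.25 + 1 / 9 + 1) / 3)
        assert f["glrlm_LongRunEmphasis"] == pytest.approx(14.0 / 3.0)
        assert f["glrlm_RunPercentage"] == pytest.approx(0.5)

    def test_constant_region_single_runs(self):
        """All-equal 4x4x4 block: along an axis every line is one run of 4,
        so LRE = 16 for axial directions."""
        levels = np.ones((4, 4, 4), dtype=np.int64)
        mask = np.ones((4, 4, 4), dtype=bool)
        f = glrlm_features(levels, mask, n_levels=1, directions=[(1, 0, 0)])
        assert f["glrlm_LongRunEmphasis"] == pytest.approx(16.0)
        assert f["glrlm_RunPercentage"] == pytest.approx(16 / 64)
        assert f["glrlm_GrayLevelVariance"] == 0.0

    def test_direction_symmetry(self):
        levels, mask, n = _random_region(17, size=6)
        a = glrlm_features(levels, mask, n, directions=DIRECTIONS_3D)
        b = glrlm_features(levels, mask, n, directions=list(DIRECTIONS_3D)[::-1])
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)


class TestGlszm:
    def test_hand_counted_zones(self):
        """Two separated zones of level 1 (sizes 2 and 1) and one zone of
        level 2 (size 3) in a flat grid."""
        levels = np.ones((5, 5, 1), dtype=np.int64) * 9  # filler outside mask
        mask = np.zeros((5, 5, 1), dtype=bool)
        # zone A: level 1, two 26-connected voxels
        levels[0, 0, 0] = levels[0, 1, 0] = 1
        mask[0, 0, 0] = mask[0, 1, 0] = True
        # zone B: level 1, isolated voxel
        levels[4, 4, 0] = 1
        mask[4, 4, 0] = True
        # zone C: level 2, an L of three voxels
        levels[2, 2, 0] = levels[3, 2, 0] = levels[3, 3, 0] = 2
        mask[2, 2, 0] = mask[3, 2, 0] = mask[3, 3, 0] = True
        f = glszm_features(levels, mask, n_levels=2)
        # 3 zones over 6 voxels; sizes {2, 1, 3}
        assert f["glszm_ZonePercentage"] == pytest.approx(0.5)
        assert f["glszm_SmallAreaEmphasis"] == pytest.approx((1 / 4 + 1 + 1 / 9) / 3)
        assert f["glszm_LargeAreaEmphasis"] == pytest.approx((4 + 1 + 9) / 3)
        assert f["glszm_GrayLevelNonUniformity"] == pytest.approx((2**2 + 1**2) / 3)


class TestGldm:
    def test_constant_block_dependencies(self):
        """In an all-equal 3x3x3 block every neighbour matches, so the centre
        voxel has dependence 26, faces 17, edges 11, corners 7."""
        levels = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.ones((3, 3, 3), dtype=bool)
        f = gldm_features(levels, mask, n_levels=1)
        # dependence sizes j = neighbours + 1: 8 corners->8, 12 edges->12,
        # 6 faces->18, 1 centre->27
        expected_lde = (8 * 8**2 + 12 * 12**2 + 6 * 18**2 + 1 * 27**2) / 27
        assert f["gldm_LargeDependenceEmphasis"] == pytest.approx(expected_lde)
        assert f["gldm_GrayLevelVariance"] == 0.0

    def test_alpha_widens_dependence(self):
        levels, mask, n = _random_region(23, size=5)
        tight = gldm_features(levels, mask, n, alpha=0.0)
        loose = gldm_features(levels, mask, n, alpha=10.0)
        assert (
            loose["gldm_LargeDependenceEmphasis"]
            >= tight["gldm_LargeDependenceEmphasis"]
        )


class TestNgtdm:
    def test_constant_region_conventions(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        mask = np.ones((4, 4, 4), dtype=bool)
        f = ngtdm_features(levels, mask, n_levels=1)
        assert f["ngtdm_Coarseness"] == pytest.approx(1e6)
        assert f["ngtdm_Contrast"] == 0.0
        assert f["ngtdm_Busyness"] == 0.0

    def test_two_tone_coarseness_by_hand(self):
        """Split 2x2x2 all-in-mask block: each voxel has 7 neighbours."""
        levels = np.ones((2, 2, 2), dtype=np.int64)
        levels[1] = 2
        mask = np.ones((2, 2, 2), dtype=bool)
        f = ngtdm_features(levels, mask, n_levels=2)
        # every voxel's neighbour mean = (3*own + 4*other)/7 -> |i - A| = 4/7
        s = 4 * 4.0 / 7.0
        denom = 0.5 * s + 0.5 * s
        assert f["ngtdm_Coarseness"] == pytest.approx(1.0 / denom)


class TestCatalogueTexture:
    def test_all_71_names_finite_on_phantom_region(self, sample_case):
        img, seg = sample_case.post
        mask = seg.observed == 2
        from frfx.radiomics import discretize

        vals = img.voxels[mask].astype(float)
        bins, _ = discretize(vals, 25.0)
        levels = np.zeros(mask.shape, dtype=np.int64)
        levels[mask] = bins
        f = texture_features(levels, mask, int(bins.max()))
        assert set(f) == set(TEXTURE_NAMES)
        assert len(TEXTURE_NAMES) == 71
        assert np.all(np.isfinite(list(f.values())))

    def test_minimum_support_enforced(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, :2] = True
        with pytest.raises(ValueError, match="27"):
            texture_features(levels, mask, 1)
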