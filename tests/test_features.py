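"""Feature math: morphology, first-order statistics, texture families.

Every texture family is checked on small random VOIs against independent
brute-force enumerations (pair counting, flood fill, exhaustive border
search, neighbor enumeration) to 1e-9 relative tolerance.
"""

import numpy as np
import pytest

import oracles
from conftest import make_voi, make_volume_pair
from radsurv import texture
from radsurv.features import (
    FeatureId,
    FeatureRegistry,
    extract_all,
    firstorder_features,
    morph_features,
    morph_flatness,
    morph_volume,
)
from radsurv.preprocess import DiscretizedVoi, PrepConfig
from radsurv.scoring import published_rscore_definition
from radsurv.synthdata import PhantomSpec, generate_tumor_volume
from radsurv.volume import VoiMask


class TestMorphology:
    def test_volume_single_voxel(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert morph_volume(VoiMask(m, (1, 1, 3))) == pytest.approx(3.0)

    def test_volume_linearity(self, rng):
        m = rng.random((6, 6, 6)) < 0.5
        m[0, 0, 0] = True
        mask = VoiMask(m, (1, 1, 3))
        assert morph_volume(mask) == pytest.approx(3.0 * m.sum())

    def test_sphere_volume_analytic(self):
        spec = PhantomSpec(
            grid_shape=(48, 48, 48), spacing_mm=(0.5, 0.5, 0.5),
            semi_axes_mm=(10, 10, 10), amplitude_hu=0.0, noise_sd_hu=0.0,
        )
        _, mask = generate_tumor_volume(spec)
        assert morph_volume(mask) == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_ball_flatness_is_one(self):
        spec = PhantomSpec(
            grid_shape=(60, 60, 24), spacing_mm=(0.7, 0.7, 2.0),
            semi_axes_mm=(15, 15, 15), amplitude_hu=0.0, noise_sd_hu=0.0,
        )
        _, mask = generate_tumor_volume(spec)
        assert morph_flatness(mask) == pytest.approx(1.0, abs=0.05)

    def test_ellipsoid_421_flatness(self):
        # least/major axis-length ratio of a 40:20:10 mm ellipsoid is 0.25
        spec = PhantomSpec(
            grid_shape=(120, 70, 40), spacing_mm=(0.8, 0.8, 0.8),
            semi_axes_mm=(40, 20, 10), amplitude_hu=0.0, noise_sd_hu=0.0,
        )
        _, mask = generate_tumor_volume(spec)
        feats = morph_features(mask)
        assert feats["flatness"] == pytest.approx(0.25, abs=0.01)
        assert feats["elongation"] == pytest.approx(0.5, abs=0.01)

    def test_axis_permutation_invariance(self, rng):
        m = rng.random((7, 7, 7)) < 0.4
        m[3, 3, 3] = True
        f1 = morph_flatness(VoiMask(m, (1, 1, 1)))
        f2 = morph_flatness(VoiMask(m.transpose(2, 0, 1), (1, 1, 1)))
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_coplanar_mask_rejected(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[:, :, 2] = True
        with pytest.raises(ValueError, match="degenerate"):
            morph_flatness(VoiMask(m, (1, 1, 1)))

    def test_features_ignore_intensities(self, rng):
        # morphology must depend on the mask only
        m = rng.random((6, 6, 6)) < 0.5
        m[2, 2, 2] = m[2, 3, 2] = m[3, 2, 3] = m[4, 4, 1] = True
        mask = VoiMask(m, (1, 1, 2))
        assert morph_features(mask) == morph_features(mask)


class TestFirstOrder:
    def test_hand_checkable_order_statistics(self):
        vals = np.array([1.0, 2, 3, 4, 5]).reshape(5, 1, 1)
        vol, mask = make_volume_pair(vals)
        f = firstorder_features(vol, mask)
        assert f["maximum"] == 5 and f["median"] == 3 and f["percentile25"] == 2

    def test_constant_region_zero_spread(self):
        vol, mask = make_volume_pair(np.full((3, 3, 3), 9.0))
        f = firstorder_features(vol, mask)
        assert f["robust_mad"] == 0 and f["variance"] == 0 and f["skewness"] == 0

    def test_robust_mad_two_pass_oracle(self, rng):
        x = rng.random(1000)
        vol, mask = make_volume_pair(x.reshape(10, 10, 10))
        got = firstorder_features(vol, mask)["robust_mad"]
        # independent two-pass recomputation
        lo, hi = np.percentile(x, [10, 90])
        sub = [v for v in x if lo <= v <= hi]
        mean_sub = sum(sub) / len(sub)
        expected = sum(abs(v - mean_sub) for v in sub) / len(sub)
        assert got == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
class TestTextureOracles:
    """Vectorized texture features equal plain-loop enumeration oracles."""

    def _voi(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 7, 3))  # <= 216 voxels
        return make_voi(shape=shape, n_levels=int(rng.integers(2, 6)), seed=seed)

    def test_glcm(self, seed):
        voi = self._voi(seed)
        p_oracle = oracles.glcm_matrix(voi.levels, voi.mask.values, voi.n_levels)
        np.testing.assert_allclose(texture.glcm_matrix(voi), p_oracle, rtol=1e-9, atol=1e-12)
        expected = oracles.glcm_features(p_oracle)
        got = texture.glcm_features(voi)
        for name, val in expected.items():
            assert got[name] == pytest.approx(val, rel=1e-9, abs=1e-9), name

    def test_glszm(self, seed):
        voi = self._voi(seed)
        mat = oracles.glszm_matrix(voi.levels, voi.mask.values, voi.n_levels)
        np.testing.assert_allclose(texture.glszm_matrix(voi), mat)
        expected = oracles.zone_features(mat, voi.mask.n_voxels, "zone", "zone_size")
        got = texture.glszm_features(voi)
        for name, val in expected.items():
            assert got[name] == pytest.approx(val, rel=1e-9, abs=1e-9), name

    def test_gldzm(self, seed):
        voi = self._voi(seed)
        mat = oracles.gldzm_matrix(voi.levels, voi.mask.values, voi.n_levels)
        np.testing.assert_allclose(texture.gldzm_matrix(voi), mat)
        expected = oracles.zone_features(mat, voi.mask.n_voxels, "distance", "zone_distance")
        got = texture.gldzm_features(voi)
        for name, val in expected.items():
            assert got[name] == pytest.approx(val, rel=1e-9, abs=1e-9), name

    def test_ngldm(self, seed):
        voi = self._voi(seed)
        mat = oracles.ngldm_matrix(voi.levels, voi.mask.values, voi.n_levels)
        np.testing.assert_allclose(texture.ngldm_matrix(voi), mat)
        expected = oracles.ngldm_features(mat)
        got = texture.ngldm_features(voi)
        for name, val in expected.items():
            assert got[name] == pytest.approx(val, rel=1e-9, abs=1e-9), name


class TestTextureProperties:
    def test_single_level_degenerate(self):
        m = np.ones((3, 3, 3), dtype=bool)
        levels = np.ones((3, 3, 3), dtype=np.int32)
        voi = DiscretizedVoi(levels, 4, VoiMask(m, (1, 1, 1)), binning={})
        f = texture.glcm_features(voi)
        assert f["joint_entropy"] == 0 and f["contrast"] == 0 and f["cluster_shade"] == 0
        fz = texture.glszm_features(voi)
        # one zone of 27 voxels at level 1
        assert fz["large_zone_high_gray_level_emphasis"] == pytest.approx(27**2)

    def test_glcm_gray_inversion_symmetry(self, rng):
        voi = make_voi(shape=(5, 5, 4), n_levels=4, seed=7)
        inv_levels = np.where(voi.mask.values, voi.n_levels + 1 - voi.levels, 0)
        inv = DiscretizedVoi(inv_levels, voi.n_levels, voi.mask, binning={})
        f, fi = texture.glcm_features(voi), texture.glcm_features(inv)
        assert fi["joint_entropy"] == pytest.approx(f["joint_entropy"], rel=1e-12)
        assert fi["contrast"] == pytest.approx(f["contrast"], rel=1e-12)
        assert fi["cluster_shade"] == pytest.approx(-f["cluster_shade"], rel=1e-9)

    def test_matrices_normalize_to_one(self, rng):
        voi = make_voi(shape=(6, 6, 4), n_levels=5, seed=11)
        assert texture.glcm_matrix(voi).sum() == pytest.approx(1.0)
        for mat_fn in (texture.glszm_matrix, texture.gldzm_matrix, texture.ngldm_matrix):
            mat = mat_fn(voi)
            assert (mat >= 0).all()
            assert (mat / mat.sum()).sum() == pytest.approx(1.0)

    def test_zone_doubling_preserves_normalized_features(self):
        # duplicating the VOI content in a disjoint region doubles the zone
        # count but leaves probability-normalized features unchanged
        voi = make_voi(shape=(4, 4, 3), n_levels=3, seed=5)
        shape = voi.levels.shape
        big_levels = np.zeros((shape[0] * 2 + 3, shape[1], shape[2]), dtype=np.int32)
        big_mask = np.zeros_like(big_levels, dtype=bool)
        big_levels[: shape[0]] = voi.levels
        big_mask[: shape[0]] = voi.mask.values
        big_levels[shape[0] + 3 :] = voi.levels
        big_mask[shape[0] + 3 :] = voi.mask.values
        big = DiscretizedVoi(big_levels, 3, VoiMask(big_mask, (1, 1, 1)), binning={})
        assert texture.glszm_matrix(big).sum() == 2 * texture.glszm_matrix(voi).sum()
        f1, f2 = texture.glszm_features(voi), texture.glszm_features(big)
        for name in ("small_zone_emphasis", "large_zone_high_gray_level_emphasis", "zone_entropy"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-12)

    def test_ngldm_dependence_counts(self):
        # uniform 3x3x3 solid: center voxel has all 26 neighbors equal
        m = np.ones((3, 3, 3), dtype=bool)
        voi = DiscretizedVoi(np.ones((3, 3, 3), np.int32), 2, VoiMask(m, (1, 1, 1)), binning={})
        mat = texture.ngldm_matrix(voi)
        assert mat[0, 26] == 1  # the center
        # isolated differing voxel has dependence 0
        levels = np.ones((3, 3, 3), np.int32)
        levels[1, 1, 1] = 2
        voi2 = DiscretizedVoi(levels, 2, VoiMask(m, (1, 1, 1)), binning={})
        mat2 = texture.ngldm_matrix(voi2)
        assert mat2[1, 0] == 1

    def test_gldzm_single_voxel_and_cube(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        voi = DiscretizedVoi(np.where(m, 2, 0).astype(np.int32), 3, VoiMask(m, (1, 1, 1)), binning={})
        mat = texture.gldzm_matrix(voi)
        assert mat.shape[1] == 1 and mat[1, 0] == 1  # distance 1, level 2
        assert texture.gldzm_features(voi)["large_distance_high_gray_level_emphasis"] == pytest.approx(4.0)
        solid = np.ones((4, 4, 4), dtype=bool)
        voi2 = DiscretizedVoi(np.ones((4, 4, 4), np.int32), 2, VoiMask(solid, (1, 1, 1)), binning={})
        mat2 = texture.gldzm_matrix(voi2)
        assert mat2.sum() == 1 and mat2[0, 0] == 1  # one zone touching the border

    def test_affine_intensity_invariance_end_to_end(self, rng):
        vals = rng.random((8, 8, 6)) * 50 + 20
        vol, mask = make_volume_pair(vals)
        vol2, _ = make_volume_pair(vals * 2.0 - 30.0)
        from radsurv.preprocess import discretize

        f1 = texture.glcm_features(discretize(vol, mask, 16))
        f2 = texture.glcm_features(discretize(vol2, mask, 16))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-12)


class TestExtractAll:
    def test_published_signature_registry(self):
        # restricting the registry to the published signature yields exactly
        # the 15 named features
        ids = [fid for fid, _ in published_rscore_definition().terms]
        registry = FeatureRegistry.from_ids(ids)
        spec = PhantomSpec(seed=3)
        vol, mask = generate_tumor_volume(spec)
        vals = extract_all(vol, vol, mask, registry=registry)
        assert set(vals) == set(ids) and len(vals) == 15
        assert all(np.isfinite(v) for v in vals.values())

    def test_identical_phases_give_identical_features(self):
        spec = PhantomSpec(seed=4)
        vol, mask = generate_tumor_volume(spec)
        registry = FeatureRegistry.default(phases=("AP", "PVP"), transforms=("N",))
        vals = extract_all(vol, vol, mask, registry=registry)
        for fid, v in vals.items():
            f = FeatureId.parse(fid)
            if f.phase == "AP":
                twin = str(FeatureId("PVP", f.transform, f.family, f.name))
                assert vals[twin] == v

    def test_homogeneous_phantom_zero_texture(self):
        spec = PhantomSpec(amplitude_hu=0.0, noise_sd_hu=0.0, seed=0)
        vol, mask = generate_tumor_volume(spec)
        registry = FeatureRegistry.from_ids(
            ["AP|N|glcm|joint_entropy", "AP|N|glcm|contrast", "AP|N|glcm|cluster_shade"]
        )
        vals = extract_all(vol, None, mask, registry=registry)
        assert all(v == 0.0 for v in vals.values())

    def test_missing_phase_error_carries_context(self):
        spec = PhantomSpec(seed=5)
        vol, mask = generate_tumor_volume(spec)
        registry = FeatureRegistry.from_ids(["PVP|N|glcm|joint_entropy"])
        with pytest.raises(ValueError, match="PVP"):
            extract_all(vol, None, mask, registry=registry)

    def test_deterministic_ordering(self):
        spec = PhantomSpec(seed=6)
        vol, mask = generate_tumor_volume(spec)
        registry = FeatureRegistry.default(phases=("AP",), transforms=("N",))
        v1 = extract_all(vol, None, mask, registry=registry)
        v2 = extract_all(vol, None, mask, registry=registry)
        assert list(v1) == list(v2) and v1 == v2
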