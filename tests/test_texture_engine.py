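import numpy as np
import pytest

import oracles
from conftest import random_masked_patch, random_quantized_patch
from eotrh_texture.errors import EmptyROIError
from eotrh_texture import texture_engine as te


def qp(levels, n_g=None, mask=None):
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    return te.QuantizedPatch(
        levels=levels, n_g=int(n_g or levels.max()), bin_width=1.0, mask=np.asarray(mask, bool)
    )


def checkerboard(n=6):
    return (np.indices((n, n)).sum(axis=0) % 2) + 1


class TestDiscretize:
    def test_floor_rule_on_worked_values(self):
        patch = np.zeros((4, 4))
        patch[0, :4] = [0.0, 24.9, 25.0, 50.0]
        mask = np.ones((4, 4), dtype=bool)
        q = te.discretize(patch, mask, bin_width=25.0)
        assert list(q.levels[0]) == [1, 1, 2, 3]
        assert q.n_g == 3

    def test_constant_region_is_single_level(self):
        q = te.discretize(np.full((5, 5), 7.3), np.ones((5, 5), bool), 25.0)
        assert q.n_g == 1
        assert (q.masked_levels == 1).all()

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError, match="bin_width"):
            te.discretize(np.zeros((5, 5)), np.ones((5, 5), bool), 0.0)

    def test_too_few_masked_pixels_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, :3] = True
        with pytest.raises(EmptyROIError):
            te.discretize(np.zeros((5, 5)), mask, 1.0)

    def test_shift_invariance(self, rng):
        patch, mask = random_masked_patch(rng)
        q1 = te.discretize(patch, mask, 10.0)
        q2 = te.discretize(patch + 123.4, mask, 10.0)
        np.testing.assert_array_equal(q1.levels, q2.levels)


class TestFirstOrder:
    def test_worked_example_1234(self):
        patch = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.ones((2, 2), dtype=bool)
        f = te.fos_features(patch, mask, bin_width=1.0)
        assert f["mean"] == pytest.approx(2.5)
        assert f["range"] == pytest.approx(3.0)
        assert f["variance"] == pytest.approx(1.25)
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)
        # linear interpolation between order statistics
        assert f["percentile_10"] == pytest.approx(1.3)
        assert f["energy"] == pytest.approx(1 + 4 + 9 + 16)
        assert f["root_mean_squared"] == pytest.approx(np.sqrt(30 / 4))

    def test_constant_region_degeneracies(self):
        patch = np.full((6, 6), 42.0)
        mask = np.ones((6, 6), dtype=bool)
        f = te.fos_features(patch, mask)
        assert f["mean"] == 42.0
        assert f["variance"] == 0.0
        assert f["range"] == 0.0
        assert f["uniformity"] == 1.0
        assert f["entropy"] == 0.0
        assert np.isnan(f["skewness"])
        assert np.isnan(f["kurtosis"])

    def test_moments_match_direct_formulas(self, rng):
        patch, mask = random_masked_patch(rng)
        f = te.fos_features(patch, mask)
        x = patch[mask]
        assert f["variance"] == pytest.approx(np.mean((x - x.mean()) ** 2))
        assert f["mean_absolute_deviation"] == pytest.approx(
            np.mean(np.abs(x - x.mean()))
        )
        m2 = np.mean((x - x.mean()) ** 2)
        assert f["kurtosis"] == pytest.approx(np.mean((x - x.mean()) ** 4) / m2**2)
        assert f["interquartile_range"] == pytest.approx(
            np.percentile(x, 75) - np.percentile(x, 25)
        )


class TestGLCM:
    def test_striped_patch_horizontal_pairs(self):
        levels = np.array([[1, 1, 2], [1, 1, 2], [1, 1, 2]])
        q = qp(levels, mask=np.ones((3, 3), bool))
        mats = te.glcm_matrix(q, directions=(0,))
        p = mats[0]
        # 6 ordered horizontal pairs: (1,1) x3, (1,2) x3; symmetrized
        np.testing.assert_allclose(p, [[0.5, 0.25], [0.25, 0.0]])
        f = te._glcm_features_single(p)
        assert f["contrast"] == pytest.approx(0.5)

    def test_checkerboard_contrast_one(self):
        q = qp(checkerboard(), mask=np.ones((6, 6), bool))
        p = te.glcm_matrix(q, directions=(0,))[0]
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]])
        f = te._glcm_features_single(p)
        assert f["contrast"] == pytest.approx(1.0)

    def test_constant_patch_degeneracies(self):
        q = qp(np.ones((5, 5), dtype=int), mask=np.ones((5, 5), bool))
        f = te.glcm_features(q)
        assert f["contrast"] == 0.0
        assert np.isnan(f["correlation"])
        assert f["joint_energy"] == 1.0
        assert f["maximum_probability"] == 1.0

    def test_all_nan_when_no_valid_pairs(self):
        # isolated masked pixels only: no pair lies fully inside the mask
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = mask[0, 3] = mask[3, 0] = mask[3, 3] = True
        levels = np.where(mask, 1, 0)
        with pytest.warns(UserWarning, match="no valid"):
            f = te.glcm_features(qp(levels, n_g=1, mask=mask))
        assert all(np.isnan(v) for v in f.values())

    def test_normalization_per_direction(self, rng):
        for _ in range(5):
            q = random_quantized_patch(rng)
            for angle, p in te.glcm_matrix(q).items():
                assert p.sum() == pytest.approx(1.0)


class TestNGTDM:
    def test_center_spike_hand_computed(self):
        levels = np.array([[1, 1, 1], [1, 2, 1], [1, 1, 1]])
        q = qp(levels, mask=np.ones((3, 3), bool))
        n, p, s = te.ngtdm_vectors(q)
        assert s[1] == pytest.approx(1.0)  # |2 - 1| for the centre
        # corners: neighbours {1,1,2} -> |1 - 4/3|; edges: {1,1,1,2,1} -> |1 - 6/5|
        assert s[0] == pytest.approx(4 * (1 / 3) + 4 * (1 / 5))
        assert n.tolist() == [8.0, 1.0]

    def test_constant_patch_caps_coarseness(self):
        q = qp(np.ones((4, 4), dtype=int), mask=np.ones((4, 4), bool))
        f = te.ngtdm_features(q)
        assert f["coarseness"] == te.COARSENESS_CAP
        assert f["contrast"] == 0.0

    def test_two_level_balanced_busyness_positive(self):
        levels = np.ones((4, 4), dtype=int)
        levels[:, 2:] = 2
        q = qp(levels, mask=np.ones((4, 4), bool))
        f = te.ngtdm_features(q)
        assert np.isfinite(f["busyness"]) and f["busyness"] > 0


class TestGLDM:
    def test_constant_full_mask_dependence_counts(self):
        q = qp(np.ones((3, 3), dtype=int), mask=np.ones((3, 3), bool))
        mat = te.gldm_matrix(q, delta=1, alpha=0)
        # corners have 3 dependent neighbours, edges 5, centre 8
        assert mat[0, 3] == 4
        assert mat[0, 5] == 4
        assert mat[0, 8] == 1
        assert mat.sum() == 9

    def test_alpha_saturation_makes_all_neighbours_dependent(self, rng):
        q = random_quantized_patch(rng)
        mat = te.gldm_matrix(q, alpha=q.n_g)  # alpha >= n_g - 1
        mat0 = te.gldm_matrix(
            te.QuantizedPatch(
                levels=np.where(q.mask, 1, 0), n_g=1, bin_width=1.0, mask=q.mask
            ),
            alpha=0,
        )
        # same dependence-count distribution as a constant patch
        np.testing.assert_array_equal(mat.sum(axis=0), mat0.sum(axis=0))

    def test_checkerboard_matches_brute_force(self):
        levels = checkerboard(6)
        mask = np.ones((6, 6), dtype=bool)
        q = qp(levels, mask=mask)
        np.testing.assert_array_equal(
            te.gldm_matrix(q), oracles.gldm_bf(levels, mask, q.n_g)
        )
        f = te.gldm_features(q)
        assert np.isfinite(f["dependence_variance"])


class TestGLRLM:
    def test_single_row_run_enumeration(self):
        levels = np.array([[1, 1, 1, 2, 2, 3]])
        q = qp(levels, mask=np.ones((1, 6), bool))
        mat = te.glrlm_matrix(q, directions=(0,))[0]
        assert mat[0, 2] == 1  # level 1, length 3
        assert mat[1, 1] == 1  # level 2, length 2
        assert mat[2, 0] == 1  # level 3, length 1
        assert mat.sum() == 3
        f = te._rl_features(mat, q.n_p)
        assert f["run_percentage"] == pytest.approx(0.5)

    def test_constant_patch_long_runs(self):
        n = 5
        q = qp(np.ones((n, n), dtype=int), mask=np.ones((n, n), bool))
        mat = te.glrlm_matrix(q, directions=(0,))[0]
        assert mat[0, n - 1] == n
        f = te._rl_features(mat, q.n_p)
        assert f["long_run_emphasis"] == pytest.approx(n**2)

    def test_checkerboard_all_unit_runs_axially(self):
        q = qp(checkerboard(), mask=np.ones((6, 6), bool))
        for angle in (0, 90):
            mat = te.glrlm_matrix(q, directions=(angle,))[angle]
            f = te._rl_features(mat, q.n_p)
            assert f["short_run_emphasis"] == 1.0
            assert f["long_run_emphasis"] == 1.0
            assert f["run_percentage"] == 1.0

    def test_run_pixel_conservation(self, rng):
        for _ in range(10):
            q = random_quantized_patch(rng)
            for angle, mat in te.glrlm_matrix(q).items():
                j = np.arange(1, mat.shape[1] + 1)
                assert np.sum(mat * j[None, :]) == q.n_p


class TestGLSZM:
    def test_constant_patch_single_zone(self):
        q = qp(np.ones((5, 5), dtype=int), mask=np.ones((5, 5), bool))
        f = te.glszm_features(q)
        assert f["zone_percentage"] == pytest.approx(1.0 / 25.0)
        mat = te.glszm_matrix(q)
        assert mat.sum() == 1
        assert mat[0, 24] == 1

    def test_two_disjoint_blobs_counted(self):
        levels = np.ones((6, 6), dtype=int)
        levels[0, 0:2] = 2
        levels[4, 3:5] = 2
        q = qp(levels, mask=np.ones((6, 6), bool))
        mat = te.glszm_matrix(q)
        assert mat[1, 1] == 2  # two zones of level 2, size 2

    def test_checkerboard_merges_diagonals_into_two_zones(self):
        q = qp(checkerboard(), mask=np.ones((6, 6), bool))
        mat = te.glszm_matrix(q)
        assert mat.sum() == 2  # 8-connectivity joins same-level diagonals

    def test_zone_size_conservation(self, rng):
        for _ in range(10):
            q = random_quantized_patch(rng)
            mat = te.glszm_matrix(q)
            j = np.arange(1, mat.shape[1] + 1)
            assert np.sum(mat * j[None, :]) == q.n_p


class TestBruteForceEquivalence:
    """Every matrix equals exhaustive enumeration on random masked patches."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_matrices_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        q = random_quantized_patch(rng)
        levels, mask, n_g = q.levels, q.mask, q.n_g
        for angle, p in te.glcm_matrix(q).items():
            ref = oracles.glcm_bf(levels, mask, n_g, angle)
            np.testing.assert_allclose(p, ref, atol=1e-12)
        for angle, mat in te.glrlm_matrix(q).items():
            ref = oracles.glrlm_bf(levels, mask, n_g, angle)
            np.testing.assert_array_equal(mat[:, : ref.shape[1]], ref)
            assert mat[:, ref.shape[1] :].sum() == 0
        ref = oracles.glszm_bf(levels, mask, n_g)
        mat = te.glszm_matrix(q)
        np.testing.assert_array_equal(mat[:, : ref.shape[1]], ref)
        np.testing.assert_array_equal(te.gldm_matrix(q), oracles.gldm_bf(levels, mask, n_g))
        n, p_vec, s = te.ngtdm_vectors(q)
        n_ref, p_ref, s_ref = oracles.ngtdm_bf(levels, mask, n_g)
        np.testing.assert_allclose(n, n_ref, atol=1e-12)
        np.testing.assert_allclose(s, s_ref, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_gldm_nonzero_alpha_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        q = random_quantized_patch(rng)
        np.testing.assert_array_equal(
            te.gldm_matrix(q, alpha=1), oracles.gldm_bf(q.levels, q.mask, q.n_g, alpha=1)
        )


class TestFullPanel:
    def test_93_canonical_names(self, rng):
        patch, mask = random_masked_patch(rng)
        feats = te.extract_all(patch, mask)
        assert list(feats) == te.feature_manifest()
        assert len(feats) == 93

    def test_family_counts(self):
        counts = {fam: len(names) for fam, names in te.FAMILY_NAMES.items()}
        assert counts == {"FOS": 18, "GLCM": 24, "NGTDM": 5, "GLDM": 14, "GLRLM": 16, "GLSZM": 16}

    def test_shipped_manifest_matches_code(self):
        assert te.read_shipped_manifest() == te.feature_manifest()

    def test_rotation_invariance_of_direction_averaged_families(self, rng):
        patch, mask = random_masked_patch(rng)
        f1 = te.extract_all(patch, mask)
        f2 = te.extract_all(np.rot90(patch), np.rot90(mask))
        for key in f1:
            if key.startswith(("glcm_", "glrlm_")):
                assert f1[key] == pytest.approx(f2[key], abs=1e-9), key

    def test_intensity_shift_invariance_of_matrix_families(self, rng):
        patch, mask = random_masked_patch(rng)
        f1 = te.extract_all(patch, mask, bin_width=10.0)
        f2 = te.extract_all(patch + 500.0, mask, bin_width=10.0)
        for key in f1:
            if not key.startswith("fos_"):
                assert f1[key] == pytest.approx(f2[key], abs=1e-9), key

    def test_determinism(self, rng):
        patch, mask = random_masked_patch(rng)
        assert te.extract_all(patch, mask) == te.extract_all(patch.copy(), mask.copy())
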