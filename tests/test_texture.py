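import numpy as np
import pytest
from skimage.feature import graycomatrix

from dcedyn import texture
from dcedyn.texture import (DegenerateMatrixError, HARALICK_NAMES,
                            NEIGHBOR_OFFSETS, glcm, haralick, lbp_codes,
                            lcp_features, n_transitions, quantize,
                            ulbp_histogram, uniform_codes)

from conftest import patch_stack


def brute_force_glcm(levels2d, n_levels):
    """Exhaustive double loop over all ordered 8-connected pairs in a patch."""
    H, W = levels2d.shape
    mat = np.zeros((n_levels, n_levels))
    for r in range(H):
        for c in range(W):
            for dr, dc in NEIGHBOR_OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    mat[levels2d[r, c], levels2d[rr, cc]] += 1
    return mat / mat.sum()


def brute_force_lbp(patch, r, c):
    """Per-voxel comparison oracle for the 8-bit code."""
    code = 0
    for p, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        if patch[r + dr, c + dc] < patch[r, c]:
            code |= 1 << p
    return code


class TestQuantize:
    def test_constant_region_maps_to_level_zero(self):
        q, bounds = quantize(np.full((3, 10), 7.0))
        assert (q == 0).all()

    def test_identity_on_integer_levels(self):
        vals = np.arange(16, dtype=float)
        q, _ = quantize(vals, levels=16)
        assert np.array_equal(q, np.arange(16))

    def test_bounds_are_global_over_time(self):
        stack = np.array([[0.0, 1.0], [10.0, 11.0]])  # 2 frames
        q, (lo, hi) = quantize(stack, levels=16)
        assert (lo, hi) == (0.0, 11.0)
        assert q[0].max() < q[1].min()  # later frame occupies higher levels

    def test_uniform_values_fill_bins_evenly(self):
        rng = np.random.default_rng(0)
        q, _ = quantize(rng.random(200_000), levels=16)
        occ = np.bincount(q, minlength=16) / 200_000
        assert np.max(np.abs(occ - 1 / 16)) < 0.005  # multinomial tolerance

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.array([]))


class TestGlcm:
    def test_constant_disc_all_mass_on_diagonal(self):
        stack = patch_stack(np.full((4, 4), 3.0))
        levels, _ = quantize(stack.values)
        pairs = texture._stack_neighbor_pairs(stack)
        mat = glcm(levels[0], pairs)
        assert mat[0, 0] == 1.0 and mat.sum() == 1.0

    def test_two_voxel_pair_symmetry(self):
        stack = patch_stack(np.array([[3.0, 5.0]]))
        levels = np.array([3, 5])  # use explicit levels
        pairs = texture._stack_neighbor_pairs(stack)
        mat = glcm(levels, pairs)
        assert mat[3, 5] == 0.5 and mat[5, 3] == 0.5

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.integers(0, 8, size=(5, 5))
        stack = patch_stack(patch.astype(float))
        pairs = texture._stack_neighbor_pairs(stack)
        np.testing.assert_allclose(glcm(patch.ravel(), pairs, n_levels=8),
                                   brute_force_glcm(patch, 8))

    def test_matches_skimage_counts(self):
        """Independent cross-check: sum of the 4 symmetric skimage matrices."""
        rng = np.random.default_rng(3)
        patch = rng.integers(0, 6, size=(6, 6))
        stack = patch_stack(patch.astype(float))
        pairs = texture._stack_neighbor_pairs(stack)
        mine = glcm(patch.ravel(), pairs, n_levels=6, normalise=False)
        sk = graycomatrix(patch.astype(np.uint8), [1],
                          [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                          levels=6, symmetric=True)[:, :, 0, :].sum(axis=-1)
        np.testing.assert_allclose(mine, sk)

    def test_symmetry_and_normalisation(self):
        rng = np.random.default_rng(1)
        stack = patch_stack(rng.random((6, 6)))
        levels, _ = quantize(stack.values)
        mat = glcm(levels[0], texture._stack_neighbor_pairs(stack))
        assert np.isclose(mat.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(mat, mat.T)

    def test_pairs_do_not_cross_discs(self):
        # two adjacent single-voxel "discs": no within-disc pairs at all
        import dcedyn.roi as roi
        stack = roi.RegionStack(
            unit=roi.RegionUnit("WM", "high"),
            values=np.array([[1.0, 2.0]]),
            coords=np.array([[0, 1, 1], [0, 1, 2]]),
            sample_ids=np.array([0, 1]), frame_times_s=np.array([0.0]))
        with pytest.raises(DegenerateMatrixError):
            glcm(np.array([0, 1]), texture._stack_neighbor_pairs(stack))


class TestHaralick:
    def test_single_cell_diagonal(self):
        mat = np.zeros((16, 16))
        mat[4, 4] = 1.0
        h = dict(zip(HARALICK_NAMES, haralick(mat)))
        assert h["energy"] == 1.0
        assert h["entropy"] == 0.0
        assert h["contrast"] == 0.0
        assert h["correlation"] == 1.0  # degenerate marginals

    def test_checkerboard_hand_computation(self):
        mat = np.zeros((2, 2))
        mat[0, 1] = mat[1, 0] = 0.5
        h = dict(zip(HARALICK_NAMES, haralick(mat)))
        assert h["contrast"] == 1.0
        assert h["energy"] == 0.5
        assert np.isclose(h["correlation"], -1.0)
        # sum distribution concentrates at a+b=1: SA=1, sum variance 0
        assert np.isclose(h["sum_average"], 1.0)
        assert np.isclose(h["sum_variance"], 0.0)

    def test_vector_length_is_nine(self):
        rng = np.random.default_rng(0)
        mat = rng.random((16, 16))
        mat = (mat + mat.T) / 2
        mat /= mat.sum()
        assert len(haralick(mat)) == 9

    def test_requires_normalised_matrix(self):
        with pytest.raises(ValueError, match="normalised"):
            haralick(np.ones((4, 4)))

    def test_idm_printed_form_flag(self):
        mat = np.zeros((4, 4))
        mat[1, 2] = mat[2, 1] = 0.5
        standard = dict(zip(HARALICK_NAMES, haralick(mat)))["idm"]
        printed = dict(zip(HARALICK_NAMES,
                           haralick(mat, idm_printed_form=True)))["idm"]
        assert np.isclose(standard, 0.5)          # 1 / (1 + (1-2)^2)
        assert np.isclose(printed, 1.0 / 10.0)    # 1 / (1 + (1+2)^2)


class TestLbp:
    def test_worked_example(self):
        """Center 4 with neighbours 1..8 (E,NE,N,NW,W,SW,S,SE) -> bits 11100000."""
        patch = np.zeros((3, 3))
        patch[1, 1] = 4.0
        for value, (dr, dc) in zip(range(1, 9), NEIGHBOR_OFFSETS):
            patch[1 + dr, 1 + dc] = value
        codes, _ = lbp_codes(patch[None], np.array([[0, 1, 1]]))
        bits = [(codes[0] >> p) & 1 for p in range(8)]
        assert bits == [1, 1, 1, 0, 0, 0, 0, 0]

    def test_constant_patch_code_zero(self):
        codes, _ = lbp_codes(np.full((1, 5, 5), 2.0), np.array([[0, 2, 2]]))
        assert codes[0] == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_per_voxel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.random((4, 4))
        coords = np.array([[0, r, c] for r in range(1, 3) for c in range(1, 3)])
        codes, n_excl = lbp_codes(patch[None], coords)
        assert n_excl == 0
        expected = [brute_force_lbp(patch, r, c) for _, r, c in coords]
        assert codes.tolist() == expected

    def test_border_voxels_excluded_and_counted(self):
        patch = np.random.default_rng(0).random((1, 4, 4))
        coords = np.array([[0, 0, 0], [0, 1, 1], [0, 3, 3]])
        codes, n_excl = lbp_codes(patch, coords)
        assert n_excl == 2
        assert len(codes) == 1


class TestUlbp:
    def test_58_uniform_codes_by_enumeration(self):
        # independent transition counter via string rotation
        def transitions(code):
            bits = format(code, "08b")
            return sum(a != b for a, b in zip(bits, bits[1:] + bits[0]))
        uniform = [c for c in range(256) if transitions(c) <= 2]
        assert len(uniform) == 58
        assert sorted(uniform) == uniform_codes().tolist()
        assert all(n_transitions(c) <= 2 for c in uniform)

    def test_histogram_length_and_normalisation(self):
        rng = np.random.default_rng(0)
        hist = ulbp_histogram(rng.integers(0, 256, size=500))
        assert len(hist) == 59
        assert np.isclose(hist.sum(), 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ulbp_histogram(np.array([], dtype=int))

    def test_invariant_to_monotone_intensity_maps(self):
        """Codes depend only on order relations of intensities."""
        rng = np.random.default_rng(4)
        patch = rng.random((6, 6))
        coords = np.array([[0, r, c] for r in range(1, 5) for c in range(1, 5)])
        base, _ = lbp_codes(patch[None], coords)
        shifted, _ = lbp_codes((3.0 * patch + 10.0)[None], coords)
        assert np.array_equal(base, shifted)

    def test_pooled_mass_complement_symmetric(self):
        """Complementing every code preserves uniformity, hence the pooled bin."""
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 256, size=400)
        a = ulbp_histogram(codes)
        b = ulbp_histogram(255 - codes)
        assert np.isclose(a[58], b[58])


class TestLcp:
    def test_length_81(self):
        rng = np.random.default_rng(0)
        patch = rng.random((6, 6))
        coords = np.array([[0, r, c] for r in range(1, 5) for c in range(1, 5)])
        assert len(lcp_features(patch[None], coords)) == 81

    def test_constant_image_concentrates_one_pattern(self):
        coords = np.array([[0, r, c] for r in range(1, 5) for c in range(1, 5)])
        feats = lcp_features(np.full((1, 6, 6), 5.0), coords)
        occurrence = feats[:9]
        assert occurrence[0] == 1.0 and occurrence[1:].sum() == 0.0
        assert np.isfinite(feats).all()

    def test_least_squares_weights_recover_eighth(self):
        """Centers equal to the neighbour mean give weights of 1/8 each."""
        rng = np.random.default_rng(2)
        neigh = rng.random((40, 8))
        centers = neigh.mean(axis=1)
        w = texture._config_weights(neigh, centers)
        np.testing.assert_allclose(w, np.full(8, 1 / 8), atol=1e-6)
        # normal-equations oracle
        oracle = np.linalg.lstsq(neigh, centers, rcond=None)[0]
        np.testing.assert_allclose(w, oracle, atol=1e-6)

    def test_rank_deficient_system_is_ridge_regularised(self):
        neigh = np.ones((10, 8))
        w = texture._config_weights(neigh, np.ones(10))
        assert np.isfinite(w).all()

    def test_occurrence_block_rotation_invariant(self):
        rng = np.random.default_rng(6)
        patch = rng.random((7, 7))
        coords = np.array([[0, r, c] for r in range(1, 6) for c in range(1, 6)])
        occ = lcp_features(patch[None], coords)[:9]
        occ_rot = lcp_features(np.rot90(patch)[None].copy(), coords)[:9]
        np.testing.assert_allclose(occ, occ_rot, atol=1e-12)


class TestTrajectories:
    def test_feature_dimensions(self, template_small, phantom_subject):
        import dcedyn.roi as roi
        series, _, _, _ = phantom_subject
        stack = roi.extract_region_stack(series, template_small,
                                         roi.RegionUnit("GMC", "high"))
        assert texture.glcm_trajectory(stack).values.shape[0] == 9
        assert texture.ulbp_trajectory(series, stack).values.shape[0] == 59
        assert texture.lcp_trajectory(series, stack).values.shape[0] == 81
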