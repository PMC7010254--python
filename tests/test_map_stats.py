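"""Map thresholding, masked correlations, matrix assembly, PD repair."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogfactor import map_stats as ms

from _oracles import intersection_count_loop, nearest_pd_alternating


def _map(values, task_id="t"):
    return ms.StatMap(np.asarray(values, float), task_id=task_id)


class TestThresholdMask:
    def test_all_zero_map_gives_empty_mask(self):
        mask = ms.threshold_mask(_map(np.zeros((3, 3, 3))), z=2.3)
        assert mask.voxel_count == 0

    def test_boundary_value_excluded(self):
        v = np.zeros((2, 2, 2))
        v[0, 0, 0] = 2.3
        assert ms.threshold_mask(_map(v), z=2.3).voxel_count == 0

    def test_toy_grid_hand_count(self):
        v = np.array([3.0, 2.4, 2.3, 1.0, -3.0, 0.0, 5.1, 2.2]).reshape(2, 2, 2)
        assert ms.threshold_mask(_map(v), z=2.3).voxel_count == 3

    def test_min_cluster_prunes_isolated_voxels(self):
        v = np.zeros((8, 8, 8))
        v[0, 0, 0] = 5.0                  # singleton
        v[4:6, 4:6, 4:6] = 5.0            # 8-voxel cluster
        mask = ms.threshold_mask(_map(v), z=2.3, min_cluster=2)
        assert mask.voxel_count == 8


class TestIntersectionMask:
    def test_idempotent(self, rng):
        a = ms.ActivationMask(rng.random((5, 5, 5)) > 0.5)
        assert np.array_equal(ms.intersection_mask(a, a).values, a.values)

    def test_disjoint_masks_empty(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0], b[2] = True, True
        inter = ms.intersection_mask(ms.ActivationMask(a), ms.ActivationMask(b))
        assert inter.voxel_count == 0

    def test_random_masks_match_loop_oracle(self, rng):
        a = rng.random((24, 24, 24)) > 0.5
        b = rng.random((24, 24, 24)) > 0.5
        inter = ms.intersection_mask(ms.ActivationMask(a), ms.ActivationMask(b))
        assert inter.voxel_count == intersection_count_loop(a, b)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ms.GridMismatchError):
            ms.intersection_mask(ms.ActivationMask(np.ones((2, 2, 2), bool)),
                                 ms.ActivationMask(np.ones((3, 3, 3), bool)))


class TestSpatialCorrelation:
    def test_self_correlation_is_one(self, rng):
        a = _map(rng.standard_normal((4, 4, 4)))
        mask = ms.ActivationMask(np.ones((4, 4, 4), bool))
        r, n = ms.spatial_correlation(a, a, mask)
        assert r == pytest.approx(1.0)
        assert n == 64

    def test_affine_invariance(self, rng):
        a = _map(rng.standard_normal((4, 4, 4)))
        b = _map(2.0 * a.values + 5.0)
        mask = ms.ActivationMask(np.ones((4, 4, 4), bool))
        assert ms.spatial_correlation(a, b, mask)[0] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        a = _map(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4))
        b = _map(np.array([2.0, 1.0, 4.0, 3.0]).reshape(1, 1, 4))
        mask = ms.ActivationMask(np.ones((1, 1, 4), bool))
        r, n = ms.spatial_correlation(a, b, mask, n_min=4)
        assert r == pytest.approx(0.6)
        assert n == 4

    def test_small_mask_rejected(self, rng):
        a = _map(rng.standard_normal((3, 3, 3)))
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ms.UndefinedCorrelationError):
            ms.spatial_correlation(a, a, ms.ActivationMask(mask), n_min=10)

    def test_zero_variance_rejected(self):
        a = _map(np.full((3, 3, 3), 7.0))
        b = _map(np.arange(27, dtype=float).reshape(3, 3, 3))
        mask = ms.ActivationMask(np.ones((3, 3, 3), bool))
        with pytest.raises(ms.UndefinedCorrelationError, match="variance"):
            ms.spatial_correlation(a, b, mask, n_min=1)


class TestPairwiseMatrix:
    @pytest.mark.parametrize("p,n_pairs", [(2, 1), (5, 10), (12, 66)])
    def test_pair_counts(self, rng, p, n_pairs):
        maps = [_map(rng.standard_normal((8, 8, 8)) + 3.0, task_id=f"t{i}")
                for i in range(p)]
        mat = ms.pairwise_matrix(maps, z=2.3)
        assert mat.n_pairs == n_pairs
        assert mat.n_unique_values == n_pairs + p
        assert np.allclose(mat.r, mat.r.T)
        assert np.allclose(np.diag(mat.r), 1.0)

    def test_entries_match_per_pair_computation(self, rng):
        maps = [_map(rng.standard_normal((8, 8, 8)) + 3.0, task_id=f"t{i}")
                for i in range(5)]
        mat = ms.pairwise_matrix(maps, z=2.3)
        for i, j in itertools.combinations(range(5), 2):
            mi = ms.threshold_mask(maps[i], 2.3)
            mj = ms.threshold_mask(maps[j], 2.3)
            r, n = ms.spatial_correlation(maps[i], maps[j],
                                          ms.intersection_mask(mi, mj))
            assert mat.r[i, j] == pytest.approx(r)
            assert mat.n_voxels[i, j] == n

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reorder_invariance(self, seed):
        rng = np.random.default_rng(seed)
        maps = [_map(rng.standard_normal((6, 6, 6)) + 3.0, task_id=f"t{i}")
                for i in range(4)]
        mat = ms.pairwise_matrix(maps, z=2.3)
        perm = rng.permutation(4)
        mat_p = ms.pairwise_matrix([maps[k] for k in perm], z=2.3)
        for a in range(4):
            for b in range(4):
                i, j = perm[a], perm[b]
                assert mat_p.r[a, b] == pytest.approx(mat.r[i, j])

    def test_undefined_pair_reported(self):
        ok = _map(np.random.default_rng(0).standard_normal((4, 4, 4)) + 3.0, "ok")
        cold = _map(np.zeros((4, 4, 4)), "cold")     # nothing above threshold
        with pytest.raises(ms.UndefinedCorrelationError, match="cold"):
            ms.pairwise_matrix([ok, cold], z=2.3)


class TestNearestPdRepair:
    def _matrix(self, r):
        p = r.shape[0]
        return ms.PairCorrelationMatrix(
            tasks=[f"t{i}" for i in range(p)], r=r,
            n_voxels=np.full((p, p), 100))

    def test_pd_input_unchanged(self):
        r = np.eye(3)
        out = ms.nearest_pd_repair(self._matrix(r))
        assert not out.repaired
        assert np.array_equal(out.r, r)

    def test_indefinite_3x3_repaired(self):
        r = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        out = ms.nearest_pd_repair(self._matrix(r), eig_floor=1e-6)
        assert out.repaired
        assert np.linalg.eigvalsh(out.r).min() >= 1e-6 * (1 - 1e-6)
        assert np.allclose(np.diag(out.r), 1.0)

    def test_mildly_indefinite_matches_alternating_projection_oracle(self, rng):
        # a valid correlation matrix pushed just past the PD boundary, the
        # regime pairwise-mask assembly actually produces
        lam = rng.standard_normal((12, 4))
        cov = lam @ lam.T + 0.1 * np.eye(12)
        d = np.sqrt(np.diag(cov))
        r = cov / np.outer(d, d)
        jitter = 0.01 * rng.standard_normal((12, 12))
        r = r + jitter + jitter.T
        np.fill_diagonal(r, 1.0)
        assert np.linalg.eigvalsh(r).min() < 0
        out = ms.nearest_pd_repair(self._matrix(r), eig_floor=1e-6)
        oracle = nearest_pd_alternating(r, eig_floor=1e-6)
        assert np.max(np.abs(out.r - oracle)) < 5e-3
        assert np.linalg.eigvalsh(out.r).min() >= 1e-6 * (1 - 1e-6)

    def test_strongly_indefinite_repair_is_as_close_as_projection_oracle(self, rng):
        a = rng.uniform(-1, 1, (12, 12))
        r = 0.5 * (a + a.T)
        np.fill_diagonal(r, 1.0)
        assert np.linalg.eigvalsh(r).min() < 0
        out = ms.nearest_pd_repair(self._matrix(r), eig_floor=1e-6)
        oracle = nearest_pd_alternating(r, eig_floor=1e-6)
        assert np.linalg.eigvalsh(out.r).min() >= 1e-6 * (1 - 1e-6)
        assert np.allclose(np.diag(out.r), 1.0)
        # no farther from the input than the reference projection
        assert (np.linalg.norm(out.r - r, "fro")
                <= 1.05 * np.linalg.norm(oracle - r, "fro"))


class TestDomainConjunction:
    def test_identical_masks_unchanged(self, rng):
        m = ms.ActivationMask(rng.random((5, 5, 5)) > 0.4)
        out = ms.domain_conjunction_mask([m, m, m])
        assert np.array_equal(out.values, m.values)

    def test_any_empty_input_gives_empty_output(self, rng):
        full = ms.ActivationMask(np.ones((4, 4, 4), bool))
        empty = ms.ActivationMask(np.zeros((4, 4, 4), bool))
        assert ms.domain_conjunction_mask([full, empty, full]).voxel_count == 0

    def test_order_independent_and_matches_loop(self, rng):
        masks = [ms.ActivationMask(rng.random((6, 6, 6)) > 0.3)
                 for _ in range(3)]
        ref = ms.domain_conjunction_mask(masks).values
        for perm in itertools.permutations(range(3)):
            out = ms.domain_conjunction_mask([masks[k] for k in perm])
            assert np.array_equal(out.values, ref)
        manual = masks[0].values & masks[1].values & masks[2].values
        assert np.array_equal(ref, manual)

    def test_requires_exactly_three(self, rng):
        m = ms.ActivationMask(np.ones((3, 3, 3), bool))
        with pytest.raises(ValueError, match="exactly 3"):
            ms.domain_conjunction_mask([m, m])


class TestIO:
    def test_nifti_roundtrip(self, tmp_path, rng):
        values = rng.standard_normal((6, 6, 6))
        path = tmp_path / "task-demo_zmap.nii.gz"
        ms.save_map(values, path)
        loaded = ms.load_stat_map(path)
        assert loaded.task_id == "demo"
        assert np.allclose(loaded.values, values, atol=1e-6)

    def test_pair_matrix_roundtrip(self, tmp_path, rng):
        maps = [_map(rng.standard_normal((6, 6, 6)) + 3.0, task_id=f"t{i}")
                for i in range(3)]
        mat = ms.pairwise_matrix(maps, z=2.3)
        ms.save_pair_matrix(mat, tmp_path / "pairs")
        back = ms.load_pair_matrix(tmp_path / "pairs")
        assert back.tasks == mat.tasks
        assert np.allclose(back.r, mat.r)
        assert np.array_equal(back.n_voxels, mat.n_voxels)
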