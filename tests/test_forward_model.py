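import numpy as np
import pytest
import scipy.sparse as sp

from lesionconn import forward_model as fm
from lesionconn import geometry, lesion_adjust, phantoms


def nnls_oracle(A, y):
    """Exhaustive active-set search: best feasible support of <=6 columns."""
    from itertools import combinations
    n = A.shape[1]
    best, best_obj = np.zeros(n), float(np.sum(y ** 2))
    for k in range(1, n + 1):
        for support in combinations(range(n), k):
            sol, *_ = np.linalg.lstsq(A[:, support], y, rcond=None)
            if np.any(sol < -1e-10):
                continue
            x = np.zeros(n)
            x[list(support)] = np.clip(sol, 0, None)
            obj = float(np.sum((A @ x - y) ** 2))
            if obj < best_obj - 1e-15:
                best, best_obj = x, obj
    return best, best_obj


class TestBuildOperator:
    def test_fig2_column_sums(self, fig2_healthy):
        phantom, _, _, _ = fig2_healthy
        A = fm.build_operator(phantom.segment_table())
        assert A.shape == (15, 3)
        np.testing.assert_allclose(np.asarray(A.sum(axis=0)).ravel(),
                                   [5.0, 3.0, 3.0], atol=1e-12)
        np.testing.assert_allclose(A.data, 1.0, atol=1e-12)

    def test_single_streamline_column(self):
        pts = np.array([[0.0, 0.5, 0.5], [3.0, 0.5, 0.5]])
        seg = geometry.traverse(pts, (3, 1, 1))
        A = fm.build_operator(seg).toarray()
        np.testing.assert_allclose(A[:, 0], [1.0, 1.0, 1.0])

    def test_empty_table_gives_zero_matrix(self):
        seg = geometry.SegmentTable(np.empty(0, int), np.empty(0, int),
                                    np.empty(0), (2, 2, 2), n_streamlines=3)
        A = fm.build_operator(seg)
        assert A.shape == (8, 3) and A.nnz == 0

    def test_duplicate_records_summed(self):
        seg = geometry.SegmentTable([0, 0], [5, 5], [0.25, 0.5], (2, 2, 2),
                                    n_streamlines=1)
        assert fm.build_operator(seg)[5, 0] == pytest.approx(0.75)


class TestAugment:
    def test_single_voxel_lesion_column(self):
        A = sp.eye(8, format="csr")
        mask = np.zeros((2, 2, 2), bool)
        mask[1, 0, 1] = True
        op = fm.augment_with_lesions(A, mask)
        assert op.L.shape == (8, 1)
        v = np.ravel_multi_index((1, 0, 1), (2, 2, 2))
        assert op.L[v, 0] == -1.0 and op.L.nnz == 1
        assert op.k == {int(v): 0}

    def test_empty_mask_is_identity_augmentation(self):
        A = sp.eye(8, format="csr")
        op = fm.augment_with_lesions(A, np.zeros((2, 2, 2), bool))
        assert op.n_lesion_voxels == 0
        assert (op.matrix() != A).nnz == 0

    def test_columns_in_ascending_voxel_order(self):
        A = sp.eye(8, format="csr")
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 1] = mask[1, 1, 0] = mask[0, 1, 0] = True
        op = fm.augment_with_lesions(A, mask)
        assert op.L.shape[1] == 3
        voxels = sorted(op.k, key=op.k.get)
        assert voxels == sorted(voxels)
        for v, j in op.k.items():
            assert op.L[v, j] == -1.0


class TestFit:
    def test_biased_estimates_without_lesion_columns(self, fig2_lesioned):
        phantom, signal, _, _ = fig2_lesioned
        A = fm.build_operator(phantom.segment_table())
        res = fm.fit(A, signal.ravel())
        np.testing.assert_allclose(np.round(res.x, 3), [0.165, 0.115, 0.138])

    def test_healthy_fit_exact(self, fig2_healthy):
        phantom, signal, _, truth = fig2_healthy
        A = fm.build_operator(phantom.segment_table())
        res = fm.fit(A, signal.ravel())
        np.testing.assert_allclose(res.x, truth, atol=1e-12)
        assert res.objective <= 1e-24

    def test_augmented_fit_recovers_truth_and_loss(self, fig2_lesioned):
        phantom, signal, mask, truth = fig2_lesioned
        A = fm.build_operator(phantom.segment_table())
        op = fm.augment_with_lesions(A, mask)
        res = fm.fit(op, signal.ravel())
        np.testing.assert_allclose(res.x, truth, atol=1e-9)
        np.testing.assert_allclose(res.xL, [0.07], atol=1e-9)
        assert res.objective <= 1e-16

    def test_dimension_mismatch_raises(self, fig2_lesioned):
        phantom, signal, _, _ = fig2_lesioned
        A = fm.build_operator(phantom.segment_table())
        with pytest.raises(ValueError, match="rows"):
            fm.fit(A, signal.ravel()[:-1])

    def test_augmented_objective_never_worse(self, rng):
        """The augmented feasible set contains the standard one."""
        for _ in range(10):
            phantom = phantoms.make_crossing_phantom(2, 2, rng)
            mask = phantoms.generate_lesion_mask(phantom.wm_mask, 0.1, rng)
            signal = phantoms.apply_damage(phantom.forward_signal(), mask,
                                           0.5)
            A = fm.build_operator(phantom.segment_table())
            std = fm.fit(A, signal.ravel())
            aug = fm.fit(fm.augment_with_lesions(A, mask), signal.ravel())
            assert aug.objective <= std.objective + 1e-12

    def test_lesion_voxel_residual_zero_and_loss_identity(self, rng):
        """Where coverage >= signal, the lesion column absorbs the gap."""
        phantom = phantoms.make_crossing_phantom(2, 3, rng)
        mask = phantoms.generate_lesion_mask(phantom.wm_mask, 0.1, rng)
        signal = phantoms.apply_damage(phantom.forward_signal(), mask, 0.75)
        A = fm.build_operator(phantom.segment_table())
        op = fm.augment_with_lesions(A, mask)
        res = fm.fit(op, signal.ravel())
        coverage = op.A @ res.x
        y = signal.ravel()
        for v, col in op.k.items():
            if coverage[v] >= y[v]:
                assert abs(res.residual[v]) <= 1e-9
                assert res.xL[col] == pytest.approx(coverage[v] - y[v],
                                                    abs=1e-9)

    def test_matches_exhaustive_oracle_on_random_systems(self, rng):
        for _ in range(20):
            m, n = int(rng.integers(6, 12)), int(rng.integers(2, 7))
            A = rng.normal(size=(m, n))
            y = rng.normal(size=m)
            res = fm.fit(sp.csr_matrix(A), y)
            x_star, obj_star = nnls_oracle(A, y)
            np.testing.assert_allclose(res.x, x_star, atol=1e-8)


class TestResidualMap:
    def test_augmented_rmse_zero_everywhere(self, fig2_lesioned):
        phantom, signal, mask, _ = fig2_lesioned
        A = fm.build_operator(phantom.segment_table())
        res = fm.fit(fm.augment_with_lesions(A, mask), signal.ravel())
        rmse = fm.residual_rmse_map(res, phantom.grid_shape)
        assert np.all(rmse <= 1e-9)

    def test_standard_rmse_positive_in_lesion(self, fig2_lesioned):
        phantom, signal, mask, _ = fig2_lesioned
        A = fm.build_operator(phantom.segment_table())
        res = fm.fit(A, signal.ravel())
        rmse = fm.residual_rmse_map(res, phantom.grid_shape)
        assert rmse[mask][0] > 1e-6

    def test_healthy_forward_signal_fits_exactly(self, fig2_healthy):
        phantom, signal, _, _ = fig2_healthy
        A = fm.build_operator(phantom.segment_table())
        res = fm.fit(A, signal.ravel())
        assert np.all(fm.residual_rmse_map(res, phantom.grid_shape) <= 1e-12)
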