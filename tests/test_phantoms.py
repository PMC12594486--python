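import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lesionconn import forward_model, phantoms


class TestFig2Phantom:
    def test_crossing_voxels_sum_contributions(self, fig2_healthy):
        _, signal, _, _ = fig2_healthy
        assert signal[1, 1, 0] == pytest.approx(0.30)
        assert signal[3, 1, 0] == pytest.approx(0.30)

    def test_lesion_halves_one_voxel(self, fig2_lesioned):
        _, signal, mask, _ = fig2_lesioned
        assert mask.sum() == 1
        assert signal[mask][0] == pytest.approx(0.07)

    def test_healthy_signal_is_exact_forward_construction(self, fig2_healthy):
        phantom, signal, _, truth = fig2_healthy
        A = forward_model.build_operator(phantom.segment_table())
        y = np.asarray(A @ truth).reshape(phantom.grid_shape)
        np.testing.assert_array_equal(y, signal)

    def test_exclusive_voxel_multiplicities(self, fig2_healthy):
        """3/1/2 exclusive voxels and 2 crossings, unit lengths."""
        phantom, _, _, _ = fig2_healthy
        A = forward_model.build_operator(phantom.segment_table()).toarray()
        covered = A[(A != 0).any(axis=1)]
        assert covered.shape == (9, 3)
        np.testing.assert_allclose(covered[covered != 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(A.sum(axis=0), [5.0, 3.0, 3.0],
                                   atol=1e-12)
        n_cover = (covered != 0).sum(axis=1)
        assert (n_cover == 2).sum() == 2  # the two crossings


class TestLesionMask:
    def test_zero_target_gives_empty_mask(self, rng):
        wm = np.ones((5, 5, 5), bool)
        assert phantoms.generate_lesion_mask(wm, 0.0, rng).sum() == 0

    def test_five_percent_coverage_on_cube(self, rng):
        wm = np.ones((20, 20, 20), bool)
        mask = phantoms.generate_lesion_mask(wm, 0.05, rng)
        assert mask.sum() >= 400
        assert np.all(wm[mask])

    def test_mask_subset_of_wm(self, rng):
        wm = np.zeros((10, 10, 10), bool)
        wm[2:8, 2:8, 2:8] = True
        mask = phantoms.generate_lesion_mask(wm, 0.10, rng)
        assert np.all(wm | ~mask)
        assert mask.sum() >= 0.10 * wm.sum()

    def test_seeded_determinism(self):
        wm = np.ones((12, 12, 12), bool)
        m1 = phantoms.generate_lesion_mask(wm, 0.05, np.random.default_rng(7))
        m2 = phantoms.generate_lesion_mask(wm, 0.05, np.random.default_rng(7))
        np.testing.assert_array_equal(m1, m2)

    def test_empty_wm_raises(self, rng):
        with pytest.raises(ValueError, match="WM"):
            phantoms.generate_lesion_mask(np.zeros((3, 3, 3), bool), 0.05, rng)


class TestApplyDamage:
    @pytest.mark.parametrize("fraction,expected", [
        (0.0, 0.14), (0.5, 0.07), (1.0, 0.0)])
    def test_graded_reduction(self, fraction, expected):
        signal = np.full((2, 2, 1), 0.14)
        mask = np.zeros((2, 2, 1), bool)
        mask[0, 0, 0] = True
        out = phantoms.apply_damage(signal, mask, fraction)
        assert out[0, 0, 0] == pytest.approx(expected)
        assert np.all(out[~mask] == 0.14)

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError, match="grid"):
            phantoms.apply_damage(np.zeros((2, 2, 2)), np.zeros((3, 3, 3),
                                                                bool), 0.5)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(f1=st.floats(0, 1), f2=st.floats(0, 1), seed=st.integers(0, 99))
    def test_monotone_in_damage_fraction(self, f1, f2, seed):
        lo, hi = sorted((f1, f2))
        r = np.random.default_rng(seed)
        signal = r.uniform(0, 1, (4, 4, 2))
        mask = r.uniform(size=(4, 4, 2)) < 0.5
        assert np.all(phantoms.apply_damage(signal, mask, hi)
                      <= phantoms.apply_damage(signal, mask, lo) + 1e-15)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            phantoms.DamageLevel(1.5)


class TestCohort:
    def test_degenerate_variability_reproduces_base(self, fig2_healthy, rng):
        phantom, signal, _, _ = fig2_healthy
        subs = phantoms.synthesize_cohort(3, phantom, weight_cv=0.0,
                                          damage_level=0.0,
                                          lesion_fraction=0.05, rng=rng)
        for s in subs:
            np.testing.assert_allclose(s.signal, signal, atol=1e-15)

    def test_cohort_is_seed_reproducible(self, fig2_healthy):
        phantom, _, _, _ = fig2_healthy
        make = lambda seed: phantoms.synthesize_cohort(
            5, phantom, 0.1, 0.25, 0.05, np.random.default_rng(seed))
        a, b = make(3), make(3)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.signal, sb.signal)
            np.testing.assert_array_equal(sa.lesion_mask, sb.lesion_mask)

    def test_fresh_lesions_and_coverage(self, fig2_healthy, rng):
        phantom, _, _, _ = fig2_healthy
        subs = phantoms.synthesize_cohort(10, phantom, 0.1, 0.25, 0.05, rng)
        n_wm = phantom.wm_mask.sum()
        for s in subs:
            assert s.lesion_mask.sum() >= 0.05 * n_wm
            assert np.all(phantom.wm_mask[s.lesion_mask])
        # masks should not all coincide across subjects
        assert len({s.lesion_mask.tobytes() for s in subs}) > 1

    def test_too_small_cohort_rejected(self, fig2_healthy, rng):
        with pytest.raises(ValueError):
            phantoms.synthesize_cohort(1, fig2_healthy[0], 0.1, 0.0, 0.05,
                                       rng)


def test_crossing_phantom_identifiable(rng):
    """Every bundle of the random crossing phantom owns exclusive voxels."""
    phantom = phantoms.make_crossing_phantom(3, 4, rng)
    A = forward_model.build_operator(phantom.segment_table()).toarray()
    cover = (A != 0).sum(axis=1)
    for i in range(A.shape[1]):
        exclusive = (A[:, i] != 0) & (cover == 1)
        assert exclusive.sum() >= 2
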