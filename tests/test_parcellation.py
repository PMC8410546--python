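"""ROI machinery: PCA time courses, fPAD, mNC, influence and atlas reduction."""

import numpy as np
import pytest

import meginverse as mi
from meginverse.datatypes import Algorithm, Atlas
from meginverse.resolution import ResolutionMatrix


def chain_atlas(n_rois, dipoles_per_roi=1, n_clusters=1):
    """ROIs in a chain (1-2, 2-3, ...), evenly grouped into clusters."""
    dipole_roi = np.repeat(np.arange(1, n_rois + 1), dipoles_per_roi)
    roi_cluster = 1 + (np.arange(n_rois) * n_clusters) // n_rois
    adjacency = {(i, i + 1) for i in range(1, n_rois)}
    return Atlas(dipole_roi=dipole_roi, roi_cluster=roi_cluster, roi_adjacency=adjacency)


class TestRoiPca:
    def test_rank_one_roi_fully_explained(self):
        atlas = chain_atlas(2, dipoles_per_roi=2)
        shared = np.sin(np.linspace(0, 10, 50))
        data = np.vstack([shared, 2 * shared, shared, -shared])
        tc = mi.roi_timecourse_pca(data, atlas)
        np.testing.assert_allclose(tc.explained_variance_fraction, [1.0, 1.0])
        # ROI time course proportional to the shared signal
        c = np.corrcoef(tc.data[0], shared)[0, 1]
        assert abs(c) == pytest.approx(1.0)

    def test_single_dipole_roi_identity(self):
        atlas = chain_atlas(3)
        data = np.random.default_rng(0).standard_normal((3, 40))
        tc = mi.roi_timecourse_pca(data, atlas)
        centered = data - data.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(tc.data, centered, atol=1e-12)

    def test_two_dipole_known_covariance(self):
        # covariance [[2,1],[1,2]]: PC1 loading (1,1)/sqrt(2), explains 3/4
        rng = np.random.default_rng(1)
        n = 200_000
        common = rng.standard_normal(n)
        a = common + rng.standard_normal(n)
        b = common + rng.standard_normal(n)
        atlas = chain_atlas(1, dipoles_per_roi=2)
        tc = mi.roi_timecourse_pca(np.vstack([a, b]), atlas)
        np.testing.assert_allclose(np.abs(tc.mixing_columns[0]), [1 / np.sqrt(2)] * 2, atol=0.01)
        assert tc.explained_variance_fraction[0] == pytest.approx(0.75, abs=0.01)

    def test_sign_convention_deterministic(self):
        atlas = chain_atlas(1, dipoles_per_roi=3)
        data = np.random.default_rng(2).standard_normal((3, 30))
        tc1 = mi.roi_timecourse_pca(data, atlas)
        tc2 = mi.roi_timecourse_pca(-data, atlas)
        assert np.sum(tc1.mixing_columns[0]) > 0
        assert np.sum(tc2.mixing_columns[0]) > 0


class TestFpad:
    def test_identity_resolution_zero_everywhere(self, small_atlas):
        rm = ResolutionMatrix(np.eye(small_atlas.n_dipoles), Algorithm.MNE)
        np.testing.assert_array_equal(mi.fpad(rm, small_atlas), np.zeros(small_atlas.n_rois))

    def test_half_peaks_outside(self):
        atlas = chain_atlas(2, dipoles_per_roi=2)  # ROIs {0,1}, {2,3}
        r = np.eye(4)
        r[:, 1] = [0, 0, 1, 0]  # dipole 1's PSF peaks in ROI 2
        fp = mi.fpad(ResolutionMatrix(r, Algorithm.MNE), atlas)
        np.testing.assert_allclose(fp, [0.5, 0.0])

    def test_singleton_rois_reduce_to_pad_indicator(self, small_head, small_leadfield, identity_noise):
        atlas = mi.build_synthetic_atlas(small_head, n_rois=small_head.n_dipoles, n_clusters=2, seed=3)
        lam = mi.regularization_from_snr(small_leadfield, identity_noise, 2.5)
        op = mi.lsmn_operator(small_leadfield, identity_noise, mi.mne_weights(small_leadfield), lam)
        rm = mi.resolution_matrix(op, small_leadfield)
        fp = mi.fpad(rm, atlas)
        padv = mi.pad(rm, small_head.dipole_positions)
        # singleton ROI -> fPAD is the indicator of PAD > 0 (per-ROI order
        # follows ROI ids; map through the atlas labels)
        expected = np.zeros(atlas.n_rois)
        for d in range(atlas.n_dipoles):
            expected[atlas.dipole_roi[d] - 1] = float(padv[d] > 0)
        np.testing.assert_array_equal(fp, expected)


class TestMeanNeighborCorrelation:
    def _tc(self, data):
        return mi.parcellation.ROITimecourses(
            data=data, mixing_columns=[], explained_variance_fraction=np.ones(data.shape[0])
        )

    def test_shared_time_course_gives_one(self):
        atlas = chain_atlas(3)
        shared = np.random.default_rng(0).standard_normal(100)
        mnc, excl = mi.mean_neighbor_correlation(self._tc(np.tile(shared, (3, 1))), atlas)
        assert mnc == pytest.approx(1.0)
        assert excl == 0

    def test_independent_courses_near_zero(self):
        atlas = chain_atlas(4)
        data = np.random.default_rng(1).standard_normal((4, 7680))
        mnc, _ = mi.mean_neighbor_correlation(self._tc(data), atlas)
        assert abs(mnc) < 3 / np.sqrt(7680 * 3) * 10

    def test_constructed_correlation_half(self):
        rng = np.random.default_rng(2)
        n = 100_000
        common = rng.standard_normal(n)
        a = common + rng.standard_normal(n)
        b = common + rng.standard_normal(n)
        atlas = chain_atlas(2)
        mnc, _ = mi.mean_neighbor_correlation(self._tc(np.vstack([a, b])), atlas)
        assert mnc == pytest.approx(0.5, abs=0.02)

    def test_constant_course_excluded(self):
        atlas = chain_atlas(3)
        data = np.random.default_rng(3).standard_normal((3, 50))
        data[1] = 1.0
        # both chain pairs touch the constant ROI: everything excluded -> error
        with pytest.raises(ValueError):
            mi.mean_neighbor_correlation(self._tc(data), atlas)
        # with one extra pair avoiding ROI 2, the excluded pairs are counted
        atlas2 = chain_atlas(3)
        atlas2.roi_adjacency.add((1, 3))
        mnc, excl = mi.mean_neighbor_correlation(self._tc(data), atlas2)
        assert excl == 2 and np.isfinite(mnc)


class TestInfluence:
    def test_single_dipole_roi_is_column_norm(self):
        l = np.array([[3.0, 0.0], [4.0, 1.0]])
        atlas = chain_atlas(2)
        infl = mi.roi_influence(mi.Leadfield(l), atlas)
        np.testing.assert_allclose(infl, [5.0, 1.0])

    def test_cluster_influence_additive(self, small_leadfield, small_atlas):
        infl = mi.roi_influence(small_leadfield, small_atlas)
        cl = mi.cluster_influence(infl, small_atlas)
        assert cl.sum() == pytest.approx(infl.sum())
        assert infl.sum() == pytest.approx(small_leadfield.column_norms.sum())

    def test_hand_summed_toy(self):
        l = np.array([[1.0, 0.0, 2.0, 0.0], [0.0, 2.0, 0.0, 1.0]])
        atlas = chain_atlas(2, dipoles_per_roi=2)
        infl = mi.roi_influence(mi.Leadfield(l), atlas)
        np.testing.assert_allclose(infl, [3.0, 3.0])


class TestAllocation:
    def test_equal_influences_symmetric(self):
        counts = mi.allocate_roi_counts(np.ones(4), 8, np.full(4, 10))
        np.testing.assert_array_equal(counts, [2, 2, 2, 2])

    def test_exact_quotas(self):
        counts = mi.allocate_roi_counts(np.array([50.0, 30.0, 20.0]), 10, np.full(3, 20))
        np.testing.assert_array_equal(counts, [5, 3, 2])

    def test_floor_of_one_lifts_weak_cluster(self):
        counts = mi.allocate_roi_counts(np.array([70.0, 20.0, 10.0]), 5, np.full(3, 20))
        np.testing.assert_array_equal(counts, [3, 1, 1])

    def test_scale_invariance_and_exact_sum(self):
        rng = np.random.default_rng(5)
        infl = rng.uniform(1, 10, size=6)
        cur = np.full(6, 30)
        c1 = mi.allocate_roi_counts(infl, 23, cur)
        c2 = mi.allocate_roi_counts(1000 * infl, 23, cur)
        np.testing.assert_array_equal(c1, c2)
        assert c1.sum() == 23

    def test_target_exceeding_rois_rejected(self):
        with pytest.raises(ValueError):
            mi.allocate_roi_counts(np.ones(2), 7, np.array([3, 3]))


class TestGreedyMerge:
    def test_no_op_when_counts_match(self, small_atlas, small_leadfield):
        current = np.bincount(small_atlas.roi_cluster - 1, minlength=small_atlas.n_clusters)
        reduced, plan = mi.greedy_merge(small_atlas, small_leadfield, current)
        np.testing.assert_array_equal(reduced.dipole_roi, small_atlas.dipole_roi)
        assert plan.merges == []

    def test_weakest_pair_merges_first(self):
        # chain of 3 single-dipole ROIs with influences (1, 1, 8)
        l = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 8.0]])
        atlas = chain_atlas(3)
        reduced, plan = mi.greedy_merge(atlas, mi.Leadfield(l), np.array([2]))
        infl = mi.roi_influence(mi.Leadfield(l), reduced)
        np.testing.assert_allclose(sorted(infl), [2.0, 8.0])
        assert len(plan.merges) == 1

    def test_influence_conserved_and_variance_non_increasing(self, small_head):
        rng_seeds = range(10)
        for seed in rng_seeds:
            cfg = mi.SimulationConfig(n_sensors=40, n_dipoles=120, seed=seed)
            head = mi.build_spherical_head(cfg)
            lf = mi.compute_leadfield(head)
            atlas = mi.build_synthetic_atlas(head, n_rois=16, n_clusters=4, seed=seed)
            target = 10
            reduced, _ = mi.reduce_atlas(atlas, lf, target)
            infl0 = mi.roi_influence(lf, atlas)
            infl1 = mi.roi_influence(lf, reduced)
            assert infl1.sum() == pytest.approx(infl0.sum())
            assert reduced.n_rois == target
            # merging the weakest ROIs evens out the distribution
            assert np.var(infl1 / infl1.mean()) <= np.var(infl0 / infl0.mean()) + 1e-12

    def test_partition_preserved(self, small_atlas, small_leadfield):
        reduced, _ = mi.reduce_atlas(small_atlas, small_leadfield, 6)
        labels = np.unique(reduced.dipole_roi)
        np.testing.assert_array_equal(labels, np.arange(1, reduced.n_rois + 1))

    def test_disconnected_cluster_raises(self):
        l = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        atlas = Atlas(
            dipole_roi=np.array([1, 2, 3]),
            roi_cluster=np.array([1, 1, 1]),
            roi_adjacency=set(),  # no adjacency at all
        )
        with pytest.raises(RuntimeError):
            mi.greedy_merge(atlas, mi.Leadfield(l), np.array([1]))
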