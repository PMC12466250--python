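"""Motion integral, phase normalization, descriptor, affinity and clustering."""

import numpy as np
import pytest
from scipy import sparse

from cineclust.flow import FlowField
from cineclust.phantom import CineSequence
from cineclust.stc2 import (AffinityGraph, ClusterAssignment, build_affinity,
                            cluster_compactness, cluster_entropy, dbscan_refine,
                            hybrid_descriptor, motion_integral, phase_normalize,
                            spectral_cluster, DescriptorMap, MotionMap)


def _graph_from_dense(W):
    n = W.shape[0]
    Ws = sparse.csr_matrix(W)
    deg = np.asarray(Ws.sum(axis=1)).ravel()
    D = sparse.diags(deg, format="csr")
    return AffinityGraph(nodes=np.stack([np.arange(n), np.zeros(n, int)], 1),
                         W=Ws, degree=D, laplacian=(D - Ws).tocsr())


class TestMotionIntegral:
    def test_zero_flow_gives_zero_map(self):
        out = motion_integral(FlowField(np.zeros((3, 8, 8, 2))))
        assert np.all(out.values == 0)

    def test_uniform_translation_gives_zero_map(self):
        vec = np.zeros((2, 10, 10, 2))
        vec[0, ..., 0] = 1.7
        vec[1, ..., 1] = -0.4
        out = motion_integral(FlowField(vec))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_unit_shear_hand_computed_on_5x5(self):
        # drow = row index, dcol = 0: the only nonzero partial derivative is
        # d(drow)/d(row) = 1 on interior rows, so interior Imotion = 1
        vec = np.zeros((1, 5, 5, 2))
        vec[0, ..., 0] = np.arange(5, dtype=float)[:, None]
        out = motion_integral(FlowField(vec))
        np.testing.assert_allclose(out.values[1:-1, :], 1.0)
        # edge-replicated central differences halve the border derivative
        np.testing.assert_allclose(out.values[0, :], 0.25)

    def test_invariant_to_global_constant_offset(self, rng):
        vec = rng.normal(0, 1, (4, 12, 12, 2))
        shifted = vec + np.array([2.5, -1.0])
        a = motion_integral(FlowField(vec)).values
        b = motion_integral(FlowField(shifted)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_respects_valid_mask(self, rng):
        vec = rng.normal(0, 1, (4, 8, 8, 2))
        full = motion_integral(FlowField(vec)).values
        partial = motion_integral(
            FlowField(vec, valid_mask=np.array([True, True, False, False]))).values
        assert np.all(partial <= full + 1e-12)

    def test_empty_flow_rejected(self):
        with pytest.raises(ValueError):
            motion_integral(FlowField(np.zeros((0, 4, 4, 2))))


class TestPhaseNormalize:
    def test_equal_energies_keep_all_pairs(self):
        vec = np.ones((5, 6, 6, 2))
        out = phase_normalize(FlowField(vec), energy_quantile=0.8)
        assert out.valid().all()

    def test_exclusion_count_bounded_by_quantile(self, rng):
        vec = rng.normal(0, 1, (19, 8, 8, 2))
        out = phase_normalize(FlowField(vec), energy_quantile=0.8)
        assert (~out.valid()).sum() <= int(np.ceil(0.2 * 19))

    def test_minimum_energy_pair_rolled_first(self):
        vec = np.zeros((4, 6, 6, 2))
        for t, mag in enumerate([2.0, 0.1, 1.0, 3.0]):
            vec[t] = mag
        out = phase_normalize(FlowField(vec), energy_quantile=1.0)
        energies = np.mean(np.sum(out.vectors ** 2, axis=-1), axis=(1, 2))
        assert np.argmin(energies) == 0
        assert out.phase_offset == 1

    def test_all_excluded_is_impossible_by_construction(self):
        # the quantile threshold always keeps at least the minimum-energy pair
        vec = np.random.default_rng(1).normal(0, 1, (6, 4, 4, 2))
        out = phase_normalize(FlowField(vec), energy_quantile=0.01)
        assert out.valid().sum() >= 1

    def test_reduces_healthy_motion_integral_on_phantom(self, lesion_phantom):
        from cineclust.flow import estimate_flow

        _, seq, truth = lesion_phantom
        fl = estimate_flow(seq, n_levels=2, iterations=15)
        healthy = truth.myocardium_mask.all(axis=0) & ~truth.lesion_mask.any(axis=0)
        before = motion_integral(fl).values[healthy].mean()
        after = motion_integral(phase_normalize(fl, 0.8)).values[healthy].mean()
        assert after <= before


class TestHybridDescriptor:
    def test_lambda_t_zero_returns_scaled_mean_image(self, clean_phantom):
        _, seq, _ = clean_phantom
        motion = MotionMap(np.zeros(seq.shape))
        out = hybrid_descriptor(seq, motion, lambda_s=2.0, lambda_t=0.0,
                                standardize=False)
        np.testing.assert_allclose(out.values, 2.0 * seq.frames.mean(axis=0))

    def test_lambda_s_zero_returns_scaled_motion(self, clean_phantom):
        _, seq, _ = clean_phantom
        motion = MotionMap(np.abs(np.random.default_rng(2).normal(
            1, 0.1, seq.shape)))
        out = hybrid_descriptor(seq, motion, lambda_s=0.0, lambda_t=3.0,
                                standardize=False)
        np.testing.assert_allclose(out.values, 3.0 * motion.values)

    def test_hand_arithmetic_equal_weights(self):
        frames = np.stack([np.array([[0.0, 1.0], [2.0, 3.0]]) / 3.0] * 2)
        seq = CineSequence(frames, np.array([0.0, 0.5]))
        motion = MotionMap(np.array([[4.0, 3.0], [2.0, 1.0]]))
        out = hybrid_descriptor(seq, motion, 0.5, 0.5, standardize=False)
        expected = 0.5 * frames[0] + 0.5 * motion.values
        np.testing.assert_allclose(out.values, expected)

    def test_both_weights_zero_rejected(self, clean_phantom):
        _, seq, _ = clean_phantom
        with pytest.raises(ValueError):
            hybrid_descriptor(seq, MotionMap(np.zeros(seq.shape)), 0.0, 0.0)


class TestBuildAffinity:
    def test_kernel_values_on_known_descriptor_gaps(self):
        desc = DescriptorMap(np.array([[0.0, 0.0], [0.0, 1.5 * np.sqrt(2)]]),
                             0.5, 0.5)
        roi = np.ones((2, 2), bool)
        g = build_affinity(desc, roi, sigma=1.5, neighbor_radius=3)
        W = g.W.toarray()
        # equal descriptors -> affinity 1; gap sigma*sqrt(2) -> e^-1
        assert W[0, 1] == pytest.approx(1.0)
        assert W[0, 3] == pytest.approx(np.exp(-1.0))
        np.testing.assert_allclose(np.diag(W), 1.0)

    def test_laplacian_rows_sum_to_zero_and_psd(self, rng):
        desc = DescriptorMap(rng.normal(0, 1, (6, 6)), 0.5, 0.5)
        g = build_affinity(desc, np.ones((6, 6), bool), sigma=1.0,
                           neighbor_radius=2)
        L = g.laplacian.toarray()
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(L, L.T, atol=1e-12)
        evals = np.linalg.eigvalsh(L)
        assert evals.min() >= -1e-9

    def test_decreasing_sigma_never_increases_offdiagonal(self, rng):
        desc = DescriptorMap(rng.normal(0, 1, (5, 5)), 0.5, 0.5)
        roi = np.ones((5, 5), bool)
        W_big = build_affinity(desc, roi, sigma=2.0).W.toarray()
        W_small = build_affinity(desc, roi, sigma=0.7).W.toarray()
        off = ~np.eye(25, dtype=bool)
        assert np.all(W_small[off] <= W_big[off] + 1e-15)

    def test_node_budget_guard(self, rng):
        desc = DescriptorMap(rng.normal(0, 1, (20, 20)), 0.5, 0.5)
        with pytest.raises(ValueError, match="subsample"):
            build_affinity(desc, np.ones((20, 20), bool), max_nodes=100)

    def test_empty_roi_rejected(self):
        desc = DescriptorMap(np.zeros((4, 4)), 0.5, 0.5)
        with pytest.raises(ValueError):
            build_affinity(desc, np.zeros((4, 4), bool))


class TestSpectralCluster:
    def test_two_cliques_with_weak_bridge_split_exactly(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 0.9
        W[4:, 4:] = 0.9
        np.fill_diagonal(W, 1.0)
        W[3, 4] = W[4, 3] = 0.01
        labels = spectral_cluster(_graph_from_dense(W), k=2, seed=0).labels
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_gives_singletons(self, rng):
        W = rng.uniform(0.1, 1.0, (6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        labels = spectral_cluster(_graph_from_dense(W), k=6, seed=0).labels
        assert sorted(labels) == list(range(6))

    def test_same_seed_same_labels(self, rng):
        W = rng.uniform(0.1, 1.0, (10, 10))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        g = _graph_from_dense(W)
        a = spectral_cluster(g, k=3, seed=5).labels
        b = spectral_cluster(g, k=3, seed=5).labels
        np.testing.assert_array_equal(a, b)

    def test_disconnected_components_warn(self):
        W = np.eye(6)
        with pytest.warns(UserWarning, match="components"):
            spectral_cluster(_graph_from_dense(W), k=2, seed=0)

    def test_soft_membership_rows_stochastic(self, rng):
        W = rng.uniform(0.1, 1.0, (9, 9))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        out = spectral_cluster(_graph_from_dense(W), k=3, seed=1)
        np.testing.assert_allclose(out.soft.sum(axis=1), 1.0, atol=1e-9)


class TestDbscanRefine:
    def test_solid_block_stays_one_cluster(self):
        rr, cc = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        nodes = np.stack([rr.ravel(), cc.ravel()], axis=1)
        assign = ClusterAssignment(np.zeros(25, int), k=1)
        out = dbscan_refine(assign, nodes, eps=2.5, min_samples=5)
        assert out.k == 1
        assert np.all(out.labels == 0)

    def test_far_single_pixel_becomes_noise(self):
        rr, cc = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        blob = np.stack([rr.ravel(), cc.ravel()], axis=1)
        nodes = np.vstack([blob, [[0, 15]]])  # 10 px from the blob
        assign = ClusterAssignment(np.zeros(26, int), k=1)
        out = dbscan_refine(assign, nodes, eps=2.5, min_samples=5)
        assert out.labels[-1] == -1
        assert np.all(out.labels[:-1] == out.labels[0])

    def test_splits_disconnected_fragments(self):
        rr, cc = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        blob = np.stack([rr.ravel(), cc.ravel()], axis=1)
        nodes = np.vstack([blob, blob + [0, 20]])
        assign = ClusterAssignment(np.zeros(32, int), k=1)
        out = dbscan_refine(assign, nodes, eps=2.5, min_samples=5)
        assert out.k == 2

    def test_noise_monotone_under_point_removal(self, rng):
        nodes = rng.uniform(0, 20, (60, 2))
        assign = ClusterAssignment(np.zeros(60, int), k=1)
        first = dbscan_refine(assign, nodes, eps=2.5, min_samples=5)
        keep = np.ones(60, bool)
        keep[rng.choice(np.flatnonzero(first.labels >= 0),
                        size=10, replace=False)] = False
        second = dbscan_refine(ClusterAssignment(np.zeros(keep.sum(), int), k=1),
                               nodes[keep], eps=2.5, min_samples=5)
        # a point that was noise stays noise once neighbours are removed
        old_noise = (first.labels == -1)[keep]
        assert np.all(second.labels[old_noise] == -1)


class TestClusterQuality:
    def test_one_hot_entropy_zero(self):
        assign = ClusterAssignment(np.array([0, 1, 2]), k=3)
        per_node, mean = cluster_entropy(assign)
        np.testing.assert_allclose(per_node, 0.0)
        assert mean == 0.0

    def test_uniform_membership_max_entropy(self):
        soft = np.full((5, 4), 0.25)
        assign = ClusterAssignment(np.zeros(5, int), k=4, soft=soft)
        _, mean = cluster_entropy(assign)
        assert mean == pytest.approx(np.log(4), abs=1e-12)

    def test_hand_mixture_entropy(self):
        soft = np.array([[0.5, 0.25, 0.25]])
        assign = ClusterAssignment(np.array([0]), k=3, soft=soft)
        per_node, _ = cluster_entropy(assign)
        assert per_node[0] == pytest.approx(1.5 * np.log(2), abs=1e-12)

    def test_invalid_soft_rows_rejected(self):
        soft = np.array([[0.5, 0.2, 0.2]])
        assign = ClusterAssignment(np.array([0]), k=3, soft=soft)
        with pytest.raises(ValueError):
            cluster_entropy(assign)

    def test_compactness_extremes_and_hand_case(self):
        values = np.array([0.0, 0.0, 1.0, 1.0])
        two = ClusterAssignment(np.array([0, 0, 1, 1]), k=2)
        assert cluster_compactness(two, values) == pytest.approx(100.0)
        one = ClusterAssignment(np.zeros(4, int), k=1)
        assert cluster_compactness(one, values) == pytest.approx(0.0)
        singletons = ClusterAssignment(np.arange(4), k=4)
        assert cluster_compactness(singletons, values) == pytest.approx(100.0)

    def test_zero_variance_warns_full_compactness(self):
        assign = ClusterAssignment(np.array([0, 0, 1]), k=2)
        with pytest.warns(UserWarning):
            out = cluster_compactness(assign, np.ones(3))
        assert out == 100.0
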