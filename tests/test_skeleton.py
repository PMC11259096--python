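"""Skeleton-graph extraction and network morphometrics."""

import numpy as np
import pytest
from scipy import ndimage

from angiokit.phantoms import VesselPhantomSpec, generate_vessel_phantom
from angiokit.preprocess import BinaryStack, preprocess_stack
from angiokit.skeleton import (
    NetworkMetrics,
    average_rois,
    build_graph,
    measure,
    skeletonize,
)
from angiokit.stacks import stack_volume_mm3


def bs(vox, voxel_size=(1.0, 1.0, 1.0)):
    return BinaryStack(np.asarray(vox, bool), voxel_size)


class TestSkeletonize:
    def test_empty_mask_empty_skeleton(self):
        out = skeletonize(bs(np.zeros((5, 5, 5))))
        assert out.count() == 0

    def test_straight_tube_thins_to_single_path(self):
        spec = VesselPhantomSpec(
            grid_shape=(25, 30, 220), topology="straight_tube", noise_sd=0.0
        )
        _, gt = generate_vessel_phantom(spec)
        skel = skeletonize(bs(gt.clean_mask))
        graph = build_graph(skel, prune_um=6.0)
        assert len(graph.segments) == 1
        assert graph.n_endpoints == 2
        assert graph.n_junctions == 0

    def test_component_count_preserved(self):
        vox = np.zeros((7, 40, 40), bool)
        vox[2:5, 5:10, 5:30] = True
        vox[2:5, 25:30, 5:30] = True
        skel = skeletonize(bs(vox))
        s = np.ones((3, 3, 3), bool)
        assert ndimage.label(skel.voxels, s)[1] == ndimage.label(vox, s)[1]


class TestBuildGraph:
    def test_straight_path_of_11_voxels(self):
        vox = np.zeros((3, 3, 13), bool)
        vox[1, 1, 1:12] = True
        graph = build_graph(bs(vox), prune_um=0.0)
        assert len(graph.segments) == 1
        assert graph.segments[0].length_um == pytest.approx(10.0)
        assert graph.n_endpoints == 2
        assert graph.n_junctions == 0

    def test_diagonal_steps_use_euclidean_length(self):
        vox = np.zeros((3, 8, 8), bool)
        for i in range(6):
            vox[1, 1 + i, 1 + i] = True
        graph = build_graph(bs(vox), prune_um=0.0)
        assert graph.segments[0].length_um == pytest.approx(5 * np.sqrt(2))

    def test_anisotropic_z_steps(self):
        vox = np.zeros((6, 3, 3), bool)
        vox[0:6, 1, 1] = True
        graph = build_graph(bs(vox, (5.0, 1.0, 1.0)), prune_um=0.0)
        assert graph.segments[0].length_um == pytest.approx(25.0)

    def test_y_shape_three_segments_one_junction(self):
        vox = np.zeros((3, 24, 24), bool)
        vox[1, 12, 2:13] = True        # horizontal arm into center
        vox[1, 2:12, 12] = True        # vertical arm
        vox[1, 13:23, 13:23] &= False
        for i in range(10):            # diagonal arm
            vox[1, 13 + i, 13 + i] = True
        graph = build_graph(bs(vox), prune_um=0.0)
        assert len(graph.segments) == 3
        assert graph.n_junctions == 1
        assert graph.n_endpoints == 3

    def test_closed_ring_single_cyclic_segment(self):
        # diamond ring: every voxel has exactly two (diagonal) neighbours
        vox = np.zeros((3, 13, 13), bool)
        c, r = 6, 4
        for y in range(13):
            for x in range(13):
                if abs(y - c) + abs(x - c) == r:
                    vox[1, y, x] = True
        graph = build_graph(bs(vox), prune_um=0.0)
        assert len(graph.segments) == 1
        assert graph.n_endpoints == 0
        assert graph.n_junctions == 0
        assert graph.segments[0].length_um == pytest.approx(4 * r * np.sqrt(2))

    def test_handshake_identity_on_tree_phantom(self, tree_phantom):
        _, gt = tree_phantom
        skel = skeletonize(bs(gt.clean_mask))
        graph = build_graph(skel, prune_um=6.0)
        deg_sum = sum(n.degree for n in graph.nodes.values())
        assert deg_sum == 2 * len(graph.segments)

    def test_tree_identity_per_phantom(self, tree_phantom):
        _, gt = tree_phantom
        skel = skeletonize(bs(gt.clean_mask))
        graph = build_graph(skel, prune_um=6.0)
        assert graph.n_endpoints + graph.n_junctions == len(graph.segments) + 1

    def test_dilation_leaves_topology_counts_unchanged(self):
        spec = VesselPhantomSpec(
            grid_shape=(25, 220, 220), topology="y_junction", noise_sd=0.0
        )
        _, gt = generate_vessel_phantom(spec)
        g1 = build_graph(skeletonize(bs(gt.clean_mask)), prune_um=6.0)
        fat = ndimage.binary_dilation(gt.clean_mask)
        g2 = build_graph(skeletonize(bs(fat)), prune_um=6.0)
        assert (g1.n_endpoints, g1.n_junctions) == (g2.n_endpoints, g2.n_junctions)

    def test_scale_equivariance_of_lengths(self):
        vox = np.zeros((3, 3, 13), bool)
        vox[1, 1, 1:12] = True
        g1 = build_graph(bs(vox, (1.0, 1.0, 1.0)), prune_um=0.0)
        g3 = build_graph(bs(vox, (3.0, 3.0, 3.0)), prune_um=0.0)
        assert g3.segments[0].length_um == pytest.approx(
            3 * g1.segments[0].length_um
        )


class TestMeasure:
    def test_empty_graph_zero_metrics(self):
        graph = build_graph(bs(np.zeros((4, 4, 4))), prune_um=0.0)
        m = measure(graph, 1e-3)
        assert m.n_vessels == 0
        assert m.total_length_um == 0.0
        assert m.avg_branch_length_um is None

    def test_y_metrics_arithmetic(self):
        # three 50 µm segments at one junction: pure metric arithmetic
        from angiokit.skeleton import SkeletonGraph, SkeletonNode, SkeletonSegment

        nodes = {
            0: SkeletonNode(0, "junction", [(0, 0, 0)], (0.0, 0.0, 0.0), degree=3),
            1: SkeletonNode(1, "endpoint", [(0, 0, 50)], (0.0, 0.0, 50.0), degree=1),
            2: SkeletonNode(2, "endpoint", [(0, 50, 0)], (0.0, 50.0, 0.0), degree=1),
            3: SkeletonNode(3, "endpoint", [(0, 0, 50)], (50.0, 0.0, 0.0), degree=1),
        }
        segments = [
            SkeletonSegment(i, 0, i + 1, [], 50.0) for i in range(3)
        ]
        graph = SkeletonGraph(nodes, segments, (1.0, 1.0, 1.0), 1)
        m = measure(graph, 0.001)
        assert m.n_vessels == 3
        assert m.n_branch_points == 1
        assert m.n_endpoints == 3
        assert m.n_branches == 4
        assert m.total_length_um == pytest.approx(150.0)
        assert m.total_length_per_mm3 == pytest.approx(150_000.0)
        assert m.avg_branch_length_um == pytest.approx(50.0)

    def test_nonpositive_volume_rejected(self):
        graph = build_graph(bs(np.zeros((4, 4, 4))), prune_um=0.0)
        with pytest.raises(ValueError):
            measure(graph, 0.0)

    def test_straight_tube_length_recovery_within_5pct(self):
        spec = VesselPhantomSpec(
            grid_shape=(25, 30, 220),
            topology="straight_tube",
            length_um=200.0,
            rng_seed=1,
        )
        stack, _ = generate_vessel_phantom(spec)
        mask = preprocess_stack(stack, threshold_method="otsu_global")
        graph = build_graph(skeletonize(mask), prune_um=6.0)
        m = measure(graph, stack_volume_mm3(stack))
        assert m.n_vessels == 1
        assert m.total_length_um == pytest.approx(200.0, rel=0.05)


class TestAverageRois:
    def test_single_roi_identity(self):
        m = NetworkMetrics(total_length_um=120.0, n_vessels=3, n_components=1)
        out = average_rois([m])
        assert out.total_length_um == 120.0
        assert out.n_vessels == 3

    def test_mean_and_permutation_invariance(self):
        a = NetworkMetrics(total_length_per_mm3=100.0)
        b = NetworkMetrics(total_length_per_mm3=200.0)
        assert average_rois([a, b]).total_length_per_mm3 == pytest.approx(150.0)
        assert (
            average_rois([b, a]).total_length_per_mm3
            == average_rois([a, b]).total_length_per_mm3
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_rois([])
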