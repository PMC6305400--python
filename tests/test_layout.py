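"""Branch-tree construction, angular allocation, length modes and ordering."""

import numpy as np
import pytest

from circdendro import (
    AngleMode,
    LayoutConfig,
    LengthMode,
    assign_angles,
    assign_lengths,
    branch_geometry,
    build_branch_tree,
    collapse_subtree,
    count_summary,
    expand_subtree,
    generate_tree,
    radial_distance,
    tree_spec,
)
from circdendro.errors import FeatureError, LayoutError
from circdendro.io_swc import APICAL_DENDRITE, AXON, NeuronMorphology, ROOT_PARENT, SOMA
from circdendro.layout import iter_nodes, layout_table, order_neurites, order_siblings
from circdendro.synthetic import TreeSpec

from conftest import mp, random_spec


def laid_out(morph, **cfg):
    config = LayoutConfig(**cfg)
    trees = build_branch_tree(morph)
    assign_lengths(trees, morph, config)
    return assign_angles(trees, config, morph), config


def two_neurite_morph(e1=3, e2=9, seed=6):
    return generate_tree(tree_spec([e1, e2], seed=seed))


def leaf_spans(trees):
    return [
        n.theta_end - n.theta_start for t in trees for n in iter_nodes([t]) if n.is_leaf
    ]


class TestBuildBranchTree:
    def test_unbranched_neurite_single_node(self, straight_neurite):
        trees = build_branch_tree(straight_neurite)
        assert len(trees) == 1
        assert trees[0].is_leaf and trees[0].e_sub == 1

    def test_one_bifurcation(self, y_neuron):
        (root,) = build_branch_tree(y_neuron)
        assert len(root.children) == 2
        assert root.e_sub == 2

    def test_counts_match_morphometry(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            m = generate_tree(random_spec(rng))
            trees = build_branch_tree(m)
            s = count_summary(m)
            nodes = [n for t in trees for n in iter_nodes([t])]
            assert sum(1 for n in nodes if n.is_leaf) == s.terminal_count
            assert sum(1 for n in nodes if not n.is_leaf) == s.bifurcation_count
            assert len(trees) == s.neurite_count

    def test_empty_morphology_warns(self):
        m = NeuronMorphology([mp(1, SOMA, 0, 0, 0, 5, ROOT_PARENT)])
        with pytest.warns(UserWarning):
            assert build_branch_tree(m) == []


class TestAngles:
    def test_endm_spans(self):
        m = two_neurite_morph(3, 9)
        trees, _ = laid_out(m, angle_mode="endm")
        assert leaf_spans(trees) == pytest.approx([30.0] * 12)
        alphas = sorted(t.theta_end - t.theta_start for t in trees)
        assert alphas == pytest.approx([90.0, 270.0])

    def test_ndm_spans(self):
        m = two_neurite_morph(3, 9)
        trees, _ = laid_out(m, angle_mode="ndm")
        alphas = [t.theta_end - t.theta_start for t in trees]
        assert alphas == pytest.approx([180.0, 180.0])
        by_tree = sorted(
            {round(s, 9) for s in leaf_spans([t])}.pop() for t in trees
        )
        assert by_tree == pytest.approx([20.0, 60.0])

    def test_wdm_equal_weights_reduces_to_endm(self):
        m = two_neurite_morph(4, 7)
        t_endm, _ = laid_out(m, angle_mode="endm")
        t_wdm, _ = laid_out(m, angle_mode="wdm")  # default weight 1 per leaf
        for a, b in zip(iter_nodes(t_endm), iter_nodes(t_wdm)):
            assert a.span == pytest.approx(b.span)

    def test_wdm_weights_proportional(self, y_neuron):
        trees = build_branch_tree(y_neuron)
        leaves = [n for n in iter_nodes(trees) if n.is_leaf]
        config = LayoutConfig(
            angle_mode="wdm", weights={leaves[0].key: 3.0, leaves[1].key: 1.0}
        )
        assign_lengths(trees, y_neuron, config)
        assign_angles(trees, config)
        spans = leaf_spans(trees)
        assert spans == pytest.approx([270.0, 90.0])

    def test_wdm_non_positive_weight_rejected(self, y_neuron):
        trees = build_branch_tree(y_neuron)
        leaf = next(n for n in iter_nodes(trees) if n.is_leaf)
        config = LayoutConfig(angle_mode="wdm", weights={leaf.key: -1.0})
        with pytest.raises(LayoutError):
            assign_angles(trees, config)

    def test_empty_layout_rejected(self):
        with pytest.raises(LayoutError):
            assign_angles([], LayoutConfig())

    def test_clockwise_reverses_progression(self, y_neuron):
        ccw, _ = laid_out(y_neuron, clockwise=False, start_angle=0.0)
        cw, _ = laid_out(y_neuron, clockwise=True, start_angle=0.0)
        assert ccw[0].theta_start == pytest.approx(0.0)
        assert ccw[0].theta_end == pytest.approx(360.0)
        assert cw[0].theta_end == pytest.approx(0.0)
        assert cw[0].theta_start == pytest.approx(-360.0)

    def test_ray_angle_within_span(self):
        rng = np.random.default_rng(8)
        for mode in ("endm", "ndm", "wdm"):
            m = generate_tree(random_spec(rng))
            trees, _ = laid_out(m, angle_mode=mode)
            for n in (x for t in trees for x in iter_nodes([t])):
                assert n.theta_start <= n.ray_angle < n.theta_end

    def test_anchoring_centers_apical_up(self):
        m = generate_tree(
            TreeSpec(((3, 2), (APICAL_DENDRITE, 4), (AXON, 3), (3, 2)), seed=12)
        )
        trees, _ = laid_out(m, anchor=True)
        stypes = [m.point(t.branch.point_ids[0]).structure_type for t in trees]
        assert stypes[0] == APICAL_DENDRITE and stypes[-1] == AXON
        apical = trees[0]
        assert 0.5 * (apical.theta_start + apical.theta_end) == pytest.approx(90.0)


class TestLengths:
    def test_unitary_depths(self):
        m = generate_tree(tree_spec([4], seed=2))
        trees, _ = laid_out(m, length_mode="um", unit_length=10.0)
        soma_r = m.soma_mean_radius
        for n in iter_nodes(trees):
            assert n.length == 10.0
            assert n.r0 == pytest.approx(soma_r + 10.0 * (n.branch.branch_order - 1))

    def test_real_lengths_bit_equal_to_geometry(self):
        m = generate_tree(tree_spec([3, 5], seed=7))
        trees, _ = laid_out(m, length_mode="rlm")
        for n in (x for t in trees for x in iter_nodes([t])):
            assert n.length == branch_geometry(n.branch, m).path_length

    def test_radial_mode_on_collinear_fixture(self, straight_neurite):
        trees, _ = laid_out(straight_neurite, length_mode="rm")
        (root,) = trees
        assert root.r0 + root.length == pytest.approx(
            radial_distance(root.key, straight_neurite)
        )

    def test_radial_mode_clamps_inward_branches(self):
        # child end point nearer the soma than its parent's outer radius
        pts = [
            mp(1, SOMA, 0, 0, 0, 1, ROOT_PARENT),
            mp(2, 3, 50, 0, 0, 1, 1),
            mp(3, 3, 60, 0, 0, 1, 2),     # bifurcation at 60
            mp(4, 3, 80, 0, 0, 1, 3),
            mp(5, 3, 30, 0, 0, 1, 3),     # curls back toward the soma
        ]
        m = NeuronMorphology(pts)
        trees = build_branch_tree(m)
        with pytest.warns(UserWarning, match="clamped"):
            assign_lengths(trees, m, LayoutConfig(length_mode="rm"))
        lengths = [n.length for n in iter_nodes(trees)]
        assert all(l > 0 for l in lengths)

    def test_mapped_mode_affine_rescale(self):
        m = two_neurite_morph(2, 3)
        config = LayoutConfig(length_mode="lmm", mapped_range=(5.0, 50.0))
        trees = build_branch_tree(m)
        feats = {
            n.key: branch_geometry(n.branch, m).mean_diameter
            for t in trees
            for n in iter_nodes([t])
        }
        assign_lengths(trees, m, config, feats)
        lengths = [n.length for t in trees for n in iter_nodes([t])]
        assert min(lengths) == pytest.approx(5.0)
        assert max(lengths) == pytest.approx(50.0)

    def test_mapped_mode_missing_feature_rejected(self):
        m = two_neurite_morph(2, 3)
        trees = build_branch_tree(m)
        config = LayoutConfig(length_mode="lmm")
        with pytest.raises(FeatureError):
            assign_lengths(trees, m, config, {})

    def test_mapped_mode_constant_feature_midpoint(self, y_neuron):
        trees = build_branch_tree(y_neuron)
        config = LayoutConfig(length_mode="lmm", mapped_range=(10.0, 30.0))
        feats = {n.key: 1.0 for n in iter_nodes(trees)}
        assign_lengths(trees, y_neuron, config, feats)
        assert all(n.length == pytest.approx(20.0) for n in iter_nodes(trees))


class TestInvariants:
    @pytest.mark.parametrize("angle_mode", list(AngleMode))
    @pytest.mark.parametrize("length_mode", list(LengthMode))
    def test_conservation_and_nesting(self, angle_mode, length_mode):
        seed = 1 + list(AngleMode).index(angle_mode) * 4 + list(LengthMode).index(length_mode)
        rng = np.random.default_rng(seed)
        m = generate_tree(random_spec(rng))
        trees = build_branch_tree(m)
        config = LayoutConfig(angle_mode=angle_mode, length_mode=length_mode)
        feats = (
            {n.key: float(i) for i, n in enumerate(iter_nodes(trees))}
            if length_mode is LengthMode.MAPPED
            else None
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # rm-mode clamping
            assign_lengths(trees, m, config, feats)
        trees = assign_angles(trees, config, m)
        total = sum(t.theta_end - t.theta_start for t in trees)
        assert abs(total - 360.0) < 1e-9
        for node in (x for t in trees for x in iter_nodes([t])):
            if node.is_leaf:
                continue
            kids = node.children
            assert kids[0].theta_start == pytest.approx(node.theta_start, abs=1e-12)
            assert kids[-1].theta_end == pytest.approx(node.theta_end, abs=1e-12)
            for a, b in zip(kids, kids[1:]):
                assert a.theta_end == pytest.approx(b.theta_start, abs=1e-9)

    def test_endm_leaf_spans_uniform_to_machine_precision(self):
        rng = np.random.default_rng(99)
        m = generate_tree(random_spec(rng))
        trees, _ = laid_out(m, angle_mode="endm")
        spans = leaf_spans(trees)
        assert max(spans) - min(spans) < 1e-12


class TestOrdering:
    def test_descending_by_endings(self):
        m = two_neurite_morph(3, 9)
        trees = build_branch_tree(m)
        ordered = order_neurites(trees, m, "endings", descending=True)
        assert [t.e_sub for t in ordered] == [9, 3]

    def test_stability_on_ties(self):
        m = generate_tree(tree_spec([2, 2, 2], seed=3))
        trees = build_branch_tree(m)
        ordered = order_neurites(trees, m, "endings")
        assert [t.key for t in ordered] == [t.key for t in trees]

    def test_unknown_key_rejected(self):
        m = two_neurite_morph()
        trees = build_branch_tree(m)
        with pytest.raises(FeatureError):
            order_neurites(trees, m, "charisma")

    def test_sibling_sort_idempotent_and_topology_preserving(self):
        m = generate_tree(tree_spec([6], seed=15))
        trees = build_branch_tree(m)

        def shape(node):
            return tuple(sorted(shape(c) for c in node.children))

        before = shape(trees[0])
        order_siblings(trees[0], m, "length")
        once = [n.key for n in iter_nodes(trees)]
        after = shape(trees[0])
        order_siblings(trees[0], m, "length")
        twice = [n.key for n in iter_nodes(trees)]
        assert once == twice
        assert before == after  # canonical shape unchanged

    def test_sibling_sort_ascending_lengths(self):
        m = generate_tree(tree_spec([5], seed=30))
        trees = build_branch_tree(m)
        order_siblings(trees[0], m, "length")
        for n in iter_nodes(trees):
            if len(n.children) >= 2:
                ls = [branch_geometry(c.branch, m).path_length for c in n.children]
                assert ls == sorted(ls)

    def test_leaf_count_invariant_under_permutation(self):
        m = generate_tree(tree_spec([7], seed=44))
        trees = build_branch_tree(m)
        e0 = trees[0].e_sub
        order_siblings(trees[0], m, "volume", descending=True)
        assert trees[0].e_sub == e0


class TestCollapse:
    def test_collapse_labels_with_ending_count(self):
        m = generate_tree(tree_spec([6], seed=2))
        trees, _ = laid_out(m)
        root = trees[0]
        collapse_subtree(root)
        assert root.collapse_label == "6"
        assert root.span == pytest.approx(root.span)  # span retained

    def test_collapse_leaf_rejected(self, straight_neurite):
        trees, _ = laid_out(straight_neurite)
        with pytest.raises(LayoutError):
            collapse_subtree(trees[0])

    def test_expand_collapse_roundtrip(self):
        m = generate_tree(tree_spec([5], seed=9))
        trees, _ = laid_out(m)
        root = trees[0]
        before = layout_table(trees)
        expand_subtree(collapse_subtree(root))
        assert layout_table(trees) == before


def test_layout_table_shape():
    m = generate_tree(tree_spec([3, 2], seed=1))
    trees, _ = laid_out(m)
    lines = layout_table(trees).strip().splitlines()
    s = count_summary(m)
    assert len(lines) == 1 + s.terminal_count + s.bifurcation_count
    assert all(len(l.split("\t")) == len(lines[0].split("\t")) for l in lines)
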