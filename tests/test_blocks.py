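"""Building-block extraction, fiber numbers |n,l>, and hierarchy classes."""

import math

import pytest

from fibersync.blocks import (
    classify,
    classify_all,
    extract_block,
    fiber_numbers,
    fiber_size_histogram,
    format_fiber_numbers,
)
from fibersync.fibration import FiberPartition, minimal_balanced_coloring
from fibersync.fixtures import fixtures
from fibersync.grn import ACTIVATION, REPRESSION, RegNetwork

GOLDEN = (1 + math.sqrt(5)) / 2


def block_of(net, member):
    partition = minimal_balanced_coloring(net)
    return extract_block(net, partition, partition.fiber_of(member)), partition


class TestExtractBlock:
    def test_regulon_block(self):
        net = fixtures("fig2a")
        block, _ = block_of(net, "gltX")
        assert block.members == {"cbpAM", "gltX", "gyrB", "msrA"}
        assert block.regulators == {"fis"}

    def test_fff_block(self):
        net = fixtures("fig4")
        block, _ = block_of(net, "pyrC")
        assert block.members == {"purR", "pyrC"}
        assert block.regulators == {"fur"}

    def test_singleton_inputless_block(self):
        net = RegNetwork.from_edges([("x", "y", ACTIVATION)])
        block, _ = block_of(net, "x")
        assert block.members == {"x"}
        assert block.regulators == set()
        assert (block.n, block.l) == (0.0, 0)

    def test_regulator_count_matches_distinct_feeders(self):
        for name in ("fig2a", "fig2b", "fig3", "fig4", "fig5"):
            net = fixtures(name)
            partition = minimal_balanced_coloring(net)
            for fid in partition.fibers:
                block = extract_block(net, partition, fid)
                expected = {
                    src
                    for m in block.members
                    for src, _ in net.in_edges(m)
                    if src not in block.members
                }
                assert block.l == len(expected) == len(block.regulators)


class TestFiberNumbers:
    def test_two_regulator_regulon_is_0_2(self):
        net = fixtures("fig2b")
        block, _ = block_of(net, "fiu")
        assert (block.n, block.l) == (0.0, 2)

    def test_fff_is_1_1(self):
        net = fixtures("fig4")
        block, _ = block_of(net, "purR")
        assert (block.n, block.l) == (1.0, 1)

    def test_trp_is_1_0(self):
        net = fixtures("fig3")
        block, _ = block_of(net, "trpR")
        assert (block.n, block.l) == (1.0, 0)

    def test_fibonacci_loop_branching_ratio(self):
        net = fixtures("fig6")
        block, _ = block_of(net, "exuR")
        assert block.n == pytest.approx(GOLDEN, abs=1e-9)
        # successive ratios converge: depths 20 and 50 agree to < 1e-6
        n20, _, _ = fiber_numbers(block, depth=20)
        n50, _, _ = fiber_numbers(block, depth=50)
        assert abs(n20 - n50) < 1e-6

    def test_double_self_loop_fiber_gives_n_2(self):
        # two AR loops of distinct signs, lifted identically to the target:
        # the input tree doubles each layer (a binary tree)
        net = RegNetwork.from_edges(
            [
                ("a", "a", ACTIVATION),
                ("a", "a", REPRESSION),
                ("a", "b", ACTIVATION),
                ("a", "b", REPRESSION),
            ]
        )
        block, partition = block_of(net, "b")
        assert block.members == {"a", "b"}
        assert (block.n, block.l) == (2.0, 0)
        assert classify(block, partition, net)[0] == "binary-tree"

    def test_single_sign_target_of_looped_regulator_is_a_regulon(self):
        # the loops live outside the fiber, so the fiber itself has n = 0
        net = RegNetwork.from_edges(
            [
                ("a", "a", ACTIVATION),
                ("a", "a", REPRESSION),
                ("a", "b", ACTIVATION),
            ]
        )
        block, _ = block_of(net, "b")
        assert (block.n, block.l) == (0.0, 1)

    def test_shallow_depth_rejected(self):
        net = fixtures("fig3")
        block, _ = block_of(net, "trpR")
        with pytest.raises(ValueError):
            fiber_numbers(block, depth=4)

    def test_n_zero_iff_restricted_tree_finite(self):
        # regulon: no feedback -> finite restricted tree -> n = 0
        net = fixtures("fig2a")
        block, _ = block_of(net, "gltX")
        assert block.n == 0.0
        assert 0 in block.layer_sizes

    def test_single_self_loop_layers_eventually_constant(self):
        net = fixtures("fig3")
        block, _ = block_of(net, "trpR")
        assert set(block.layer_sizes[1:]) == {1}


class TestClassify:
    def test_trp_is_ar_loop(self):
        net = fixtures("fig3")
        block, partition = block_of(net, "trpR")
        assert classify(block, partition, net) == ("ar-loop", "|1,0>")

    def test_fis_regulon(self):
        net = fixtures("fig2a")
        block, partition = block_of(net, "msrA")
        assert classify(block, partition, net) == ("regulon", "|0,1>")

    def test_multilayer_composite_label(self):
        net = fixtures("fig5")
        block, partition = block_of(net, "add")
        label = classify(block, partition, net)
        assert label == ("multilayer-composite", "|0,1>(+)|1,1>")

    def test_fibonacci_class(self):
        net = fixtures("fig6")
        block, partition = block_of(net, "exuR")
        cls, label = classify(block, partition, net)
        assert cls == "fibonacci"
        assert label.startswith("|1.6180,")

    def test_total_over_all_fixture_blocks(self):
        known = {
            "regulon", "ar-loop", "fff", "binary-tree", "fibonacci",
            "multilayer-composite", "other",
        }
        for name in ("fig1", "fig2a", "fig2b", "fig3", "fig4", "fig5", "fig6"):
            net = fixtures(name)
            for block in classify_all(net, minimal_balanced_coloring(net)):
                assert block.class_label in known


def test_format_fiber_numbers():
    assert format_fiber_numbers(1.0, 0) == "|1,0>"
    assert format_fiber_numbers(GOLDEN, 2) == "|1.6180,2>"


class TestHistogram:
    def test_counts(self):
        p = FiberPartition.from_colors(
            {"a": 0, "b": 0, "c": 1, "d": 2, "e": 2, "f": 2}
        )
        assert fiber_size_histogram(p) == {2: 1, 3: 1}

    def test_all_singletons_empty(self):
        p = FiberPartition.from_colors({"a": 0, "b": 1})
        assert fiber_size_histogram(p) == {}

    def test_bad_range(self):
        p = FiberPartition.from_colors({"a": 0})
        with pytest.raises(ValueError):
            fiber_size_histogram(p, min_size=5, max_size=2)

    def test_planted_sizes_recovered(self):
        from fibersync.synth import plant_fibered_grn

        _, partition = plant_fibered_grn((15, 0.12, (0.6, 0.3, 0.1)), [3, 3, 3], 0)
        assert fiber_size_histogram(partition) == {3: 3}
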