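"""Fibers of a GRN via minimal balanced coloring, input trees, and the base graph.

Two genes belong to the same *fiber* when their input trees — the rooted
trees of all reversed signal paths into them, with loops unfolded — are
isomorphic.  In an admissible dynamical model this guarantees the existence
of a solution that is synchronous within each fiber.  The fiber partition
equals the coarsest *balanced coloring* (coarsest equitable partition of the
signed in-neighbourhood structure), which this module computes by iterative
partition refinement.  A brute-force cross-check based on input-tree
canonical forms (:func:`fibers_by_oracle`) is provided, together with the
quotient (:func:`base_graph`) that collapses each fiber to one node.

One ad-hoc rule supplements pure input-tree isomorphism: strongly connected
components with no input from the rest of the network (including isolated
input-less genes) are assigned to different fibers, because the synchronous
solutions that would merge them require fine-tuned initial conditions and
carry no regulatory information.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .grn import RegNetwork

__all__ = [
    "FiberPartition",
    "InputTree",
    "TreeVertex",
    "UnbalancedPartitionError",
    "minimal_balanced_coloring",
    "fibers_by_oracle",
    "input_tree",
    "trees_isomorphic",
    "base_graph",
    "check_balanced",
    "source_components",
]


class UnbalancedPartitionError(ValueError):
    """Raised when a partition claimed to be balanced is not."""


@dataclass(frozen=True)
class FiberPartition:
    """An assignment of nodes to fibers (balanced-coloring classes).

    Fiber ids are small integers assigned by first occurrence in ascending
    node-id order, so identical inputs always yield identical ids.
    """

    colors: Mapping[str, int]

    @classmethod
    def from_colors(cls, colors: Mapping[str, int]) -> "FiberPartition":
        """Canonicalize arbitrary color labels into deterministic fiber ids."""
        remap: dict[int, int] = {}
        out: dict[str, int] = {}
        for node in sorted(colors):
            c = colors[node]
            if c not in remap:
                remap[c] = len(remap)
            out[node] = remap[c]
        return cls(out)

    @property
    def fibers(self) -> dict[int, frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for node, c in self.colors.items():
            groups.setdefault(c, set()).add(node)
        return {c: frozenset(m) for c, m in groups.items()}

    def fiber_of(self, node: str) -> int:
        return self.colors[node]

    def members(self, fiber_id: int) -> frozenset[str]:
        return self.fibers[fiber_id]

    def sizes(self) -> dict[int, int]:
        return {c: len(m) for c, m in self.fibers.items()}

    def as_sets(self) -> frozenset[frozenset[str]]:
        """Label-free view, for comparing partitions."""
        return frozenset(self.fibers.values())

    def __len__(self) -> int:
        return len(set(self.colors.values()))


# -- balanced coloring ---------------------------------------------------


def _in_signature(net: RegNetwork, node: str, colors: Mapping[str, int]):
    """Multiset of (in-neighbour color, edge sign), as a sorted tuple."""
    return tuple(sorted((colors[src], sign) for src, sign in net.in_edges(node)))


def _seeded_refinement(net: RegNetwork, colors: dict[str, int]) -> dict[str, int]:
    """Split-only refinement to the coarsest balanced partition refining a seed.

    Nodes are regrouped by (current color, in-signature) until the number of
    classes is stable; the class count is non-decreasing and the loop ends in
    at most |nodes| iterations.
    """
    nodes = sorted(net.nodes)
    n_colors = len(set(colors.values()))
    for _ in range(len(nodes) + 1):
        table: dict[tuple, int] = {}
        new: dict[str, int] = {}
        for node in nodes:
            key = (colors[node], _in_signature(net, node, colors))
            new[node] = table.setdefault(key, len(table))
        if len(table) == n_colors:
            return new
        colors, n_colors = new, len(table)
    raise AssertionError("refinement did not stabilise within |nodes| iterations")


def source_components(net: RegNetwork) -> list[frozenset[str]]:
    """SCCs with no incoming edge from outside the component.

    Includes isolated and input-less nodes (singleton SCCs).  Self-loops and
    edges within the component do not count as input.
    """
    digraph = nx.DiGraph()
    digraph.add_nodes_from(net.nodes)
    digraph.add_edges_from((s, t) for s, t, _ in net.edges)
    comps = []
    for comp in nx.strongly_connected_components(digraph):
        external = any(
            src not in comp
            for node in comp
            for src, _ in net.in_edges(node)
        )
        if not external:
            comps.append(frozenset(comp))
    return sorted(comps, key=min)


def _separate_sources(net: RegNetwork, colors: dict[str, int]) -> dict[str, int]:
    """Enforce that distinct no-input source components occupy distinct fibers.

    Classes mixing nodes from two or more source components are split (one
    sub-class per component; free nodes form their own sub-class), and the
    partition is re-refined to restore balance; repeated to a fixed point.
    """
    tag: dict[str, int] = {}
    for i, comp in enumerate(source_components(net)):
        for node in comp:
            tag[node] = i
    for _ in range(len(net.nodes) + 1):
        classes: dict[int, list[str]] = {}
        for node, c in colors.items():
            classes.setdefault(c, []).append(node)
        dirty = False
        new = dict(colors)
        next_color = max(colors.values(), default=-1) + 1
        for c, members in classes.items():
            tags_here = {tag[m] for m in members if m in tag}
            if len(tags_here) < 2:
                continue
            dirty = True
            sub: dict[object, int] = {}
            for m in sorted(members):
                key = tag.get(m, "free")
                if key not in sub:
                    sub[key] = next_color
                    next_color += 1
                new[m] = sub[key]
        if not dirty:
            return colors
        colors = _seeded_refinement(net, new)
    raise AssertionError("source separation did not reach a fixed point")


def minimal_balanced_coloring(net: RegNetwork) -> FiberPartition:
    """Coarsest balanced partition of a signed digraph (the fiber partition).

    Starts from the trivial single-color partition, refines by the multiset
    of (in-neighbour color, edge sign), then separates no-input source
    components.  The result is asserted balanced before being returned.
    """
    if not net.nodes:
        raise ValueError("cannot color an empty network")
    colors = {node: 0 for node in net.nodes}
    colors = _seeded_refinement(net, colors)
    colors = _separate_sources(net, colors)
    partition = FiberPartition.from_colors(colors)
    check_balanced(net, partition)
    return partition


def check_balanced(net: RegNetwork, partition: FiberPartition) -> None:
    """Raise :class:`UnbalancedPartitionError` unless the partition is balanced.

    Balanced means any two same-fiber nodes have identical multisets of
    (fiber of source, edge sign) over their incoming edges.
    """
    colors = partition.colors
    if set(colors) != set(net.nodes):
        raise UnbalancedPartitionError("partition does not cover the node set")
    for fiber_id, members in partition.fibers.items():
        sigs = {_in_signature(net, m, colors) for m in members}
        if len(sigs) > 1:
            raise UnbalancedPartitionError(
                f"fiber {fiber_id} members have differing input signatures"
            )


# -- input trees ---------------------------------------------------------


@dataclass(frozen=True)
class TreeVertex:
    """One vertex of an unfolded input tree.

    ``node`` is the graph node this vertex represents, ``sign`` labels the
    edge to the parent vertex (``None`` at the root), ``parent`` indexes the
    parent within the previous layer (``None`` at the root).
    """

    node: str
    sign: Optional[str]
    parent: Optional[int]


@dataclass(frozen=True)
class InputTree:
    """Breadth-first unfolding of all reversed paths into a root node.

    ``layer_sizes[k]`` counts the length-``k`` paths ending at the root
    (``layer_sizes[0] == 1``).  ``layers`` holds the explicit vertices when
    the tree was materialised, else ``None``.
    """

    root: str
    depth: int
    layer_sizes: tuple[int, ...]
    layers: Optional[tuple[tuple[TreeVertex, ...], ...]] = None


def _layer_size_counts(net: RegNetwork, root: str, depth: int) -> list[int]:
    """Exact input-tree layer sizes via path counting (arbitrary precision)."""
    counts: dict[str, int] = {root: 1}
    sizes = [1]
    for _ in range(depth):
        nxt: dict[str, int] = {}
        for node, mult in counts.items():
            for src, _ in net.in_edges(node):
                nxt[src] = nxt.get(src, 0) + mult
        sizes.append(sum(nxt.values()))
        counts = nxt
    return sizes


_MATERIALIZE_LIMIT = 2_000_000


def input_tree(
    net: RegNetwork, root: str, depth: int, materialize: bool = True
) -> InputTree:
    """Unfold the incoming edges of ``root`` to the given depth.

    Layer sizes are always computed exactly; the explicit vertex layers are
    built unless ``materialize`` is false, and refuse to expand past
    2,000,000 vertices.
    """
    if root not in net.nodes:
        raise KeyError(f"unknown root node: {root!r}")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    sizes = _layer_size_counts(net, root, depth)
    layers = None
    if materialize:
        if sum(sizes) > _MATERIALIZE_LIMIT:
            raise ValueError(
                f"input tree of {root!r} has {sum(sizes)} vertices; "
                "pass materialize=False for layer sizes only"
            )
        built: list[tuple[TreeVertex, ...]] = [(TreeVertex(root, None, None),)]
        for _ in range(depth):
            prev = built[-1]
            layer: list[TreeVertex] = []
            for idx, vertex in enumerate(prev):
                for src, sign in net.in_edges(vertex.node):
                    layer.append(TreeVertex(src, sign, idx))
            built.append(tuple(layer))
        layers = tuple(built)
    return InputTree(root, depth, tuple(sizes), layers)


def _canonical_root(tree: InputTree, intern: dict) -> int:
    """Interned canonical form of the root, bottom-up over the layers."""
    if tree.layers is None:
        raise ValueError("tree was not materialised; cannot canonicalise")
    # ids[k][i] = canonical id of vertex i in layer k, computed deepest-first
    child_ids: list[list[int]] = [[] for _ in tree.layers]
    for k in range(len(tree.layers) - 1, -1, -1):
        children: list[list[tuple[str, int]]] = [[] for _ in tree.layers[k]]
        if k + 1 < len(tree.layers):
            for i, vertex in enumerate(tree.layers[k + 1]):
                children[vertex.parent].append((vertex.sign, child_ids[k + 1][i]))
        for i, vertex in enumerate(tree.layers[k]):
            key = tuple(sorted(children[i]))
            child_ids[k].append(intern.setdefault(key, len(intern)))
    return child_ids[0][0]


def trees_isomorphic(t1: InputTree, t2: InputTree) -> bool:
    """True iff the two input trees are topologically identical.

    Children are compared as multisets of (edge sign, subtree canonical
    form); the graph node identities carried by tree vertices are ignored.
    Requires equal depths.
    """
    if t1.depth != t2.depth:
        raise ValueError(f"depth mismatch: {t1.depth} != {t2.depth}")
    intern: dict = {}
    return _canonical_root(t1, intern) == _canonical_root(t2, intern)


def fibers_by_oracle(net: RegNetwork, depth: Optional[int] = None) -> FiberPartition:
    """Fiber partition by input-tree isomorphism at finite depth.

    Canonical forms of depth-``d`` input trees are computed for every node
    by interned bottom-up hashing directly on the graph (equivalent to
    explicit tree unfolding, without the exponential blow-up).  The default
    depth |nodes| suffices for equivalence with the coarsest equitable
    partition.  The no-input source-component separation rule is applied
    afterwards.  Serves as the brute-force oracle for
    :func:`minimal_balanced_coloring`.
    """
    if not net.nodes:
        raise ValueError("cannot partition an empty network")
    if depth is None:
        depth = len(net.nodes)
    nodes = sorted(net.nodes)
    cf = {node: 0 for node in nodes}
    for _ in range(depth):
        table: dict[tuple, int] = {}
        new: dict[str, int] = {}
        for node in nodes:
            key = tuple(sorted((sign, cf[src]) for src, sign in net.in_edges(node)))
            new[node] = table.setdefault(key, len(table))
        cf = new
    cf = _separate_sources(net, cf)
    return FiberPartition.from_colors(cf)


# -- quotient ------------------------------------------------------------


def base_graph(net: RegNetwork, partition: FiberPartition) -> RegNetwork:
    """Collapse each fiber to one node, producing the base of the fibration.

    Multi-member fibers are named ``fiber:<smallest member>``; singletons
    keep their own id.  The incoming edges of a base node are the
    (source fiber, sign) multiset of any single member — well defined by
    balance, which is checked first.  Distinct same-fiber sources with the
    same sign collapse to a single base edge (the base is a simple signed
    digraph).
    """
    check_balanced(net, partition)
    names: dict[int, str] = {}
    for fiber_id, members in partition.fibers.items():
        rep = min(members)
        names[fiber_id] = f"fiber:{rep}" if len(members) > 1 else rep
    edges: set[tuple[str, str, str]] = set()
    for fiber_id, members in partition.fibers.items():
        rep = min(members)
        for src, sign in net.in_edges(rep):
            edges.add((names[partition.fiber_of(src)], names[fiber_id], sign))
    return RegNetwork(frozenset(names.values()), frozenset(edges))
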