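"""Fiber building blocks and their |n, l> fiber numbers.

A fiber's *building block* is the fiber together with its external
regulators and the edges that feed it, including any feedback cycles the
fiber participates in.  Blocks are classified by two fiber numbers: ``l``,
the count of distinct external regulator nodes, and ``n``, the loop (or
branching) number — operationalised as the limiting ratio of successive
input-tree layer sizes on the cycle-carrying part of the block.  Simple
loops give integer n (0 for regulons, 1 for autoregulation and feed-forward
fibers, 2 for binary-tree fibers); feedback through a longer strongly
connected component yields non-integer golden-ratio-like values (Fibonacci
fibers).  A block whose regulators themselves form a multi-gene fiber is a
multilayer composite, labelled |n1,l1>(+)|n2,l2>.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import networkx as nx

from .fibration import FiberPartition, _layer_size_counts
from .grn import Edge, RegNetwork

__all__ = [
    "FiberBlock",
    "extract_block",
    "fiber_numbers",
    "classify",
    "fiber_size_histogram",
    "format_fiber_numbers",
]

_SNAP_TOL = 1e-6


@dataclass(frozen=True)
class FiberBlock:
    """One fiber plus its external regulators and induced edges.

    ``n`` is the loop/branching number and ``l`` the external-regulator
    count; ``layer_sizes`` records the input-tree layers used to compute
    ``n``.  ``class_label`` is one of regulon, ar-loop, fff, binary-tree,
    fibonacci, multilayer-composite, other; ``label`` is the pretty
    |n,l> form (with (+) for composites).
    """

    fiber_id: int
    members: frozenset[str]
    regulators: frozenset[str]
    edges: frozenset[Edge]
    n: Optional[float] = None
    l: Optional[int] = None
    layer_sizes: tuple[int, ...] = ()
    class_label: Optional[str] = None
    label: Optional[str] = None


def _block_digraph(edges: frozenset[Edge]) -> nx.DiGraph:
    g = nx.DiGraph()
    for s, t, _ in edges:
        g.add_edge(s, t)
    return g


def extract_block(
    net: RegNetwork, partition: FiberPartition, fiber_id: int
) -> FiberBlock:
    """Extract the building block of one fiber.

    The induced edge set contains every network edge targeting a fiber
    member, plus the edges of any strongly connected component (over the
    fiber-plus-regulators subgraph) that contains a fiber member — the
    latter captures feedback from the fiber through the network's SCC back
    to its regulators.  Fiber numbers are filled in by
    :func:`fiber_numbers`.
    """
    members = partition.members(fiber_id)
    regulators = frozenset(
        src
        for m in members
        for src, _ in net.in_edges(m)
        if src not in members
    )
    scope = members | regulators
    incoming = frozenset(
        (s, t, sign) for s, t, sign in net.edges if t in members
    )
    induced = [
        (s, t, sign) for s, t, sign in net.edges if s in scope and t in scope
    ]
    sub = nx.DiGraph()
    sub.add_nodes_from(scope)
    sub.add_edges_from((s, t) for s, t, _ in induced)
    cyc_edges: set[Edge] = set()
    for comp in nx.strongly_connected_components(sub):
        if not comp & members:
            continue
        for s, t, sign in induced:
            if s in comp and t in comp:
                cyc_edges.add((s, t, sign))
    block = FiberBlock(
        fiber_id=fiber_id,
        members=members,
        regulators=regulators,
        edges=incoming | frozenset(cyc_edges),
    )
    n, l, sizes = fiber_numbers(block)
    return replace(block, n=n, l=l, layer_sizes=sizes)


def _cycle_nodes_reaching(block: FiberBlock) -> set[str]:
    """Nodes of the block lying on a directed cycle that can reach the fiber."""
    g = _block_digraph(block.edges)
    cyclic: set[str] = set()
    for comp in nx.strongly_connected_components(g):
        comp = set(comp)
        if len(comp) > 1:
            cyclic |= comp
        else:
            (node,) = comp
            if g.has_edge(node, node):
                cyclic.add(node)
    if not cyclic:
        return set()
    reaches: set[str] = set()
    for node in cyclic:
        if node in block.members or any(
            t in block.members for t in nx.descendants(g, node)
        ):
            reaches.add(node)
    return reaches


def fiber_numbers(
    block: FiberBlock, depth: int = 50
) -> tuple[float, int, tuple[int, ...]]:
    """Compute (n, l) and the layer-size sequence behind n.

    ``l`` is the number of distinct external regulators.  ``n`` is the
    limiting ratio of successive input-tree layer sizes of a fiber member,
    computed on the block restricted to nodes that lie on directed cycles
    reaching the fiber — acyclic external regulators contribute a constant
    per layer and would mask the growth rate, so they only count toward
    ``l``.  A finite restricted tree (no feedback) gives n = 0.  The ratio
    is evaluated at ``depth`` and snapped to an integer within 1e-6.
    """
    if depth < 5:
        raise ValueError("depth < 5 makes the branching ratio unreliable")
    l = len(block.regulators)
    root = min(block.members)
    cyc = _cycle_nodes_reaching(block)
    keep = cyc | {root}
    restricted = RegNetwork(
        frozenset(keep),
        frozenset(
            (s, t, sign)
            for s, t, sign in block.edges
            if s in cyc and t in keep
        ),
    )
    sizes = _layer_size_counts(restricted, root, depth)
    if sizes[-1] == 0 or sizes[-2] == 0:
        return 0.0, l, tuple(sizes)
    n = sizes[-1] / sizes[-2]
    if abs(n - round(n)) < _SNAP_TOL:
        n = float(round(n))
    return n, l, tuple(sizes)


def format_fiber_numbers(n: float, l: int) -> str:
    """Render fiber numbers as ``|n,l>`` (non-integer n to 4 decimals)."""
    n_str = str(int(n)) if float(n).is_integer() else f"{n:.4f}"
    return f"|{n_str},{l}>"


def classify(
    block: FiberBlock,
    partition: FiberPartition,
    net: Optional[RegNetwork] = None,
    _seen: frozenset[int] = frozenset(),
) -> tuple[str, str]:
    """Assign the hierarchy class and pretty label of a block.

    Returns ``(class_label, label)``.  A block is a multilayer composite
    when any of its regulators belongs to a fiber of size >= 2; the label
    then chains the regulator fiber's own numbers, e.g. ``|0,1>(+)|1,1>``
    (one level deep; deeper chains nest).  Otherwise the class follows the
    fiber numbers: regulon (n=0), ar-loop (1,0), fff (1,1), binary-tree
    (n=2), fibonacci (non-integer n), other.
    """
    n, l = block.n, block.l
    if n is None or l is None:
        n, l, _ = fiber_numbers(block)
    own = format_fiber_numbers(n, l)
    reg_fibers = sorted(
        {
            partition.fiber_of(r)
            for r in block.regulators
            if len(partition.members(partition.fiber_of(r))) >= 2
        }
    )
    reg_fibers = [f for f in reg_fibers if f not in _seen]
    if reg_fibers and net is not None:
        parent = extract_block(net, partition, reg_fibers[0])
        if len(_seen) < 4:
            _, parent_label = classify(
                parent, partition, net, _seen | {block.fiber_id}
            )
        else:
            parent_label = format_fiber_numbers(parent.n, parent.l)
        return "multilayer-composite", f"{own}(+){parent_label}"
    if reg_fibers:
        return "multilayer-composite", f"{own}(+)?"
    if n == 0:
        return "regulon", own
    if (n, l) == (1.0, 0):
        return "ar-loop", own
    if (n, l) == (1.0, 1):
        return "fff", own
    if n == 2.0:
        return "binary-tree", own
    if not float(n).is_integer():
        return "fibonacci", own
    return "other", own


def classify_all(net: RegNetwork, partition: FiberPartition) -> list[FiberBlock]:
    """Extract and classify the block of every fiber, sorted by fiber id."""
    blocks = []
    for fiber_id in sorted(partition.fibers):
        block = extract_block(net, partition, fiber_id)
        class_label, label = classify(block, partition, net)
        blocks.append(replace(block, class_label=class_label, label=label))
    return blocks


def fiber_size_histogram(
    partition: FiberPartition, min_size: int = 2, max_size: int = 24
) -> dict[int, int]:
    """Count fibers by size within [min_size, max_size]."""
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    hist: dict[int, int] = {}
    for size in partition.sizes().values():
        if min_size <= size <= max_size:
            hist[size] = hist.get(size, 0) + 1
    return dict(sorted(hist.items()))
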