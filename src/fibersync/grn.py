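"""Signed gene regulatory networks: container, TSV dialects, and construction rules.

A gene regulatory network (GRN) is a directed graph whose nodes are genes or
operons and whose edges carry one of three regulatory signs: ``activation``,
``repression`` or ``dual``.  This module provides the in-memory container
(:class:`RegNetwork`), readers/writers for the tab-separated edge-list format
(including the SubtiWiki raw-label dialect), and the two normalisation steps
used to build analysis-ready bacterial networks: removal of sigma-factor genes
and collapsing of operons into single nodes (keeping one transcription factor
fused with the operon and splitting the remaining TFs into their own nodes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
REPRESSION = "repression"
DUAL = "dual"
#: The closed set of regulatory edge signs.
SIGNS = frozenset({ACTIVATION, REPRESSION, DUAL})

#: An edge is (source gene, target gene, sign).
Edge = tuple[str, str, str]


class GRNParseError(ValueError):
    """Raised when a GRN TSV file cannot be parsed."""


class UnknownLabelError(GRNParseError):
    """Raised when a raw effect label is outside the known mapping."""


class OperonTableError(ValueError):
    """Raised for inconsistent operon tables (e.g. a gene in two operons)."""


# Raw SubtiWiki-style effect labels and their canonical signs.
_LABEL_MAP: dict[str, str] = {
    "positive_regulation": ACTIVATION,
    "transcription_activation": ACTIVATION,
    "transcriptional_activation": ACTIVATION,
    "activation": ACTIVATION,
    "anti-activation": REPRESSION,
    "auto-repression": REPRESSION,
    "negative_autoregulation": REPRESSION,
    "transcription_repression": REPRESSION,
    "autorepression": REPRESSION,
    "negative_regulation": REPRESSION,
    "repression": REPRESSION,
    "dual": DUAL,
}


def normalize_edge_label(raw: str) -> str:
    """Map a raw regulatory-effect label to a canonical sign.

    The mapping is case-insensitive and total on the known label list;
    anything else raises :class:`UnknownLabelError`.
    """
    if not raw:
        raise UnknownLabelError("empty effect label")
    sign = _LABEL_MAP.get(raw.strip().lower())
    if sign is None:
        raise UnknownLabelError(f"unknown effect label: {raw!r}")
    return sign


@dataclass(frozen=True)
class RegNetwork:
    """A signed directed gene regulatory network.

    Node identifiers are case-sensitive non-empty strings.  Parallel edges
    between the same pair of nodes are permitted only with distinct signs
    (same-sign duplicates are collapsed on construction); self-loops are
    permitted.  Instances are immutable.
    """

    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for n in self.nodes:
            if not n:
                raise ValueError("empty node identifier")
        for s, t, sign in self.edges:
            if sign not in SIGNS:
                raise ValueError(f"invalid edge sign: {sign!r}")
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge endpoint not declared as node: ({s}, {t})")
        index: dict[str, list[tuple[str, str]]] = {n: [] for n in self.nodes}
        out: dict[str, list[tuple[str, str]]] = {n: [] for n in self.nodes}
        for s, t, sign in sorted(self.edges):
            index[t].append((s, sign))
            out[s].append((t, sign))
        object.__setattr__(self, "_in", {k: tuple(v) for k, v in index.items()})
        object.__setattr__(self, "_out", {k: tuple(v) for k, v in out.items()})

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], isolated: Iterable[str] = ()
    ) -> "RegNetwork":
        """Build a network from an edge list, inducing nodes from endpoints.

        Same-sign duplicate edges are collapsed with a logged warning.
        ``isolated`` declares additional nodes with no incident edges.
        """
        edge_list = list(edges)
        edge_set = frozenset(edge_list)
        if len(edge_set) < len(edge_list):
            logger.warning(
                "collapsed %d duplicate same-sign edge(s)",
                len(edge_list) - len(edge_set),
            )
        nodes = {s for s, _, _ in edge_set} | {t for _, t, _ in edge_set}
        nodes.update(isolated)
        return cls(frozenset(nodes), edge_set)

    # -- queries ---------------------------------------------------------

    def in_edges(self, node: str) -> tuple[tuple[str, str], ...]:
        """Incoming ``(source, sign)`` pairs of ``node``, sorted."""
        try:
            return self._in[node]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown node: {node!r}") from None

    def out_edges(self, node: str) -> tuple[tuple[str, str], ...]:
        """Outgoing ``(target, sign)`` pairs of ``node``, sorted."""
        try:
            return self._out[node]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown node: {node!r}") from None

    @property
    def isolated_nodes(self) -> frozenset[str]:
        return frozenset(
            n for n in self.nodes if not self.in_edges(n) and not self.out_edges(n)
        )

    def to_networkx(self):
        """Return the network as a ``networkx.MultiDiGraph`` with ``sign`` attrs."""
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for s, t, sign in sorted(self.edges):
            g.add_edge(s, t, sign=sign)
        return g


# -- TSV ingestion -------------------------------------------------------


def read_grn(
    path: str | Path,
    dialect: str = "plain",
    nodes_path: str | Path | None = None,
) -> RegNetwork:
    """Read a GRN edge-list TSV (header ``source<TAB>target<TAB>effect``).

    ``dialect='plain'`` accepts only the three canonical signs;
    ``dialect='subtiwiki'`` passes the effect column through
    :func:`normalize_edge_label`.  Lines starting with ``#`` are comments.
    An optional ``nodes_path`` file lists isolated node ids, one per line.
    """
    if dialect not in ("plain", "subtiwiki"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    edges: list[Edge] = []
    with path.open(encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                cols = [c.strip().lower() for c in fields[:3]]
                if cols != ["source", "target", "effect"]:
                    raise GRNParseError(
                        f"{path}:{lineno}: expected header "
                        f"'source\\ttarget\\teffect', got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) < 3:
                raise GRNParseError(f"{path}:{lineno}: expected 3 columns, got {line!r}")
            source, target, effect = (f.strip() for f in fields[:3])
            if not source or not target:
                raise GRNParseError(f"{path}:{lineno}: empty gene identifier")
            if dialect == "subtiwiki":
                try:
                    sign = normalize_edge_label(effect)
                except UnknownLabelError as exc:
                    raise GRNParseError(f"{path}:{lineno}: {exc}") from exc
            else:
                if effect not in SIGNS:
                    raise GRNParseError(
                        f"{path}:{lineno}: effect {effect!r} not one of "
                        f"{sorted(SIGNS)}"
                    )
                sign = effect
            edges.append((source, target, sign))
        if not header_seen:
            raise GRNParseError(f"{path}: missing header line")
    isolated: list[str] = []
    if nodes_path is not None:
        with Path(nodes_path).open(encoding="utf-8") as fh:
            for line in fh:
                name = line.strip()
                if name and not name.startswith("#"):
                    isolated.append(name)
    return RegNetwork.from_edges(edges, isolated=isolated)


def write_grn(
    net: RegNetwork,
    path: str | Path,
    nodes_path: str | Path | None = None,
) -> None:
    """Write the plain dialect, bit-exactly sorted by (source, target, sign).

    Isolated nodes go to ``nodes_path`` if given (they cannot be represented
    in the edge list); otherwise their presence is logged as a warning.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\teffect\n")
        for s, t, sign in sorted(net.edges):
            fh.write(f"{s}\t{t}\t{sign}\n")
    isolated = sorted(net.isolated_nodes)
    if nodes_path is not None:
        with Path(nodes_path).open("w", encoding="utf-8") as fh:
            for n in isolated:
                fh.write(n + "\n")
    elif isolated:
        logger.warning(
            "%d isolated node(s) not representable in the edge list: %s",
            len(isolated),
            ", ".join(isolated[:5]),
        )


# -- normalisation steps -------------------------------------------------


def remove_sigma_factors(net: RegNetwork, sigma_ids: Sequence[str]) -> RegNetwork:
    """Remove sigma-factor genes and all their incident edges.

    Ids absent from the network are ignored with a warning.  The input
    network is not modified.
    """
    sigma = set(sigma_ids)
    missing = sigma - set(net.nodes)
    if missing:
        logger.warning("sigma ids absent from network: %s", ", ".join(sorted(missing)))
    keep_nodes = frozenset(net.nodes - sigma)
    keep_edges = frozenset(
        (s, t, sign) for s, t, sign in net.edges if s not in sigma and t not in sigma
    )
    return RegNetwork(keep_nodes, keep_edges)


@dataclass(frozen=True)
class OperonRow:
    operon: str
    members: tuple[str, ...]
    tf_members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise OperonTableError(f"operon {self.operon!r} has no members")
        extra = set(self.tf_members) - set(self.members)
        if extra:
            raise OperonTableError(
                f"operon {self.operon!r}: TF members not in member list: {sorted(extra)}"
            )


@dataclass(frozen=True)
class OperonTable:
    """Operon composition: ordered member genes plus which members are TFs."""

    rows: tuple[OperonRow, ...]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for row in self.rows:
            for g in row.members:
                if g in seen:
                    raise OperonTableError(
                        f"gene {g!r} listed in operons {seen[g]!r} and {row.operon!r}"
                    )
                seen[g] = row.operon

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OperonTable":
        """Read ``operon<TAB>members(comma-sep)<TAB>tf_members(comma-sep)``."""
        rows: list[OperonRow] = []
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0].strip().lower() == "operon":
                    continue
                operon = fields[0].strip()
                members = tuple(
                    m.strip() for m in fields[1].split(",") if m.strip()
                ) if len(fields) > 1 else ()
                tfs = tuple(
                    m.strip() for m in fields[2].split(",") if m.strip()
                ) if len(fields) > 2 else ()
                rows.append(OperonRow(operon, members, tfs))
        return cls(tuple(rows))


def collapse_operons(
    net: RegNetwork,
    operons: OperonTable,
    incoming_to_split_tfs: bool = True,
) -> RegNetwork:
    """Collapse operon member genes into single operon nodes.

    Each operon becomes one node named by its operon id.  If an operon
    contains two or more TFs, the first TF (in member order) stays fused
    with the operon node and each remaining TF becomes its own node keeping
    its regulatory out-edges.  Incoming edges of a split TF are re-targeted
    to both the operon node and the split-TF node when
    ``incoming_to_split_tfs`` is true (the operon-wide-promoter reading),
    otherwise to the split TF only.  Members absent from the network are
    skipped; duplicate same-sign edges produced by the merge are collapsed.
    """
    member_of: dict[str, str] = {}
    split_tfs: set[str] = set()
    operon_present: dict[str, bool] = {}
    for row in operons.rows:
        present = [g for g in row.members if g in net.nodes]
        operon_present[row.operon] = bool(present)
        if not present:
            logger.warning("operon %s has no members in the network; skipped", row.operon)
            continue
        tfs_present = [g for g in row.members if g in row.tf_members and g in net.nodes]
        for g in present:
            member_of[g] = row.operon
        split_tfs.update(tfs_present[1:])

    def map_source(g: str) -> str:
        if g in split_tfs or g not in member_of:
            return g
        return member_of[g]

    def map_targets(g: str) -> tuple[str, ...]:
        if g not in member_of:
            return (g,)
        if g in split_tfs:
            if incoming_to_split_tfs:
                return (member_of[g], g)
            return (g,)
        return (member_of[g],)

    new_edges: list[Edge] = []
    for s, t, sign in net.edges:
        src = map_source(s)
        for tgt in map_targets(t):
            new_edges.append((src, tgt, sign))
    new_nodes: set[str] = set()
    for n in net.nodes:
        if n in member_of and n not in split_tfs:
            new_nodes.add(member_of[n])
        else:
            new_nodes.add(n)
    n_dupes = len(new_edges) - len(set(new_edges))
    if n_dupes:
        logger.warning("operon collapse merged %d duplicate same-sign edge(s)", n_dupes)
    return RegNetwork(frozenset(new_nodes), frozenset(new_edges))
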