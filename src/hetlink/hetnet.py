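"""Core data model for heterogeneous networks (hetnets).

A hetnet is a graph with typed nodes and typed edges. The type level is
described by a *metagraph*: its nodes are *metanodes* (node types, e.g.
Compound, Gene) and its edges are *metaedges* (edge types, e.g.
Compound-binds-Gene). Almost all metaedges are undirected; a directed
metaedge (e.g. Gene-regulates-Gene) is only meaningful when it connects a
metanode to itself and encodes an asymmetric relationship.

Type-level paths (*metapaths*) are ordered, endpoint-compatible sequences of
metaedge traversals. At the instance level, a :class:`HetNet` stores typed
nodes and edges with an orientation-aware adjacency index so that paths
conforming to a metapath can be extracted efficiently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

FORWARD = "forward"
BACKWARD = "backward"

#: key identifying a node inside a hetnet: (metanode kind, identifier)
NodeKey = tuple[str, str]


class HetnetError(ValueError):
    """Raised for schema or structural violations in metagraphs and hetnets."""


@dataclass(frozen=True)
class MetaNode:
    """A node type, e.g. ``Compound`` abbreviated ``C``."""

    kind: str
    abbrev: str

    def __post_init__(self) -> None:
        if not self.kind:
            raise HetnetError("metanode kind must be nonempty")
        if not self.abbrev:
            raise HetnetError(f"metanode {self.kind!r} needs an abbreviation")

    def __repr__(self) -> str:
        return f"MetaNode({self.kind})"


@dataclass(frozen=True)
class MetaEdge:
    """An edge type joining two metanodes with a verb-like kind.

    ``direction`` is ``"undirected"`` for symmetric relationships and
    ``"directed"`` for asymmetric self-relationships such as
    Gene-regulates-Gene. The composed abbreviation follows the
    source-abbrev + lowercase kind-abbrev + target-abbrev scheme, with
    ``>`` marking direction (e.g. ``CbG``, ``Gr>G``).
    """

    source: MetaNode
    target: MetaNode
    kind: str
    kind_abbrev: str
    direction: str = "undirected"

    def __post_init__(self) -> None:
        if self.direction not in ("undirected", "directed"):
            raise HetnetError(f"bad direction {self.direction!r}")
        if not self.kind_abbrev.islower():
            raise HetnetError(
                f"kind abbreviation {self.kind_abbrev!r} must be lowercase"
            )

    @property
    def directed(self) -> bool:
        return self.direction == "directed"

    @property
    def is_self(self) -> bool:
        return self.source == self.target

    @property
    def abbrev(self) -> str:
        marker = ">" if self.directed else ""
        return f"{self.source.abbrev}{self.kind_abbrev}{marker}{self.target.abbrev}"

    def __repr__(self) -> str:
        return f"MetaEdge({self.abbrev})"


def abbreviate_metaedge(metaedge: MetaEdge) -> str:
    """Return the composed abbreviation of a metaedge (e.g. ``CbG``, ``Gr>G``)."""
    return metaedge.abbrev


@dataclass(frozen=True)
class MetaStep:
    """One traversal of a metaedge within a metapath.

    Orientation is :data:`FORWARD` when the metaedge is traversed from its
    source metanode to its target metanode and :data:`BACKWARD` otherwise.
    For undirected self-metaedges the two orientations are indistinguishable
    and are canonicalized to forward.
    """

    metaedge: MetaEdge
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, BACKWARD):
            raise HetnetError(f"bad orientation {self.orientation!r}")
        if (
            self.orientation == BACKWARD
            and self.metaedge.is_self
            and not self.metaedge.directed
        ):
            # canonical orientation for undirected self-metaedges
            object.__setattr__(self, "orientation", FORWARD)

    @property
    def start(self) -> MetaNode:
        me = self.metaedge
        return me.source if self.orientation == FORWARD else me.target

    @property
    def end(self) -> MetaNode:
        me = self.metaedge
        return me.target if self.orientation == FORWARD else me.source

    def invert(self) -> "MetaStep":
        if self.metaedge.is_self and not self.metaedge.directed:
            return self
        flipped = BACKWARD if self.orientation == FORWARD else FORWARD
        return MetaStep(self.metaedge, flipped)

    @property
    def kind_fragment(self) -> str:
        """Abbreviation fragment for this traversal, e.g. ``b``, ``r>``, ``<r``."""
        ka = self.metaedge.kind_abbrev
        if not self.metaedge.directed:
            return ka
        return f"{ka}>" if self.orientation == FORWARD else f"<{ka}"


@dataclass(frozen=True)
class MetaPath:
    """An ordered, endpoint-compatible sequence of metaedge traversals."""

    steps: tuple[MetaStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise HetnetError("metapath needs at least one step")
        for left, right in zip(self.steps, self.steps[1:]):
            if left.end != right.start:
                raise HetnetError(
                    f"incompatible consecutive steps: {left.end.kind} != "
                    f"{right.start.kind}"
                )

    @property
    def source(self) -> MetaNode:
        return self.steps[0].start

    @property
    def target(self) -> MetaNode:
        return self.steps[-1].end

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def abbrev(self) -> str:
        parts = [self.source.abbrev]
        for step in self.steps:
            parts.append(step.kind_fragment)
            parts.append(step.end.abbrev)
        return "".join(parts)

    def invert(self) -> "MetaPath":
        return MetaPath(tuple(step.invert() for step in reversed(self.steps)))

    def __repr__(self) -> str:
        return f"MetaPath({self.abbrev})"


def invert_metapath(metapath: MetaPath) -> MetaPath:
    """Reverse a metapath, flipping each traversal's orientation."""
    return metapath.invert()


class MetaGraph:
    """The schema of a hetnet: a set of metanodes and metaedges."""

    def __init__(self) -> None:
        self.metanodes: dict[str, MetaNode] = {}
        self.metaedges: dict[tuple[str, str, str], MetaEdge] = {}
        self._abbrevs: dict[str, MetaEdge] = {}

    # -- construction ------------------------------------------------------

    def add_metanode(self, kind: str, abbrev: str) -> MetaNode:
        if kind in self.metanodes:
            raise HetnetError(f"duplicate metanode {kind!r}")
        if abbrev in {mn.abbrev for mn in self.metanodes.values()}:
            raise HetnetError(f"metanode abbreviation collision on {abbrev!r}")
        metanode = MetaNode(kind, abbrev)
        self.metanodes[kind] = metanode
        return metanode

    def add_metaedge(
        self,
        source_kind: str,
        kind: str,
        target_kind: str,
        kind_abbrev: str | None = None,
        direction: str = "undirected",
    ) -> MetaEdge:
        for endpoint in (source_kind, target_kind):
            if endpoint not in self.metanodes:
                raise HetnetError(f"unknown endpoint metanode {endpoint!r}")
        key = (source_kind, kind, target_kind)
        if key in self.metaedges:
            raise HetnetError(f"duplicate metaedge {key!r}")
        if kind_abbrev is None:
            kind_abbrev = kind[0].lower()
        metaedge = MetaEdge(
            self.metanodes[source_kind],
            self.metanodes[target_kind],
            kind,
            kind_abbrev,
            direction,
        )
        if metaedge.abbrev in self._abbrevs:
            raise HetnetError(f"metaedge abbreviation collision on {metaedge.abbrev!r}")
        self.metaedges[key] = metaedge
        self._abbrevs[metaedge.abbrev] = metaedge
        return metaedge

    # -- lookup ------------------------------------------------------------

    def get_metanode(self, kind: str) -> MetaNode:
        try:
            return self.metanodes[kind]
        except KeyError:
            raise HetnetError(f"unknown metanode {kind!r}") from None

    def get_metaedge(self, abbrev: str) -> MetaEdge:
        try:
            return self._abbrevs[abbrev]
        except KeyError:
            raise HetnetError(f"unknown metaedge abbreviation {abbrev!r}") from None

    def metaedges_of(self, metanode: MetaNode) -> list[MetaEdge]:
        """Metaedges with the given metanode as an endpoint."""
        return [
            me
            for me in self.metaedges.values()
            if me.source == metanode or me.target == metanode
        ]

    def steps_from(self, metanode: MetaNode) -> list[MetaStep]:
        """All distinct traversals starting at a metanode.

        An undirected self-metaedge contributes a single orientation-free
        traversal; every other metaedge contributes one traversal per
        compatible orientation, so a directed self-metaedge contributes two
        distinct traversals.
        """
        steps = []
        for me in self.metaedges.values():
            if me.is_self and not me.directed:
                if me.source == metanode:
                    steps.append(MetaStep(me, FORWARD))
                continue
            if me.source == metanode:
                steps.append(MetaStep(me, FORWARD))
            if me.target == metanode:
                steps.append(MetaStep(me, BACKWARD))
        return steps

    def metapath_from_abbrev(self, abbrev: str) -> MetaPath:
        """Parse a composed metapath abbreviation such as ``CbGaD``.

        Relies on the convention that metanode abbreviations are uppercase
        and kind abbreviations lowercase, with ``>``/``<`` marking the
        orientation of directed traversals.
        """
        tokens = re.findall(r"[A-Z]+|<[a-z]+|[a-z]+>|[a-z]+", abbrev)
        if "".join(tokens) != abbrev or len(tokens) < 3 or len(tokens) % 2 == 0:
            raise HetnetError(f"cannot parse metapath abbreviation {abbrev!r}")
        node_abbrevs = tokens[0::2]
        kind_frags = tokens[1::2]
        by_abbrev = {mn.abbrev: mn for mn in self.metanodes.values()}
        try:
            kinds = [by_abbrev[a] for a in node_abbrevs]
        except KeyError as exc:
            raise HetnetError(f"unknown metanode abbreviation {exc.args[0]!r}") from None
        steps = []
        for start, frag, end in zip(kinds, kind_frags, kinds[1:]):
            steps.append(self._resolve_step(start, frag, end, abbrev))
        return MetaPath(tuple(steps))

    def _resolve_step(
        self, start: MetaNode, frag: str, end: MetaNode, context: str
    ) -> MetaStep:
        backward_marked = frag.startswith("<")
        forward_marked = frag.endswith(">")
        kind_abbrev = frag.strip("<>")
        for me in self.metaedges.values():
            if me.kind_abbrev != kind_abbrev:
                continue
            if me.directed:
                if me.source == start and me.target == end and forward_marked:
                    return MetaStep(me, FORWARD)
                if me.target == start and me.source == end and backward_marked:
                    return MetaStep(me, BACKWARD)
            else:
                if me.source == start and me.target == end:
                    return MetaStep(me, FORWARD)
                if me.target == start and me.source == end:
                    return MetaStep(me, BACKWARD)
        raise HetnetError(
            f"no metaedge matches {start.abbrev}{frag}{end.abbrev} in {context!r}"
        )


def build_metagraph(
    metanodes: Iterable[tuple[str, str]],
    metaedges: Iterable[Sequence[str]],
) -> MetaGraph:
    """Build a metagraph from declarative specs.

    Parameters
    ----------
    metanodes:
        iterable of ``(kind, abbreviation)`` pairs.
    metaedges:
        iterable of ``(source_kind, kind, target_kind, kind_abbrev)`` tuples,
        with an optional fifth element ``"directed"``. ``kind_abbrev`` may be
        omitted (3-tuples), defaulting to the first letter of the kind.
    """
    mg = MetaGraph()
    for kind, abbrev in metanodes:
        mg.add_metanode(kind, abbrev)
    for spec in metaedges:
        spec = tuple(spec)
        source, kind, target = spec[:3]
        kind_abbrev = spec[3] if len(spec) > 3 else None
        direction = spec[4] if len(spec) > 4 else "undirected"
        mg.add_metaedge(source, kind, target, kind_abbrev, direction)
    return mg


@dataclass(frozen=True)
class Node:
    """A typed node instance. ``(metanode.kind, identifier)`` is unique."""

    metanode: MetaNode
    identifier: str
    name: str = ""
    properties: Mapping[str, object] = field(default_factory=dict, compare=False)

    @property
    def key(self) -> NodeKey:
        return (self.metanode.kind, self.identifier)

    def __repr__(self) -> str:
        return f"Node({self.metanode.abbrev}:{self.identifier})"


@dataclass(frozen=True)
class Edge:
    """A typed edge instance between two nodes."""

    metaedge: MetaEdge
    source: Node
    target: Node
    properties: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __repr__(self) -> str:
        arrow = ">" if self.metaedge.directed else "-"
        return (
            f"Edge({self.source.identifier}-{self.metaedge.kind}{arrow}"
            f"{self.target.identifier})"
        )


class HetNet:
    """A typed node/edge instance graph with orientation-aware adjacency.

    Self-edges (both endpoints the same node) and parallel edges of the same
    metaedge between the same node pair are forbidden. Undirected edges are
    stored once and traversable in both orientations; directed edges are
    traversable in both orientations, the backward orientation being a
    distinct traversal of the same edge.
    """

    def __init__(self, metagraph: MetaGraph) -> None:
        self.metagraph = metagraph
        self.nodes: dict[NodeKey, Node] = {}
        self._edges: dict[MetaEdge, dict[tuple[NodeKey, NodeKey], Edge]] = {
            me: {} for me in metagraph.metaedges.values()
        }
        # (node key, metaedge, orientation) -> {neighbor key: edge}
        self._adj: dict[tuple[NodeKey, MetaEdge, str], dict[NodeKey, Edge]] = {}

    # -- nodes -------------------------------------------------------------

    def add_node(
        self,
        metanode: MetaNode | str,
        identifier: str,
        name: str = "",
        properties: Mapping[str, object] | None = None,
    ) -> Node:
        if isinstance(metanode, str):
            metanode = self.metagraph.get_metanode(metanode)
        node = Node(metanode, str(identifier), name or str(identifier), properties or {})
        if node.key in self.nodes:
            raise HetnetError(f"duplicate node {node.key!r}")
        self.nodes[node.key] = node
        return node

    def get_node(self, metanode_kind: str, identifier: str) -> Node:
        try:
            return self.nodes[(metanode_kind, str(identifier))]
        except KeyError:
            raise HetnetError(
                f"unknown node ({metanode_kind!r}, {identifier!r})"
            ) from None

    def nodes_of(self, metanode: MetaNode | str) -> list[Node]:
        if isinstance(metanode, str):
            metanode = self.metagraph.get_metanode(metanode)
        return [n for n in self.nodes.values() if n.metanode == metanode]

    # -- edges -------------------------------------------------------------

    def _edge_key(
        self, metaedge: MetaEdge, source: NodeKey, target: NodeKey
    ) -> tuple[NodeKey, NodeKey]:
        # undirected self-metaedge edges are identified up to endpoint order
        if metaedge.is_self and not metaedge.directed and target < source:
            return (target, source)
        return (source, target)

    def add_edge(
        self,
        metaedge: MetaEdge | str,
        source: Node | str,
        target: Node | str,
        properties: Mapping[str, object] | None = None,
    ) -> Edge:
        if isinstance(metaedge, str):
            metaedge = self.metagraph.get_metaedge(metaedge)
        if isinstance(source, str):
            source = self.get_node(metaedge.source.kind, source)
        if isinstance(target, str):
            target = self.get_node(metaedge.target.kind, target)
        if source.metanode != metaedge.source or target.metanode != metaedge.target:
            raise HetnetError(
                f"endpoint metanodes ({source.metanode.kind}, "
                f"{target.metanode.kind}) do not match {metaedge.abbrev}"
            )
        if source.key not in self.nodes or target.key not in self.nodes:
            raise HetnetError("edge endpoints must be added to the hetnet first")
        if source.key == target.key:
            raise HetnetError(f"self-edge forbidden: {source.key!r}")
        key = self._edge_key(metaedge, source.key, target.key)
        if key in self._edges[metaedge]:
            raise HetnetError(
                f"duplicate {metaedge.abbrev} edge {source.key!r}-{target.key!r}"
            )
        edge = Edge(metaedge, source, target, properties or {})
        self._edges[metaedge][key] = edge
        self._index(edge)
        return edge

    def _index(self, edge: Edge, remove: bool = False) -> None:
        me = edge.metaedge
        entries = [
            (edge.source.key, FORWARD, edge.target.key),
            (edge.target.key, BACKWARD, edge.source.key),
        ]
        if not me.directed:
            # undirected: both orientations yield identical neighbor sets
            entries += [
                (edge.source.key, BACKWARD, edge.target.key),
                (edge.target.key, FORWARD, edge.source.key),
            ]
        for node_key, orientation, neighbor in entries:
            bucket = self._adj.setdefault((node_key, me, orientation), {})
            if remove:
                bucket.pop(neighbor, None)
            else:
                bucket[neighbor] = edge

    def remove_edge(self, edge: Edge) -> None:
        me = edge.metaedge
        key = self._edge_key(me, edge.source.key, edge.target.key)
        if key not in self._edges[me]:
            raise HetnetError(f"edge not present: {edge!r}")
        del self._edges[me][key]
        self._index(edge, remove=True)

    def edges(self, metaedge: MetaEdge | str | None = None) -> Iterator[Edge]:
        if metaedge is None:
            for bucket in self._edges.values():
                yield from bucket.values()
            return
        if isinstance(metaedge, str):
            metaedge = self.metagraph.get_metaedge(metaedge)
        yield from self._edges[metaedge].values()

    def edge_count(self, metaedge: MetaEdge | str | None = None) -> int:
        if metaedge is None:
            return sum(len(b) for b in self._edges.values())
        if isinstance(metaedge, str):
            metaedge = self.metagraph.get_metaedge(metaedge)
        return len(self._edges[metaedge])

    def has_edge(
        self, metaedge: MetaEdge | str, source: Node, target: Node
    ) -> bool:
        if isinstance(metaedge, str):
            metaedge = self.metagraph.get_metaedge(metaedge)
        key = self._edge_key(metaedge, source.key, target.key)
        return key in self._edges[metaedge]

    # -- traversal ---------------------------------------------------------

    def neighbors(
        self, node: Node, metaedge: MetaEdge, orientation: str = FORWARD
    ) -> dict[NodeKey, Edge]:
        """Neighbors reachable by traversing ``metaedge`` from ``node``.

        For undirected metaedges the two orientations are equivalent; for
        directed metaedges :data:`FORWARD` follows the arrow and
        :data:`BACKWARD` opposes it.
        """
        if metaedge not in self._edges:
            raise HetnetError(f"metaedge {metaedge!r} not in metagraph")
        return self._adj.get((node.key, metaedge, orientation), {})

    def degree(
        self, node: Node, metaedge: MetaEdge, orientation: str = FORWARD
    ) -> int:
        """Number of ``metaedge`` edges traversable from ``node``.

        Undirected metaedges give the same count in either orientation; for
        directed metaedges forward is out-degree and backward is in-degree.
        """
        if node.key not in self.nodes:
            raise HetnetError(f"node {node.key!r} not in hetnet")
        return len(self.neighbors(node, metaedge, orientation))


@dataclass(frozen=True)
class PathStep:
    """One instance-level traversal of an edge within a path."""

    edge: Edge
    orientation: str

    @property
    def start(self) -> Node:
        return self.edge.source if self.orientation == FORWARD else self.edge.target

    @property
    def end(self) -> Node:
        return self.edge.target if self.orientation == FORWARD else self.edge.source


@dataclass(frozen=True)
class Path:
    """An instance path conforming to a metapath, with no repeated nodes."""

    steps: tuple[PathStep, ...]

    @property
    def nodes(self) -> tuple[Node, ...]:
        return (self.steps[0].start,) + tuple(step.end for step in self.steps)

    @property
    def source(self) -> Node:
        return self.steps[0].start

    @property
    def target(self) -> Node:
        return self.steps[-1].end

    def __len__(self) -> int:
        return len(self.steps)

    def __repr__(self) -> str:
        labels = [self.source.identifier]
        for step in self.steps:
            labels.append(step.edge.metaedge.kind_abbrev)
            labels.append(step.end.identifier)
        return "Path(" + "-".join(labels) + ")"
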