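"""Instance-level path extraction and the degree-weighted path count (DWPC).

The DWPC measures the prevalence of a metapath between a source and target
node while damping the influence of hubs. Every node-distinct path
conforming to the metapath is weighted by its *path-degree product* (PDP):
the product, over traversed edges, of the two endpoint degrees — specific
to that edge's metaedge and traversal orientation — each raised to ``-w``.
The damping exponent ``w`` (default 0.4) is the method's sole parameter;
``w = 0`` recovers the raw path count.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hetnet import (
    BACKWARD,
    FORWARD,
    Edge,
    HetNet,
    HetnetError,
    MetaEdge,
    MetaPath,
    Node,
    Path,
    PathStep,
)


@dataclass(frozen=True)
class DwpcConfig:
    """Settings for DWPC computation.

    ``damping_exponent`` is the hub-damping exponent ``w``;
    ``exclude_query_edge`` omits paths traversing the direct edge between
    the queried pair itself (when one exists for the excluded metaedge),
    limiting self-testing leakage when featurizing supervised pairs.
    """

    damping_exponent: float = 0.4
    exclude_query_edge: bool = True

    def __post_init__(self) -> None:
        if self.damping_exponent < 0:
            raise HetnetError("damping exponent must be >= 0")


def extract_paths(
    hetnet: HetNet,
    metapath: MetaPath,
    source: Node,
    target: Node,
    exclude_edges: frozenset[Edge] | set[Edge] | None = None,
) -> list[Path]:
    """All node-distinct paths from ``source`` to ``target`` along ``metapath``.

    ``exclude_edges`` drops any path traversing one of the given edges (used
    to omit the supervised query edge itself).
    """
    if source.metanode != metapath.source:
        raise HetnetError(
            f"source metanode {source.metanode.kind} does not match "
            f"metapath start {metapath.source.kind}"
        )
    if target.metanode != metapath.target:
        raise HetnetError(
            f"target metanode {target.metanode.kind} does not match "
            f"metapath end {metapath.target.kind}"
        )
    if source.key == target.key:
        # a node-distinct path cannot both start and end at the same node
        return []
    exclude_edges = exclude_edges or frozenset()
    paths: list[Path] = []
    steps: list[PathStep] = []
    visited = {source.key}

    def extend(current: Node, depth: int) -> None:
        metastep = metapath.steps[depth]
        last = depth == len(metapath) - 1
        for neighbor_key, edge in hetnet.neighbors(
            current, metastep.metaedge, metastep.orientation
        ).items():
            if edge in exclude_edges:
                continue
            if last:
                if neighbor_key != target.key:
                    continue
            elif neighbor_key in visited or neighbor_key == target.key:
                # target may only appear as the terminal node
                continue
            steps.append(PathStep(edge, _edge_orientation(edge, current)))
            if last:
                paths.append(Path(tuple(steps)))
            else:
                visited.add(neighbor_key)
                extend(hetnet.nodes[neighbor_key], depth + 1)
                visited.discard(neighbor_key)
            steps.pop()

    extend(source, 0)
    return paths


def _edge_orientation(edge: Edge, start: Node) -> str:
    return FORWARD if edge.source.key == start.key else BACKWARD


def path_degree_product(
    hetnet: HetNet, path: Path, damping_exponent: float = 0.4
) -> float:
    """The PDP of one path: product of 2·length degree factors, each ``^-w``."""
    w = damping_exponent
    pdp = 1.0
    for step in path.steps:
        me = step.edge.metaedge
        out_orient = step.orientation
        in_orient = BACKWARD if step.orientation == FORWARD else FORWARD
        d_out = hetnet.degree(step.start, me, out_orient)
        d_in = hetnet.degree(step.end, me, in_orient)
        if d_out == 0 or d_in == 0:
            raise HetnetError("zero degree along a realized path")
        pdp *= (d_out * d_in) ** -w
    return pdp


def dwpc(
    hetnet: HetNet,
    metapath: MetaPath,
    source: Node,
    target: Node,
    config: DwpcConfig | None = None,
    query_metaedge: MetaEdge | None = None,
) -> float:
    """Degree-weighted path count: sum of PDPs over conforming paths.

    When ``config.exclude_query_edge`` is set and ``query_metaedge`` directly
    joins the pair, paths through that specific edge are omitted. Degrees in
    the PDP are always computed on the full hetnet.
    """
    config = config or DwpcConfig()
    exclude: set[Edge] = set()
    if config.exclude_query_edge and query_metaedge is not None:
        bucket = hetnet.neighbors(source, query_metaedge, FORWARD)
        edge = bucket.get(target.key)
        if edge is not None:
            exclude.add(edge)
    paths = extract_paths(hetnet, metapath, source, target, exclude)
    return sum(
        path_degree_product(hetnet, p, config.damping_exponent) for p in paths
    )


def degree_feature_definitions(
    hetnet_or_metagraph,
    source_metanode,
    target_metanode,
    exclude_metaedge: MetaEdge | None = None,
) -> list[tuple[str, MetaEdge]]:
    """Ordered (endpoint, metaedge) definitions for degree features.

    One feature per metaedge incident to the source metanode and one per
    metaedge incident to the target metanode, excluding the supervised
    metaedge on both sides. On the full biomedical schema with
    Compound/Disease endpoints and the treatment metaedge excluded this
    yields 14 features.
    """
    mg = getattr(hetnet_or_metagraph, "metagraph", hetnet_or_metagraph)
    if isinstance(source_metanode, str):
        source_metanode = mg.get_metanode(source_metanode)
    if isinstance(target_metanode, str):
        target_metanode = mg.get_metanode(target_metanode)
    defs: list[tuple[str, MetaEdge]] = []
    for endpoint, metanode in (("source", source_metanode), ("target", target_metanode)):
        for me in sorted(mg.metaedges_of(metanode), key=lambda m: m.abbrev):
            if me == exclude_metaedge:
                continue
            defs.append((endpoint, me))
    return defs


def degree_features(
    hetnet: HetNet,
    pair: tuple[Node, Node],
    definitions: list[tuple[str, MetaEdge]],
) -> list[int]:
    """Per-pair degree feature values in the order of ``definitions``."""
    source, target = pair
    values = []
    for endpoint, me in definitions:
        node = source if endpoint == "source" else target
        orientation = FORWARD if me.source == node.metanode else BACKWARD
        values.append(hetnet.degree(node, me, orientation))
    return values
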