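"""Hetnet interchange formats: JSON, TSV edge lists, and Cypher emission.

The JSON document is the lossless canonical format: it round-trips the
metagraph, node set (with properties such as source/license/url), and edge
set. The TSV edge list is a lossy convenience format (drops properties and
requires a metagraph to read back). Cypher emission produces plain CREATE
statements — node labels are metanode kinds with spaces removed and
relationship types are the uppercased verb joined to the metaedge
abbreviation (e.g. ``TREATS_CtD``) — so exported networks can be loaded
into a graph database without this package running a server.
"""

from __future__ import annotations

import json
from pathlib import Path as FilePath
from typing import IO

from .hetnet import (
    FORWARD,
    HetNet,
    HetnetError,
    MetaGraph,
    MetaPath,
    build_metagraph,
)

SCHEMA_VERSION = 1


# -- JSON ------------------------------------------------------------------


def metagraph_to_dict(metagraph: MetaGraph) -> dict:
    return {
        "metanodes": [
            {"kind": mn.kind, "abbrev": mn.abbrev}
            for mn in sorted(metagraph.metanodes.values(), key=lambda m: m.kind)
        ],
        "metaedges": [
            {
                "source": me.source.kind,
                "kind": me.kind,
                "target": me.target.kind,
                "kind_abbrev": me.kind_abbrev,
                "direction": me.direction,
            }
            for me in sorted(metagraph.metaedges.values(), key=lambda m: m.abbrev)
        ],
    }


def metagraph_from_dict(document: dict) -> MetaGraph:
    try:
        metanodes = [(mn["kind"], mn["abbrev"]) for mn in document["metanodes"]]
        metaedges = [
            (
                me["source"],
                me["kind"],
                me["target"],
                me["kind_abbrev"],
                me.get("direction", "undirected"),
            )
            for me in document["metaedges"]
        ]
    except KeyError as exc:
        raise HetnetError(f"metagraph document missing key {exc.args[0]!r}") from None
    return build_metagraph(metanodes, metaedges)


def write_hetnet_json(hetnet: HetNet) -> dict:
    """Serialize a hetnet to a JSON-ready document (lossless)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "metagraph": metagraph_to_dict(hetnet.metagraph),
        "nodes": [
            {
                "kind": node.metanode.kind,
                "identifier": node.identifier,
                "name": node.name,
                "data": dict(node.properties),
            }
            for node in sorted(hetnet.nodes.values(), key=lambda n: n.key)
        ],
        "edges": [
            {
                "source_id": edge.source.identifier,
                "target_id": edge.target.identifier,
                "metaedge": edge.metaedge.abbrev,
                "data": dict(edge.properties),
            }
            for edge in sorted(
                hetnet.edges(),
                key=lambda e: (
                    e.metaedge.abbrev,
                    e.source.identifier,
                    e.target.identifier,
                ),
            )
        ],
    }


def read_hetnet_json(document: dict) -> HetNet:
    """Deserialize a hetnet from a JSON document, validating references."""
    for key in ("metagraph", "nodes", "edges"):
        if key not in document:
            raise HetnetError(f"hetnet document missing key {key!r}")
    metagraph = metagraph_from_dict(document["metagraph"])
    hetnet = HetNet(metagraph)
    for node in document["nodes"]:
        try:
            hetnet.add_node(
                node["kind"],
                node["identifier"],
                node.get("name", ""),
                node.get("data", {}),
            )
        except KeyError as exc:
            raise HetnetError(f"node record missing key {exc.args[0]!r}") from None
    for record in document["edges"]:
        if "metaedge" not in record:
            raise HetnetError("edge record missing key 'metaedge'")
        metaedge = metagraph.get_metaedge(record["metaedge"])
        for side, kind in (
            ("source_id", metaedge.source.kind),
            ("target_id", metaedge.target.kind),
        ):
            if side not in record:
                raise HetnetError(f"edge record missing key {side!r}")
            if (kind, str(record[side])) not in hetnet.nodes:
                raise HetnetError(
                    f"dangling endpoint: {record['metaedge']} edge references "
                    f"absent node ({kind!r}, {record[side]!r})"
                )
        hetnet.add_edge(
            metaedge,
            hetnet.get_node(metaedge.source.kind, record["source_id"]),
            hetnet.get_node(metaedge.target.kind, record["target_id"]),
            record.get("data", {}),
        )
    return hetnet


def save_hetnet_json(hetnet: HetNet, path: str | FilePath) -> None:
    with open(path, "w") as handle:
        json.dump(write_hetnet_json(hetnet), handle, indent=1)


def load_hetnet_json(path: str | FilePath) -> HetNet:
    with open(path) as handle:
        return read_hetnet_json(json.load(handle))


def hetnets_equal(a: HetNet, b: HetNet) -> bool:
    """Structural equality: metagraph, node set (with names/properties),
    and edge set (with properties)."""
    return write_hetnet_json(a) == write_hetnet_json(b)


# -- TSV edge list ---------------------------------------------------------

TSV_HEADER = "source_id\tmetaedge\ttarget_id"


def write_edges_tsv(hetnet: HetNet, handle: IO[str]) -> None:
    """Write the edge list as TSV. Lossy: node names and all properties of
    nodes and edges are dropped, as are isolated nodes."""
    handle.write(TSV_HEADER + "\n")
    for edge in sorted(
        hetnet.edges(),
        key=lambda e: (e.metaedge.abbrev, e.source.identifier, e.target.identifier),
    ):
        handle.write(
            f"{edge.source.identifier}\t{edge.metaedge.abbrev}\t"
            f"{edge.target.identifier}\n"
        )


def read_edges_tsv(handle: IO[str], metagraph: MetaGraph) -> HetNet:
    """Read a TSV edge list into a hetnet, given its metagraph."""
    hetnet = HetNet(metagraph)
    header = handle.readline().rstrip("\n")
    if header != TSV_HEADER:
        raise HetnetError(f"unexpected TSV header {header!r}")
    for line_no, line in enumerate(handle, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise HetnetError(f"line {line_no}: expected 3 columns")
        source_id, abbrev, target_id = fields
        metaedge = metagraph.get_metaedge(abbrev)
        for kind, identifier in (
            (metaedge.source.kind, source_id),
            (metaedge.target.kind, target_id),
        ):
            if (kind, identifier) not in hetnet.nodes:
                hetnet.add_node(kind, identifier)
        hetnet.add_edge(
            metaedge,
            hetnet.get_node(metaedge.source.kind, source_id),
            hetnet.get_node(metaedge.target.kind, target_id),
        )
    return hetnet


# -- Cypher ----------------------------------------------------------------


def _label(kind: str) -> str:
    return kind.replace(" ", "")


def relationship_type(metaedge) -> str:
    return f"{metaedge.kind.upper()}_{metaedge.abbrev.replace('>', '')}"


def _quote(value: str) -> str:
    return "'" + str(value).replace("\\", "\\\\").replace("'", "\\'") + "'"


def emit_cypher(hetnet: HetNet) -> list[str]:
    """CREATE statements for every node and edge, in deterministic order.

    One statement per node (ordered by kind then identifier) and one per
    edge (ordered by metaedge then endpoints); undirected relationships are
    emitted in their stored orientation, as is conventional for property
    graphs that treat relationship direction as traversal-agnostic.
    """
    statements = []
    for node in sorted(hetnet.nodes.values(), key=lambda n: n.key):
        statements.append(
            f"CREATE (:{_label(node.metanode.kind)} "
            f"{{identifier: {_quote(node.identifier)}, name: {_quote(node.name)}}})"
        )
    for edge in sorted(
        hetnet.edges(),
        key=lambda e: (e.metaedge.abbrev, e.source.identifier, e.target.identifier),
    ):
        statements.append(
            f"MATCH (s:{_label(edge.metaedge.source.kind)} "
            f"{{identifier: {_quote(edge.source.identifier)}}}), "
            f"(t:{_label(edge.metaedge.target.kind)} "
            f"{{identifier: {_quote(edge.target.identifier)}}}) "
            f"CREATE (s)-[:{relationship_type(edge.metaedge)}]->(t)"
        )
    return statements


def metapath_to_cypher(metapath: MetaPath) -> str:
    """Render a metapath as a Cypher MATCH pattern string."""
    parts = [f"(n0:{_label(metapath.source.kind)})"]
    for i, step in enumerate(metapath.steps):
        rel = f"[:{relationship_type(step.metaedge)}]"
        if step.metaedge.directed:
            left, right = ("-", "->") if step.orientation == FORWARD else ("<-", "-")
        else:
            left, right = "-", "-"
        parts.append(f"{left}{rel}{right}(n{i + 1}:{_label(step.end.kind)})")
    return "MATCH path = " + "".join(parts)
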