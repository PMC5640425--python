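"""Type-level path enumeration on a metagraph.

Metapath identity is orientation-sensitive: a directed self-metaedge
contributes both of its orientations as distinct traversal steps, so a
Gene->Gene metapath and its inverse are counted separately unless they are
literally identical. Undirected self-metaedges contribute a single,
orientation-free traversal. Immediate back-and-forth over the same
undirected metaedge (e.g. CbGbC) is a legitimate metapath.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hetnet import HetnetError, MetaGraph, MetaNode, MetaPath, MetaStep


def enumerate_metapaths(
    metagraph: MetaGraph,
    source: MetaNode | str,
    target: MetaNode | str,
    min_length: int = 1,
    max_length: int = 4,
) -> list[MetaPath]:
    """All metapaths from ``source`` to ``target`` with length in range.

    Results are deterministic: sorted by length, then abbreviation.
    Metaedges may repeat within a metapath; the only constraint is endpoint
    compatibility and total length.
    """
    if min_length < 1:
        raise HetnetError("min_length must be >= 1")
    if max_length < min_length:
        raise HetnetError("max_length must be >= min_length")
    if isinstance(source, str):
        source = metagraph.get_metanode(source)
    if isinstance(target, str):
        target = metagraph.get_metanode(target)

    results: list[MetaPath] = []
    stack: list[MetaStep] = []

    def extend(current: MetaNode) -> None:
        if min_length <= len(stack) and current == target:
            results.append(MetaPath(tuple(stack)))
        if len(stack) >= max_length:
            return
        for step in metagraph.steps_from(current):
            stack.append(step)
            extend(step.end)
            stack.pop()

    extend(source)
    results.sort(key=lambda mp: (mp.length, mp.abbrev))
    return results


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Number of metapaths of one length for each ordered metanode pair."""

    length: int
    counts: dict[tuple[str, str], int]

    def __getitem__(self, pair: tuple[str, str]) -> int:
        return self.counts[pair]


def connectivity_matrix(metagraph: MetaGraph, length: int) -> ConnectivityMatrix:
    """Metapath counts of exactly ``length`` for every metanode pair.

    Computed via matrix powers of the step-count matrix (the number of
    traversal steps between metanode pairs), which agrees with exhaustive
    enumeration because metapath counts only depend on per-step choices.
    """
    if length < 1:
        raise HetnetError("length must be >= 1")
    kinds = sorted(metagraph.metanodes)
    index = {kind: i for i, kind in enumerate(kinds)}
    n = len(kinds)
    step_counts = [[0] * n for _ in range(n)]
    for kind in kinds:
        for step in metagraph.steps_from(metagraph.metanodes[kind]):
            step_counts[index[kind]][index[step.end.kind]] += 1
    power = [row[:] for row in step_counts]
    for _ in range(length - 1):
        power = [
            [
                sum(power[i][k] * step_counts[k][j] for k in range(n))
                for j in range(n)
            ]
            for i in range(n)
        ]
    counts = {
        (a, b): power[index[a]][index[b]] for a in kinds for b in kinds
    }
    return ConnectivityMatrix(length, counts)
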