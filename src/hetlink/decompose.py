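"""Decompose one prediction into its network support.

A prediction's positive support is attributed hierarchically: first across
metapath features (via their logistic-regression terms), then within each
metapath across the individual paths (via each path's share of the DWPC),
and finally aggregated over the paths' first (source-side) and last
(target-side) edges. Percentages are conserved at every level: path
percentages sum to their metapath's percentage and edge aggregations
redistribute the same mass.

Only positively contributing metapath terms enter the percentages; prior,
degree, and negative terms are excluded from the decomposition and reported
separately as diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dwpc import DwpcConfig, extract_paths, path_degree_product
from .features import DWPC_PREFIX
from .hetnet import FORWARD, HetNet, HetnetError, MetaEdge, MetaPath, Node, Path
from .model import ModelFit


@dataclass
class ContributionReport:
    """Hierarchical percentage attribution for a single prediction."""

    source: str
    target: str
    metapath_percents: pd.Series
    paths: pd.DataFrame
    source_edge_percents: pd.Series
    target_edge_percents: pd.Series
    negative_terms: pd.Series
    no_positive_support: bool = False


def metapath_contributions(
    fit: ModelFit, feature_row: pd.Series
) -> tuple[pd.Series, pd.Series, bool]:
    """Percent contribution of each positively supporting metapath term.

    ``feature_row`` holds transformed (but unstandardized) feature values;
    standardization is applied from the fit. Each metapath's term is
    coefficient times standardized value; percentages are positive terms
    normalized to 100. Returns (percents, negative_terms, no_positive_flag).
    """
    terms = {}
    supported = {}
    for name in fit.feature_names:
        if not name.startswith(DWPC_PREFIX):
            continue
        z = (feature_row[name] - fit.means[name]) / fit.stds[name]
        abbrev = name[len(DWPC_PREFIX):]
        terms[abbrev] = float(fit.coefficients[name] * z)
        supported[abbrev] = feature_row[name] > 0
    terms = pd.Series(terms, dtype=float)
    has_paths = pd.Series(supported)
    # a metapath with no paths for this pair (zero DWPC) cannot positively
    # support it, even if centering makes its term positive
    positive = terms[(terms > 0) & has_paths]
    negative = terms[(terms != 0) & ~terms.index.isin(positive.index)]
    if positive.empty:
        return pd.Series(dtype=float), negative, True
    percents = 100.0 * positive / positive.sum()
    return percents.sort_values(ascending=False), negative, False


def path_contributions(
    hetnet: HetNet,
    metapath: MetaPath,
    source: Node,
    target: Node,
    metapath_percent: float,
    config: DwpcConfig | None = None,
    query_metaedge: MetaEdge | None = None,
) -> pd.DataFrame:
    """Split a metapath's percentage across its paths by path-degree product.

    Each path receives ``metapath_percent * pdp / dwpc``; rows are ranked by
    descending percentage. Raises if the metapath has a positive percentage
    but no paths (an inconsistent state).
    """
    config = config or DwpcConfig()
    exclude = set()
    if config.exclude_query_edge and query_metaedge is not None:
        edge = hetnet.neighbors(source, query_metaedge, FORWARD).get(target.key)
        if edge is not None:
            exclude.add(edge)
    paths = extract_paths(hetnet, metapath, source, target, exclude)
    if not paths:
        if metapath_percent > 0:
            raise HetnetError(
                f"metapath {metapath.abbrev} has percent {metapath_percent} "
                "but no paths"
            )
        return pd.DataFrame(columns=["metapath", "path", "pdp", "percent"])
    pdps = [
        path_degree_product(hetnet, p, config.damping_exponent) for p in paths
    ]
    total = sum(pdps)
    frame = pd.DataFrame(
        {
            "metapath": metapath.abbrev,
            "path": paths,
            "pdp": pdps,
            "percent": [metapath_percent * w / total for w in pdps],
        }
    )
    return frame.sort_values("percent", ascending=False).reset_index(drop=True)


def terminal_edge_contributions(
    paths: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Aggregate path percentages by first (source) and last (target) edge."""
    source_totals: dict[str, float] = {}
    target_totals: dict[str, float] = {}
    for row in paths.itertuples(index=False):
        path: Path = row.path
        first = repr(path.steps[0].edge)
        last = repr(path.steps[-1].edge)
        source_totals[first] = source_totals.get(first, 0.0) + row.percent
        target_totals[last] = target_totals.get(last, 0.0) + row.percent
    return (
        pd.Series(source_totals, dtype=float).sort_values(ascending=False),
        pd.Series(target_totals, dtype=float).sort_values(ascending=False),
    )


def explain_prediction(
    fit: ModelFit,
    hetnet: HetNet,
    source: Node,
    target: Node,
    feature_row: pd.Series,
    metapaths: dict[str, MetaPath],
    config: DwpcConfig | None = None,
    query_metaedge: MetaEdge | None = None,
) -> ContributionReport:
    """Full metapath -> path -> terminal-edge decomposition for one pair."""
    percents, negatives, empty = metapath_contributions(fit, feature_row)
    frames = []
    for abbrev, percent in percents.items():
        frames.append(
            path_contributions(
                hetnet,
                metapaths[abbrev],
                source,
                target,
                percent,
                config,
                query_metaedge,
            )
        )
    paths = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["metapath", "path", "pdp", "percent"])
    )
    paths = paths.sort_values("percent", ascending=False).reset_index(drop=True)
    source_edges, target_edges = terminal_edge_contributions(paths)
    return ContributionReport(
        source=source.identifier,
        target=target.identifier,
        metapath_percents=percents,
        paths=paths,
        source_edge_percents=source_edges,
        target_edge_percents=target_edges,
        negative_terms=negatives,
        no_positive_support=empty,
    )
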