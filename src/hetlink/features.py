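"""Feature assembly and permutation-adjusted feature assessment.

For each compound-disease pair the features are: the degree-conditional
prior probability of connection (entered as its logit), per-metaedge node
degrees of the two endpoints, and one DWPC per metapath. Raw DWPCs are
heavily right-skewed, so each column is mean-scaled and passed through the
inverse hyperbolic sine before modeling.

A metapath's informativeness is judged against degree-preserving permuted
hetnets: delta AUROC is the feature's AUROC on the real network minus its
mean AUROC across permuted networks, isolating signal attributable to edge
specificity rather than node degree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .dwpc import DwpcConfig, degree_feature_definitions, degree_features, dwpc
from .hetnet import HetNet, HetnetError, MetaEdge, MetaPath, Node

DWPC_PREFIX = "dwpc:"
DEGREE_PREFIX = "degree:"


def compute_feature_matrix(
    hetnet: HetNet,
    pairs: list[tuple[Node, Node]],
    metapaths: list[MetaPath],
    prior: pd.DataFrame | None = None,
    config: DwpcConfig | None = None,
    query_metaedge: MetaEdge | None = None,
    include_degree_features: bool = True,
) -> pd.DataFrame:
    """Raw (untransformed) feature matrix for compound-disease pairs.

    Columns: ``source``, ``target``, ``prior``, ``degree:<end>:<metaedge>``
    per degree feature, and ``dwpc:<abbrev>`` per metapath. ``prior`` is
    looked up from the frame returned by
    :func:`hetlink.permutation.estimate_prior` (missing pairs get 0).
    """
    config = config or DwpcConfig()
    rows: list[dict[str, object]] = []
    prior_map: dict[tuple[str, str], float] = {}
    if prior is not None:
        prior_map = {
            (r.source, r.target): r.prior for r in prior.itertuples(index=False)
        }
    degree_defs = []
    if include_degree_features and pairs:
        degree_defs = degree_feature_definitions(
            hetnet,
            pairs[0][0].metanode,
            pairs[0][1].metanode,
            exclude_metaedge=query_metaedge,
        )
    for source, target in pairs:
        row: dict[str, object] = {
            "source": source.identifier,
            "target": target.identifier,
            "prior": prior_map.get((source.identifier, target.identifier), 0.0),
        }
        for (endpoint, me), value in zip(
            degree_defs, degree_features(hetnet, (source, target), degree_defs)
        ):
            row[f"{DEGREE_PREFIX}{endpoint}:{me.abbrev}"] = value
        for metapath in metapaths:
            row[f"{DWPC_PREFIX}{metapath.abbrev}"] = dwpc(
                hetnet, metapath, source, target, config, query_metaedge
            )
        rows.append(row)
    return pd.DataFrame(rows)


def transform_dwpc(values: np.ndarray | pd.Series) -> np.ndarray:
    """Mean-scale then inverse-hyperbolic-sine one feature column.

    ``x' = asinh(x / mean(x))``; an all-zero column (mean 0) is returned
    unchanged. Negative inputs are invalid (DWPCs and degrees are counts).
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise HetnetError("transform_dwpc requires nonnegative values")
    mean = arr.mean()
    if mean == 0:
        return arr.copy()
    return np.arcsinh(arr / mean)


def transform_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply the mean-scale + asinh transform to DWPC and degree columns.

    Degree features receive the same transform as DWPCs: both are
    nonnegative, right-skewed counts. Other columns pass through.
    """
    out = matrix.copy()
    for col in feature_columns(matrix):
        out[col] = transform_dwpc(matrix[col].to_numpy())
    return out


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [
        c
        for c in matrix.columns
        if c.startswith(DWPC_PREFIX) or c.startswith(DEGREE_PREFIX)
    ]


def feature_metadata(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column metadata: one row per feature with its type and definition."""
    records = []
    for col in matrix.columns:
        if col.startswith(DWPC_PREFIX):
            records.append(
                {"column": col, "feature_type": "dwpc", "definition": col[len(DWPC_PREFIX):]}
            )
        elif col.startswith(DEGREE_PREFIX):
            endpoint, metaedge = col[len(DEGREE_PREFIX):].split(":")
            records.append(
                {
                    "column": col,
                    "feature_type": "degree",
                    "definition": f"{endpoint} {metaedge}",
                }
            )
        elif col == "prior":
            records.append(
                {
                    "column": col,
                    "feature_type": "prior",
                    "definition": "permutation prior probability",
                }
            )
    return pd.DataFrame(records)


def sample_negatives(
    negatives: list,
    n_positives: int,
    k_per_positive: int = 4,
    seed: int = 0,
) -> list:
    """Uniform subsample of negative pairs, ``k_per_positive`` per positive.

    The sample size is capped at the available pool. The all-features stage
    assesses feature performance on positives plus this subsample; the
    predominant limit on AUROC precision is the positive count, so little is
    lost by not scoring every negative.
    """
    if k_per_positive < 1:
        raise HetnetError("k_per_positive must be >= 1")
    size = min(k_per_positive * n_positives, len(negatives))
    rng = np.random.default_rng(seed)
    index = rng.choice(len(negatives), size=size, replace=False)
    return [negatives[i] for i in sorted(index)]


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise HetnetError("auroc requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def delta_auroc(
    values: np.ndarray,
    labels: np.ndarray,
    permuted_values: np.ndarray,
) -> dict[str, float | bool]:
    """Permutation-adjusted performance of one feature.

    ``permuted_values`` has one row per permuted hetnet. The p-value tests
    whether the real-network AUROC deviates from the permuted AUROCs via a
    predictive t-test: the observed AUROC is compared to the permuted sample
    with standard error ``sd * sqrt(1 + 1/k)`` and ``k - 1`` degrees of
    freedom. Degenerate permuted variance yields an indeterminate p and a
    flag.
    """
    permuted_values = np.atleast_2d(np.asarray(permuted_values, dtype=float))
    k = permuted_values.shape[0]
    if k < 2:
        raise HetnetError("delta_auroc requires >= 2 permuted feature columns")
    observed = auroc(values, labels)
    permuted = np.array([auroc(row, labels) for row in permuted_values])
    perm_mean = float(permuted.mean())
    delta = observed - perm_mean
    sd = float(permuted.std(ddof=1))
    if sd == 0.0:
        return {
            "auroc": observed,
            "auroc_permuted_mean": perm_mean,
            "delta_auroc": delta,
            "p_value": float("nan"),
            "indeterminate": True,
        }
    t_stat = delta / (sd * np.sqrt(1.0 + 1.0 / k))
    p = float(2.0 * stats.t.sf(abs(t_stat), df=k - 1))
    return {
        "auroc": observed,
        "auroc_permuted_mean": perm_mean,
        "delta_auroc": delta,
        "p_value": p,
        "indeterminate": False,
    }


def assess_metapaths(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    permuted_matrices: list[pd.DataFrame],
) -> pd.DataFrame:
    """Delta AUROC, p, and Benjamini-Hochberg q for every DWPC column.

    ``matrix`` and each element of ``permuted_matrices`` are feature
    matrices over the same pairs; the permuted ones are computed on permuted
    hetnets. Returns one row per metapath, indexed by abbreviation.
    """
    labels = np.asarray(labels)
    records = {}
    for col in matrix.columns:
        if not col.startswith(DWPC_PREFIX):
            continue
        permuted = np.vstack(
            [pm[col].to_numpy(dtype=float) for pm in permuted_matrices]
        )
        records[col[len(DWPC_PREFIX):]] = delta_auroc(
            matrix[col].to_numpy(dtype=float), labels, permuted
        )
    result = pd.DataFrame.from_dict(records, orient="index")
    result.index.name = "metapath"
    valid = result["p_value"].notna()
    result["fdr_q"] = np.nan
    if valid.any():
        result.loc[valid, "fdr_q"] = multipletests(
            result.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    return result


def select_features(
    records: pd.DataFrame,
    fdr_threshold: float = 0.05,
    require_positive_delta: bool = True,
    metapaths: dict[str, MetaPath] | None = None,
    exclude_first_metaedge: MetaEdge | None = None,
) -> list[str]:
    """Metapath abbreviations retained for modeling.

    Keeps metapaths with ``fdr_q <= fdr_threshold`` (and positive delta
    AUROC by default), dropping indeterminate features. Optionally excludes
    metapaths whose first step traverses the supervised metaedge, guarding
    against edge-dropout contamination.
    """
    keep = records["fdr_q"] <= fdr_threshold
    if require_positive_delta:
        keep &= records["delta_auroc"] > 0
    keep &= ~records["p_value"].isna()
    selected = list(records.index[keep])
    if exclude_first_metaedge is not None:
        if metapaths is None:
            raise HetnetError(
                "metapaths mapping required to exclude by first metaedge"
            )
        selected = [
            abbrev
            for abbrev in selected
            if metapaths[abbrev].steps[0].metaedge != exclude_first_metaedge
        ]
    return selected


def scoring_summary(
    n_source_nodes: int,
    n_target_nodes: int,
    n_positives: int,
    n_sources_with_positive: int,
    n_targets_with_positive: int,
) -> dict[str, float]:
    """Study-design arithmetic for an edge-prediction task.

    Given the connected source/target node counts, the number of known
    positive edges, and the counts of sources/targets touched by at least
    one positive, derives: the number of scored pairs, the positive
    prevalence (percent), the nonzero-prior block size (only pairs whose
    endpoints both have supervised degree > 0 can have a nonzero
    permutation prior), the training negatives within that block, and the
    zero-prior pairs omitted from training.
    """
    scored_pairs = n_source_nodes * n_target_nodes
    nonzero_prior = n_sources_with_positive * n_targets_with_positive
    return {
        "scored_pairs": scored_pairs,
        "prevalence_percent": 100.0 * n_positives / scored_pairs,
        "nonzero_prior_pairs": nonzero_prior,
        "training_negatives": nonzero_prior - n_positives,
        "omitted_zero_prior_pairs": scored_pairs - nonzero_prior,
    }
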