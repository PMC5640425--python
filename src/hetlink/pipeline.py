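"""Two-stage edge-prediction workflow.

The workflow is bifurcated into an *all-features* stage and an
*all-observations* stage. The all-features stage assesses every candidate
metapath's DWPC on the positives plus a random subsample of negatives
(negative subsampling loses little, because AUROC precision is limited by
the positive count), against a Markov chain of permuted hetnets. The
all-observations stage restricts to the nonzero-prior block — pairs whose
endpoints both have supervised degree — computes features there for the
selected metapaths, and fits the elastic-net logistic model with the
unpenalized prior term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dwpc import DwpcConfig
from .features import (
    assess_metapaths,
    compute_feature_matrix,
    sample_negatives,
    select_features,
    transform_features,
)
from .hetnet import HetNet, MetaPath
from .metapaths import enumerate_metapaths
from .model import PRIOR_LOGIT, fit_model, logit
from .permutation import PermutationSettings, estimate_prior, permutation_chain
from .synthetic import SynthSpec, generate_study


def _pairs(hetnet: HetNet, frame: pd.DataFrame, treats) -> list:
    return [
        (
            hetnet.get_node(treats.source.kind, row.source),
            hetnet.get_node(treats.target.kind, row.target),
        )
        for row in frame.itertuples(index=False)
    ]


def all_features_stage(
    hetnet: HetNet,
    labels: pd.DataFrame,
    metapaths: list[MetaPath],
    treats_abbrev: str = "CtD",
    k_negatives: int = 4,
    n_permutations: int = 5,
    swap_multiplier: float = 10.0,
    damping: float = 0.4,
    seed: int = 0,
) -> dict:
    """Assess metapath DWPCs against permuted baselines.

    Returns the assessment records (delta AUROC, p, q per metapath), the
    stage pair frame with labels, and the real/permuted feature matrices.
    """
    rng = np.random.default_rng(seed)
    treats = hetnet.metagraph.get_metaedge(treats_abbrev)
    config = DwpcConfig(damping_exponent=damping)
    positives = labels[labels["label"]]
    negatives = labels[~labels["label"]]
    sampled = sample_negatives(
        list(negatives.itertuples(index=False)),
        len(positives),
        k_negatives,
        seed=int(rng.integers(2**31)),
    )
    stage = pd.concat(
        [positives, pd.DataFrame(sampled)], ignore_index=True
    )[["source", "target", "label"]]
    y = stage["label"].to_numpy()

    chain, diagnostics = permutation_chain(
        hetnet,
        PermutationSettings(
            swap_multiplier, n_permutations, int(rng.integers(2**31))
        ),
    )
    matrix = compute_feature_matrix(
        hetnet, _pairs(hetnet, stage, treats), metapaths, None, config, treats
    )
    permuted_matrices = [
        compute_feature_matrix(
            permuted,
            _pairs(permuted, stage, treats),
            metapaths,
            None,
            config,
            treats,
            include_degree_features=False,
        )
        for permuted in chain
    ]
    records = assess_metapaths(matrix, y, permuted_matrices)
    return {
        "records": records,
        "stage": stage,
        "labels": y,
        "matrix": matrix,
        "permuted_matrices": permuted_matrices,
        "chain_diagnostics": diagnostics,
    }


def all_observations_stage(
    hetnet: HetNet,
    labels: pd.DataFrame,
    metapaths: list[MetaPath],
    treats_abbrev: str = "CtD",
    n_prior_permutations: int = 500,
    damping: float = 0.4,
    l1_ratio: float = 0.2,
    cv: int = 5,
    seed: int = 0,
) -> dict:
    """Fit the model on the nonzero-prior block with selected metapaths."""
    rng = np.random.default_rng(seed)
    treats = hetnet.metagraph.get_metaedge(treats_abbrev)
    config = DwpcConfig(damping_exponent=damping)
    edges = [
        (e.source.identifier, e.target.identifier) for e in hetnet.edges(treats)
    ]
    prior = estimate_prior(
        edges,
        n_permutations=n_prior_permutations,
        seed=int(rng.integers(2**31)),
    )
    block = prior[prior["prior"] > 0][["source", "target"]].reset_index(drop=True)
    label_map = {
        (row.source, row.target): row.label
        for row in labels.itertuples(index=False)
    }
    y = np.array(
        [
            label_map[(row.source, row.target)]
            for row in block.itertuples(index=False)
        ],
        dtype=float,
    )
    matrix = compute_feature_matrix(
        hetnet, _pairs(hetnet, block, treats), metapaths, prior, config, treats
    )
    matrix = transform_features(matrix)
    matrix[PRIOR_LOGIT] = logit(matrix["prior"].to_numpy())
    fit = fit_model(
        matrix, y, l1_ratio=l1_ratio, cv=cv, seed=int(rng.integers(2**31))
    )
    return {"matrix": matrix, "labels": y, "fit": fit, "prior": prior}


def run_study_replicate(
    seed: int,
    spec: SynthSpec | None = None,
    max_length: int = 3,
    n_permutations: int = 5,
    n_prior_permutations: int = 500,
    cv: int = 3,
) -> dict:
    """One full synthetic replicate: generate, assess, select, fit.

    Returns the assessment records, the selected metapaths, the fitted
    model, and the planted mechanisms' abbreviations.
    """
    import dataclasses

    spec = spec if spec is not None else SynthSpec(seed=seed)
    if spec.seed != seed:
        spec = dataclasses.replace(spec, seed=seed)
    hetnet, labels = generate_study(spec)
    mg = hetnet.metagraph
    treats = mg.get_metaedge(spec.treats_metaedge)
    metapaths = enumerate_metapaths(
        mg, treats.source, treats.target, 2, max_length
    )
    mp_map = {mp.abbrev: mp for mp in metapaths}
    assessed = all_features_stage(
        hetnet,
        labels,
        metapaths,
        spec.treats_metaedge,
        n_permutations=n_permutations,
        seed=seed + 1_000,
    )
    selected = select_features(assessed["records"])
    planted = [abbrev for abbrev, _ in spec.mechanisms]
    # fall back to the planted set so the fit stage always has features
    fit_abbrevs = selected or planted
    observed = all_observations_stage(
        hetnet,
        labels,
        [mp_map[a] for a in fit_abbrevs],
        spec.treats_metaedge,
        n_prior_permutations=n_prior_permutations,
        cv=cv,
        seed=seed + 2_000,
    )
    return {
        "hetnet": hetnet,
        "labels": labels,
        "records": assessed["records"],
        "assessed": assessed,
        "selected": selected,
        "fit": observed["fit"],
        "observations": observed,
        "planted": planted,
        "metapaths": mp_map,
    }
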