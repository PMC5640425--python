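import pytest

from hetlink import SynthSpec, generate_study
from hetlink.hetionet import hetionet_metagraph


@pytest.fixture(scope="session")
def hetionet_mg():
    return hetionet_metagraph()


@pytest.fixture(scope="session")
def toy_metagraph():
    """Compound/Gene/Disease schema with a supervised treats metaedge."""
    return SynthSpec().metagraph()


@pytest.fixture()
def chain_hetnet(toy_metagraph):
    """Minimal hetnet: c1-binds-g1-associates-d1 plus an isolated compound."""
    from hetlink import HetNet

    net = HetNet(toy_metagraph)
    c1 = net.add_node("Compound", "c1")
    net.add_node("Compound", "c_isolated")
    g1 = net.add_node("Gene", "g1")
    d1 = net.add_node("Disease", "d1")
    net.add_edge("CbG", c1, g1)
    net.add_edge("DaG", d1, g1)
    return net


@pytest.fixture(scope="session")
def small_study():
    """Small synthetic hetnet sized for brute-force path oracles."""
    spec = SynthSpec(
        node_counts=(("Compound", 10), ("Disease", 6), ("Gene", 14)),
        edge_counts=(("CbG", 25), ("CrC", 12), ("DaG", 20), ("GiG", 18)),
        prevalence=0.05,
        seed=11,
    )
    return generate_study(spec)


@pytest.fixture(scope="session")
def synth_study():
    """Default-scale synthetic study with the planted CbGaD mechanism."""
    return generate_study(SynthSpec(seed=5))


@pytest.fixture(scope="session")
def fitted_study(synth_study):
    """Feature matrix and fitted model on the nonzero-prior block."""
    import numpy as np

    from hetlink import (
        compute_feature_matrix,
        estimate_prior,
        fit_model,
        transform_features,
    )
    from hetlink.model import PRIOR_LOGIT, logit

    net, labels = synth_study
    mg = net.metagraph
    treats = mg.get_metaedge("CtD")
    metapaths = {
        a: mg.metapath_from_abbrev(a)
        for a in ("CbGaD", "CrCtD", "CbGbCtD", "CbGiGaD")
    }
    edges = [(e.source.identifier, e.target.identifier) for e in net.edges(treats)]
    prior = estimate_prior(edges, n_permutations=500, seed=21)
    block = prior[prior.prior > 0][["source", "target"]]
    label_map = {
        (r.source, r.target): r.label for r in labels.itertuples(index=False)
    }
    y = np.array(
        [label_map[(r.source, r.target)] for r in block.itertuples(index=False)],
        dtype=float,
    )
    pairs = [
        (net.get_node("Compound", r.source), net.get_node("Disease", r.target))
        for r in block.itertuples(index=False)
    ]
    matrix = compute_feature_matrix(
        net, pairs, list(metapaths.values()), prior, query_metaedge=treats
    )
    matrix = transform_features(matrix)
    matrix[PRIOR_LOGIT] = logit(matrix["prior"].to_numpy())
    fit = fit_model(matrix, y, cv=5, seed=3)
    return {
        "net": net,
        "labels": labels,
        "matrix": matrix,
        "y": y,
        "fit": fit,
        "metapaths": metapaths,
        "treats": treats,
    }
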