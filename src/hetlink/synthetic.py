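"""Seeded generator of hetnets with known ground truth.

The generator emulates the structural features of integrative biomedical
hetnets that the prediction method relies on: typed nodes, heavy-tailed
metaedge-specific degree distributions, and treatment edges whose
occurrence correlates with planted metapaths (mechanisms). Node degrees are
skewed by sampling edge endpoints proportionally to per-node lognormal
propensities — only heavy-tailedness matters for exercising the DWPC's hub
damping, not any particular degree law.

Treatment labels are planted from a logistic model: for each
compound-disease pair, P(treatment) = sigmoid(baseline logit + sum over
planted mechanisms of effect * asinh(path count along the mechanism's
metapath)). Positive pairs become supervised edges in the hetnet, so the
generated network is self-consistent with its labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dwpc import extract_paths
from .hetnet import HetNet, HetnetError, MetaGraph, build_metagraph

DEFAULT_METANODES = [
    ("Compound", "C"),
    ("Disease", "D"),
    ("Gene", "G"),
]

DEFAULT_METAEDGES = [
    ("Compound", "binds", "Gene", "b"),
    ("Compound", "resembles", "Compound", "r"),
    ("Compound", "treats", "Disease", "t"),
    ("Disease", "associates", "Gene", "a"),
    ("Gene", "interacts", "Gene", "i"),
]


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a synthetic hetnet and its planted supervision.

    Defaults describe a desk-scale network: ~260 nodes and ~1100 edges,
    large enough for stable AUROCs yet small enough for brute-force
    oracles. ``degree_skew`` is the sigma of the lognormal endpoint
    propensities (0 gives near-uniform degrees). ``mechanisms`` maps
    metapath abbreviations to additive effects on the treatment log-odds
    scale, applied to asinh(path count). ``prevalence`` is the baseline
    treatment probability for pairs with no mechanism paths.
    """

    metanodes: tuple = tuple(DEFAULT_METANODES)
    metaedges: tuple = tuple(DEFAULT_METAEDGES)
    node_counts: tuple = (("Compound", 50), ("Disease", 25), ("Gene", 140))
    edge_counts: tuple = (
        ("CbG", 300),
        ("CrC", 120),
        ("DaG", 280),
        ("GiG", 320),
    )
    treats_metaedge: str = "CtD"
    mechanisms: tuple = (("CbGaD", 2.5),)
    prevalence: float = 0.015
    degree_skew: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise HetnetError("prevalence must be in (0, 1)")
        if any(count <= 0 for _, count in self.node_counts):
            raise HetnetError("node counts must be positive")
        if self.degree_skew < 0:
            raise HetnetError("degree_skew must be >= 0")

    def metagraph(self) -> MetaGraph:
        return build_metagraph(self.metanodes, self.metaedges)


def generate_hetnet(spec: SynthSpec) -> HetNet:
    """Generate the typed node/edge structure (without treatment edges)."""
    mg = spec.metagraph()
    rng = np.random.default_rng(spec.seed)
    hetnet = HetNet(mg)
    node_ids: dict[str, list[str]] = {}
    for kind, count in spec.node_counts:
        metanode = mg.get_metanode(kind)
        prefix = metanode.abbrev.lower()
        ids = [f"{prefix}{i}" for i in range(count)]
        for identifier in ids:
            hetnet.add_node(metanode, identifier)
        node_ids[kind] = ids

    for abbrev, n_edges in spec.edge_counts:
        me = mg.get_metaedge(abbrev)
        src_ids = node_ids[me.source.kind]
        tgt_ids = node_ids[me.target.kind]
        if me.is_self:
            possible = len(src_ids) * (len(src_ids) - 1) // 2
        else:
            possible = len(src_ids) * len(tgt_ids)
        if n_edges > possible:
            raise HetnetError(
                f"{abbrev}: requested {n_edges} edges exceeds {possible} "
                "possible simple edges"
            )
        src_w = _propensities(rng, len(src_ids), spec.degree_skew)
        tgt_w = _propensities(rng, len(tgt_ids), spec.degree_skew)
        seen: set[tuple[str, str]] = set()
        attempts = 0
        max_attempts = 500 * n_edges + 1000
        while len(seen) < n_edges:
            attempts += 1
            if attempts > max_attempts:
                raise HetnetError(
                    f"{abbrev}: could not place {n_edges} simple edges with "
                    f"degree_skew={spec.degree_skew}"
                )
            s = src_ids[rng.choice(len(src_ids), p=src_w)]
            t = tgt_ids[rng.choice(len(tgt_ids), p=tgt_w)]
            if s == t:
                continue
            if me.is_self and not me.directed and t < s:
                s, t = t, s
            if (s, t) in seen:
                continue
            seen.add((s, t))
            hetnet.add_edge(
                me,
                hetnet.get_node(me.source.kind, s),
                hetnet.get_node(me.target.kind, t),
            )
    return hetnet


def _propensities(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    weights = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return weights / weights.sum()


def plant_treatments(hetnet: HetNet, spec: SynthSpec) -> pd.DataFrame:
    """Sample treatment labels from the planted-mechanism logistic model.

    Positive pairs are added to the hetnet as supervised (treats) edges.
    Returns one row per compound-disease pair with the label, the true
    treatment probability, and the per-mechanism path counts used.
    """
    mg = hetnet.metagraph
    treats = mg.get_metaedge(spec.treats_metaedge)
    rng = np.random.default_rng(spec.seed + 1)
    metapaths = {
        abbrev: mg.metapath_from_abbrev(abbrev) for abbrev, _ in spec.mechanisms
    }
    compounds = hetnet.nodes_of(treats.source)
    diseases = hetnet.nodes_of(treats.target)
    base = logit(spec.prevalence)
    rows = []
    for compound in compounds:
        for disease in diseases:
            eta = base
            counts = {}
            for abbrev, effect in spec.mechanisms:
                n_paths = len(
                    extract_paths(hetnet, metapaths[abbrev], compound, disease)
                )
                counts[f"paths:{abbrev}"] = n_paths
                eta += effect * np.arcsinh(n_paths)
            prob = float(expit(eta))
            label = bool(rng.random() < prob)
            rows.append(
                {
                    "source": compound.identifier,
                    "target": disease.identifier,
                    "label": label,
                    "true_probability": prob,
                    **counts,
                }
            )
            if label:
                hetnet.add_edge(treats, compound, disease)
    return pd.DataFrame(rows)


def generate_study(spec: SynthSpec) -> tuple[HetNet, pd.DataFrame]:
    """Generate a hetnet plus planted treatment labels in one call."""
    hetnet = generate_hetnet(spec)
    labels = plant_treatments(hetnet, spec)
    return hetnet, labels
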