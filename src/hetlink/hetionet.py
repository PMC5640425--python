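"""The Hetionet v1.0 schema: 11 metanodes and 24 metaedges.

This module encodes only the published type-level schema of the integrative
biomedical hetnet (node types, edge types, abbreviations, directionality) —
not the network instance itself. The sole directed metaedge is
Gene-regulates-Gene; every other relationship is undirected.
"""

from __future__ import annotations

from .hetnet import MetaGraph, build_metagraph

METANODES: list[tuple[str, str]] = [
    ("Anatomy", "A"),
    ("Biological Process", "BP"),
    ("Cellular Component", "CC"),
    ("Compound", "C"),
    ("Disease", "D"),
    ("Gene", "G"),
    ("Molecular Function", "MF"),
    ("Pathway", "PW"),
    ("Pharmacologic Class", "PC"),
    ("Side Effect", "SE"),
    ("Symptom", "S"),
]

# (source kind, verb, target kind, kind abbreviation[, "directed"])
METAEDGES: list[tuple[str, ...]] = [
    ("Anatomy", "downregulates", "Gene", "d"),
    ("Anatomy", "expresses", "Gene", "e"),
    ("Anatomy", "upregulates", "Gene", "u"),
    ("Compound", "binds", "Gene", "b"),
    ("Compound", "causes", "Side Effect", "c"),
    ("Compound", "downregulates", "Gene", "d"),
    ("Compound", "palliates", "Disease", "p"),
    ("Compound", "resembles", "Compound", "r"),
    ("Compound", "treats", "Disease", "t"),
    ("Compound", "upregulates", "Gene", "u"),
    ("Disease", "associates", "Gene", "a"),
    ("Disease", "downregulates", "Gene", "d"),
    ("Disease", "localizes", "Anatomy", "l"),
    ("Disease", "presents", "Symptom", "p"),
    ("Disease", "resembles", "Disease", "r"),
    ("Disease", "upregulates", "Gene", "u"),
    ("Gene", "covaries", "Gene", "c"),
    ("Gene", "interacts", "Gene", "i"),
    ("Gene", "participates", "Biological Process", "p"),
    ("Gene", "participates", "Cellular Component", "p"),
    ("Gene", "participates", "Molecular Function", "p"),
    ("Gene", "participates", "Pathway", "p"),
    ("Gene", "regulates", "Gene", "r", "directed"),
    ("Pharmacologic Class", "includes", "Compound", "i"),
]

#: the supervised edge type for treatment prediction
TREATS = "CtD"


def hetionet_metagraph() -> MetaGraph:
    """Build the Hetionet v1.0 metagraph (11 metanodes, 24 metaedges)."""
    return build_metagraph(METANODES, METAEDGES)
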