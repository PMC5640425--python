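"""Path extraction, path-degree products, and the DWPC."""

import itertools

import pytest

from hetlink import (
    BACKWARD,
    FORWARD,
    DwpcConfig,
    HetnetError,
    degree_feature_definitions,
    degree_features,
    dwpc,
    extract_paths,
    path_degree_product,
)
from hetlink.metapaths import enumerate_metapaths


def brute_force_paths(hetnet, metapath, source, target):
    """Oracle: enumerate node sequences and validate edges step by step."""
    kinds = [metapath.source.kind] + [s.end.kind for s in metapath.steps]
    candidates = [
        [n for n in hetnet.nodes.values() if n.metanode.kind == kind]
        for kind in kinds
    ]
    found = []
    for sequence in itertools.product(*candidates):
        if sequence[0] != source or sequence[-1] != target:
            continue
        if len({n.key for n in sequence}) != len(sequence):
            continue
        for (a, b), step in zip(itertools.pairwise(sequence), metapath.steps):
            me = step.metaedge
            if me.directed:
                # forward follows the arrow a->b, backward opposes it
                wanted = (a, b) if step.orientation == FORWARD else (b, a)
                ok = any(
                    (e.source, e.target) == wanted for e in hetnet.edges(me)
                )
            elif me.is_self:
                ok = hetnet.has_edge(me, a, b)
            elif me.source.kind == a.metanode.kind:
                ok = hetnet.has_edge(me, a, b)
            else:
                ok = hetnet.has_edge(me, b, a)
            if not ok:
                break
        else:
            found.append(tuple(n.key for n in sequence))
    return sorted(found)


def scan_degree(hetnet, node, metaedge, traversal_orientation):
    """Degree by raw edge-list scan, independent of the adjacency index."""
    if not metaedge.directed:
        return sum(
            1
            for e in hetnet.edges(metaedge)
            if e.source == node or e.target == node
        )
    if traversal_orientation == FORWARD:
        return sum(1 for e in hetnet.edges(metaedge) if e.source == node)
    return sum(1 for e in hetnet.edges(metaedge) if e.target == node)


def brute_force_dwpc(hetnet, metapath, source, target, w):
    """Oracle: brute-force sequences + explicit degree products."""
    nodes = hetnet.nodes
    total = 0.0
    for sequence in brute_force_paths(hetnet, metapath, source, target):
        product = 1.0
        for (a_key, b_key), step in zip(
            itertools.pairwise(sequence), metapath.steps
        ):
            a, b = nodes[a_key], nodes[b_key]
            me = step.metaedge
            d_out = scan_degree(hetnet, a, me, step.orientation)
            d_in = scan_degree(
                hetnet, b, me,
                BACKWARD if step.orientation == FORWARD else FORWARD,
            )
            product *= (d_out * d_in) ** -w
        total += product
    return total


class TestExtractPaths:
    def test_disconnected_pair_empty(self, chain_hetnet):
        mg = chain_hetnet.metagraph
        mp = mg.metapath_from_abbrev("CbGaD")
        iso = chain_hetnet.get_node("Compound", "c_isolated")
        d1 = chain_hetnet.get_node("Disease", "d1")
        assert extract_paths(chain_hetnet, mp, iso, d1) == []

    def test_forced_chain_single_path(self, chain_hetnet):
        mg = chain_hetnet.metagraph
        mp = mg.metapath_from_abbrev("CbGaD")
        c1 = chain_hetnet.get_node("Compound", "c1")
        d1 = chain_hetnet.get_node("Disease", "d1")
        paths = extract_paths(chain_hetnet, mp, c1, d1)
        assert len(paths) == 1
        assert [n.identifier for n in paths[0].nodes] == ["c1", "g1", "d1"]

    def test_type_mismatch_rejected(self, chain_hetnet):
        mg = chain_hetnet.metagraph
        mp = mg.metapath_from_abbrev("CbGaD")
        g1 = chain_hetnet.get_node("Gene", "g1")
        d1 = chain_hetnet.get_node("Disease", "d1")
        with pytest.raises(HetnetError, match="does not match"):
            extract_paths(chain_hetnet, mp, g1, d1)

    def test_matches_brute_force_node_sequences(self, small_study):
        net, _ = small_study
        mg = net.metagraph
        compounds = net.nodes_of("Compound")[:4]
        diseases = net.nodes_of("Disease")[:3]
        metapaths = enumerate_metapaths(mg, "Compound", "Disease", 1, 3)
        for mp in metapaths:
            for source in compounds:
                for target in diseases:
                    got = sorted(
                        tuple(n.key for n in p.nodes)
                        for p in extract_paths(net, mp, source, target)
                    )
                    assert got == brute_force_paths(net, mp, source, target)


class TestPathDegreeProduct:
    def test_all_degrees_one(self, chain_hetnet):
        mg = chain_hetnet.metagraph
        mp = mg.metapath_from_abbrev("CbGaD")
        c1 = chain_hetnet.get_node("Compound", "c1")
        d1 = chain_hetnet.get_node("Disease", "d1")
        (path,) = extract_paths(chain_hetnet, mp, c1, d1)
        for w in (0.0, 0.4, 1.0):
            assert path_degree_product(chain_hetnet, path, w) == 1.0

    def test_uniform_degree_two_arithmetic(self, toy_metagraph):
        # two parallel C-G-D chains sharing endpoints: every degree factor
        # along either path is 2, so PDP = (2*2)^-w * (2*2)^-w = 2^(-4w)
        from hetlink import HetNet

        net = HetNet(toy_metagraph)
        c = net.add_node("Compound", "c")
        d = net.add_node("Disease", "d")
        for i in (1, 2):
            g = net.add_node("Gene", f"g{i}")
            net.add_edge("CbG", c, g)
            net.add_edge("DaG", d, g)
        extra_c = net.add_node("Compound", "c2")
        extra_d = net.add_node("Disease", "d2")
        for i in (1, 2):
            net.add_edge("CbG", extra_c, net.get_node("Gene", f"g{i}"))
            net.add_edge("DaG", extra_d, net.get_node("Gene", f"g{i}"))
        mp = toy_metagraph.metapath_from_abbrev("CbGaD")
        paths = extract_paths(net, mp, c, d)
        assert len(paths) == 2
        pdp = path_degree_product(net, paths[0], 0.4)
        assert pdp == pytest.approx(2 ** -1.6, abs=1e-12)

    def test_zero_damping_gives_one(self, small_study):
        net, _ = small_study
        mg = net.metagraph
        mp = mg.metapath_from_abbrev("CbGaD")
        for compound in net.nodes_of("Compound"):
            for disease in net.nodes_of("Disease"):
                for path in extract_paths(net, mp, compound, disease):
                    assert path_degree_product(net, path, 0.0) == 1.0


class TestDwpc:
    def test_no_paths_zero(self, chain_hetnet):
        mg = chain_hetnet.metagraph
        mp = mg.metapath_from_abbrev("CbGaD")
        iso = chain_hetnet.get_node("Compound", "c_isolated")
        d1 = chain_hetnet.get_node("Disease", "d1")
        assert dwpc(chain_hetnet, mp, iso, d1) == 0.0

    def test_matches_brute_force_oracle(self, small_study):
        net, _ = small_study
        mg = net.metagraph
        metapaths = enumerate_metapaths(mg, "Compound", "Disease", 2, 3)
        config = DwpcConfig(damping_exponent=0.4, exclude_query_edge=False)
        for mp in metapaths:
            for compound in net.nodes_of("Compound")[:5]:
                for disease in net.nodes_of("Disease")[:3]:
                    expected = brute_force_dwpc(net, mp, compound, disease, 0.4)
                    got = dwpc(net, mp, compound, disease, config)
                    assert got == pytest.approx(expected, abs=1e-9)

    def test_zero_damping_equals_path_count(self, small_study):
        net, _ = small_study
        mg = net.metagraph
        mp = mg.metapath_from_abbrev("CbGiGaD")
        config = DwpcConfig(damping_exponent=0.0, exclude_query_edge=False)
        compound = net.nodes_of("Compound")[0]
        disease = net.nodes_of("Disease")[0]
        count = len(extract_paths(net, mp, compound, disease))
        assert dwpc(net, mp, compound, disease, config) == pytest.approx(count)

    def test_damping_monotone(self, small_study):
        net, _ = small_study
        mg = net.metagraph
        mp = mg.metapath_from_abbrev("CbGaD")
        compound = max(
            net.nodes_of("Compound"),
            key=lambda c: net.degree(c, mg.get_metaedge("CbG")),
        )
        for disease in net.nodes_of("Disease"):
            values = [
                dwpc(net, mp, compound, disease, DwpcConfig(w, False))
                for w in (0.0, 0.2, 0.4, 0.8)
            ]
            assert values == sorted(values, reverse=True)

    def test_inversion_symmetry(self, small_study):
        net, _ = small_study
        mg = net.metagraph
        config = DwpcConfig(0.4, False)
        for abbrev in ("CbGaD", "CbGiGaD", "CrCbGaD"):
            mp = mg.metapath_from_abbrev(abbrev)
            inv = mp.invert()
            for compound in net.nodes_of("Compound")[:4]:
                for disease in net.nodes_of("Disease")[:3]:
                    assert dwpc(net, mp, compound, disease, config) == pytest.approx(
                        dwpc(net, inv, disease, compound, config), abs=1e-12
                    )

    def test_query_edge_exclusion(self, toy_metagraph):
        # c-t-d direct edge plus c-r-c2-t-d: CrCtD through the *other*
        # treats edge survives exclusion; CtDtCtD-style reuse of the query
        # edge itself is dropped
        from hetlink import HetNet

        net = HetNet(toy_metagraph)
        c = net.add_node("Compound", "c")
        c2 = net.add_node("Compound", "c2")
        d = net.add_node("Disease", "d")
        treats = toy_metagraph.get_metaedge("CtD")
        net.add_edge("CtD", c, d)
        net.add_edge("CtD", c2, d)
        net.add_edge("CrC", c, c2)
        mp = toy_metagraph.metapath_from_abbrev("CrCtD")
        with_exclusion = dwpc(
            net, mp, c, d, DwpcConfig(0.0, True), query_metaedge=treats
        )
        assert with_exclusion == 1.0
        mp_self = toy_metagraph.metapath_from_abbrev("CtDtCtD")
        assert dwpc(
            net, mp_self, c, d, DwpcConfig(0.0, True), query_metaedge=treats
        ) == 0.0


class TestDegreeFeatures:
    def test_hetionet_definition_count_is_14(self, hetionet_mg):
        treats = hetionet_mg.get_metaedge("CtD")
        defs = degree_feature_definitions(
            hetionet_mg, "Compound", "Disease", exclude_metaedge=treats
        )
        assert len(defs) == 14
        assert all(me != treats for _, me in defs)

    def test_isolated_compound_all_zero(self, chain_hetnet):
        mg = chain_hetnet.metagraph
        defs = degree_feature_definitions(
            mg, "Compound", "Disease", mg.get_metaedge("CtD")
        )
        iso = chain_hetnet.get_node("Compound", "c_isolated")
        d1 = chain_hetnet.get_node("Disease", "d1")
        values = degree_features(chain_hetnet, (iso, d1), defs)
        compound_values = [
            v for (endpoint, _), v in zip(defs, values) if endpoint == "source"
        ]
        assert all(v == 0 for v in compound_values)

    def test_matches_edge_list_scan(self, small_study):
        net, _ = small_study
        mg = net.metagraph
        defs = degree_feature_definitions(
            mg, "Compound", "Disease", mg.get_metaedge("CtD")
        )
        compound = net.nodes_of("Compound")[2]
        disease = net.nodes_of("Disease")[2]
        values = degree_features(net, (compound, disease), defs)
        for (endpoint, me), value in zip(defs, values):
            node = compound if endpoint == "source" else disease
            expected = sum(
                1
                for e in net.edges(me)
                if e.source == node or (not e.metaedge.directed and e.target == node)
            )
            assert value == expected
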