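"""Prediction decomposition: metapath, path, and terminal-edge percentages."""

import numpy as np
import pandas as pd
import pytest

from hetlink import (
    explain_prediction,
    metapath_contributions,
    path_contributions,
    terminal_edge_contributions,
)
from hetlink.model import ModelFit


def toy_fit(coefs: dict[str, float], values: dict[str, float]) -> tuple:
    """Identity-standardized model so terms equal coef * value."""
    names = list(coefs)
    fit = ModelFit(
        feature_names=names,
        coefficients=pd.Series(coefs),
        intercept=0.0,
        prior_coefficient=1.0,
        means=pd.Series(0.0, index=names),
        stds=pd.Series(1.0, index=names),
        alpha=0.1,
        l1_ratio=0.2,
    )
    return fit, pd.Series(values)


class TestMetapathContributions:
    def test_single_positive_term_is_100(self):
        fit, row = toy_fit({"dwpc:CbGaD": 0.5}, {"dwpc:CbGaD": 2.0})
        percents, negatives, empty = metapath_contributions(fit, row)
        assert not empty
        assert percents["CbGaD"] == pytest.approx(100.0)

    def test_two_equal_terms_split_evenly(self):
        fit, row = toy_fit(
            {"dwpc:CbGaD": 0.5, "dwpc:CrCtD": 1.0},
            {"dwpc:CbGaD": 2.0, "dwpc:CrCtD": 1.0},
        )
        percents, _, _ = metapath_contributions(fit, row)
        assert percents["CbGaD"] == pytest.approx(50.0)
        assert percents["CrCtD"] == pytest.approx(50.0)

    def test_negative_terms_reported_separately(self):
        fit, row = toy_fit(
            {"dwpc:CbGaD": 0.5, "dwpc:CrCtD": -1.0},
            {"dwpc:CbGaD": 2.0, "dwpc:CrCtD": 1.0},
        )
        percents, negatives, _ = metapath_contributions(fit, row)
        assert list(percents.index) == ["CbGaD"]
        assert negatives["CrCtD"] == pytest.approx(-1.0)

    def test_no_positive_terms_flagged(self):
        fit, row = toy_fit({"dwpc:CbGaD": -0.5}, {"dwpc:CbGaD": 2.0})
        percents, _, empty = metapath_contributions(fit, row)
        assert empty and percents.empty

    def test_zero_dwpc_cannot_support(self):
        # centering can make a zero-DWPC term positive under a negative
        # coefficient; such metapaths have no paths and must not be credited
        fit, row = toy_fit({"dwpc:CbGaD": -0.5}, {"dwpc:CbGaD": 0.0})
        fit.means["dwpc:CbGaD"] = 1.0  # term = -0.5 * (0-1) = +0.5
        percents, _, empty = metapath_contributions(fit, row)
        assert empty

    def test_matches_independent_term_recomputation(self, fitted_study):
        fit = fitted_study["fit"]
        matrix = fitted_study["matrix"]
        row = percents = None
        for _, candidate in matrix.iterrows():
            result, _, empty = metapath_contributions(fit, candidate)
            if not empty:
                row, percents = candidate, result
                break
        assert row is not None, "no row with positive support"
        manual = {}
        for name in fit.feature_names:
            if not name.startswith("dwpc:"):
                continue
            term = fit.coefficients[name] * (
                (row[name] - fit.means[name]) / fit.stds[name]
            )
            if term > 0 and row[name] > 0:
                manual[name.split(":", 1)[1]] = term
        total = sum(manual.values())
        for abbrev, term in manual.items():
            assert percents[abbrev] == pytest.approx(
                100.0 * term / total, abs=1e-9
            )


class TestPathContributions:
    def test_single_path_inherits_full_percent(self, chain_hetnet):
        mg = chain_hetnet.metagraph
        mp = mg.metapath_from_abbrev("CbGaD")
        c1 = chain_hetnet.get_node("Compound", "c1")
        d1 = chain_hetnet.get_node("Disease", "d1")
        frame = path_contributions(chain_hetnet, mp, c1, d1, 40.0)
        assert len(frame) == 1
        assert frame.loc[0, "percent"] == pytest.approx(40.0)

    def test_equal_pdp_paths_split_evenly(self, toy_metagraph):
        from hetlink import HetNet

        net = HetNet(toy_metagraph)
        c = net.add_node("Compound", "c")
        d = net.add_node("Disease", "d")
        for i in (1, 2):
            g = net.add_node("Gene", f"g{i}")
            net.add_edge("CbG", c, g)
            net.add_edge("DaG", d, g)
        mp = toy_metagraph.metapath_from_abbrev("CbGaD")
        frame = path_contributions(net, mp, c, d, 80.0)
        assert np.allclose(frame["percent"], 40.0)

    def test_conservation(self, fitted_study):
        from hetlink import extract_paths

        net = fitted_study["net"]
        mp = fitted_study["metapaths"]["CbGaD"]
        checked = 0
        for compound in net.nodes_of("Compound")[:10]:
            for disease in net.nodes_of("Disease")[:10]:
                if not extract_paths(net, mp, compound, disease):
                    continue
                frame = path_contributions(net, mp, compound, disease, 62.5)
                assert frame["percent"].sum() == pytest.approx(62.5, abs=1e-9)
                checked += 1
        assert checked > 0

    def test_unsupported_pair_with_percent_is_inconsistent(self, chain_hetnet):
        from hetlink import HetnetError

        mg = chain_hetnet.metagraph
        mp = mg.metapath_from_abbrev("CbGaD")
        iso = chain_hetnet.get_node("Compound", "c_isolated")
        d1 = chain_hetnet.get_node("Disease", "d1")
        with pytest.raises(HetnetError, match="no paths"):
            path_contributions(chain_hetnet, mp, iso, d1, 10.0)


class TestTerminalEdges:
    def test_shared_first_edge_aggregates(self):
        paths = pd.DataFrame(
            {
                "metapath": ["CbGaD"] * 2,
                "path": [_fake_path("e1", "e2"), _fake_path("e1", "e3")],
                "pdp": [1.0, 1.0],
                "percent": [30.0, 20.0],
            }
        )
        source, target = terminal_edge_contributions(paths)
        assert source["e1"] == pytest.approx(50.0)
        assert target["e2"] == pytest.approx(30.0)
        assert target["e3"] == pytest.approx(20.0)

    def test_mass_conserved(self):
        paths = pd.DataFrame(
            {
                "metapath": ["CbGaD"] * 3,
                "path": [
                    _fake_path("a", "x"),
                    _fake_path("b", "x"),
                    _fake_path("b", "y"),
                ],
                "pdp": [1.0] * 3,
                "percent": [10.0, 25.0, 15.0],
            }
        )
        source, target = terminal_edge_contributions(paths)
        assert source.sum() == pytest.approx(paths["percent"].sum())
        assert target.sum() == pytest.approx(paths["percent"].sum())


class _FakeEdge:
    def __init__(self, name):
        self.name = name

    def __repr__(self):
        return self.name


class _FakeStep:
    def __init__(self, edge):
        self.edge = edge


class _FakePath:
    def __init__(self, first, last):
        self.steps = (_FakeStep(_FakeEdge(first)), _FakeStep(_FakeEdge(last)))


def _fake_path(first, last):
    return _FakePath(first, last)


class TestExplainPrediction:
    def test_three_level_conservation(self, fitted_study):
        net = fitted_study["net"]
        fit = fitted_study["fit"]
        matrix = fitted_study["matrix"]
        metapaths = fitted_study["metapaths"]
        treats = fitted_study["treats"]
        # pick the highest-scoring positive row with support
        explained = 0
        for _, row in matrix.iterrows():
            report = explain_prediction(
                fit,
                net,
                net.get_node("Compound", row["source"]),
                net.get_node("Disease", row["target"]),
                row,
                metapaths,
                query_metaedge=treats,
            )
            if report.no_positive_support:
                continue
            explained += 1
            assert report.metapath_percents.sum() == pytest.approx(100.0, abs=1e-9)
            for abbrev, percent in report.metapath_percents.items():
                subset = report.paths[report.paths.metapath == abbrev]
                assert subset["percent"].sum() == pytest.approx(percent, abs=1e-9)
            total = report.paths["percent"].sum()
            assert report.source_edge_percents.sum() == pytest.approx(
                total, abs=1e-9
            )
            assert report.target_edge_percents.sum() == pytest.approx(
                total, abs=1e-9
            )
            if explained >= 10:
                break
        assert explained >= 3

    def test_invariant_to_path_order(self, fitted_study):
        from hetlink import extract_paths

        net = fitted_study["net"]
        mp = fitted_study["metapaths"]["CbGaD"]
        pairs = [
            (c, d)
            for c in net.nodes_of("Compound")[:8]
            for d in net.nodes_of("Disease")[:8]
        ]
        for compound, disease in pairs:
            if len(extract_paths(net, mp, compound, disease)) < 2:
                continue
            frame = path_contributions(net, mp, compound, disease, 100.0)
            again = path_contributions(net, mp, compound, disease, 100.0)
            pd.testing.assert_frame_equal(frame, again)
            return
        pytest.skip("no multi-path pair found")
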