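"""Flow-network reading, validation, connectance descriptors and balancing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trophodyn as td


def write_tables(tmp_path, nodes, fluxes):
    npath, fpath = tmp_path / "nodes.csv", tmp_path / "fluxes.csv"
    pd.DataFrame(nodes).to_csv(npath, index=False)
    pd.DataFrame(fluxes).to_csv(fpath, index=False)
    return npath, fpath


CHAIN_NODES = {
    "id": ["prod", "cons1", "cons2", "det"],
    "name": ["prod", "cons1", "cons2", "det"],
    "category": ["producer", "consumer", "consumer", "detritus"],
    "biomass": [10.0, 3.0, 1.0, 5.0],
    "gpp": [2.0, 0, 0, 0],
    "respiration": [0.8, 0.3, 0.4, 0],
    "import": [0, 0, 0, 0],
    "export": [0, 0, 0, 0.5],
}
CHAIN_FLUXES = {
    "source": ["prod", "prod", "cons1", "cons1", "cons2"],
    "target": ["cons1", "det", "cons2", "det", "det"],
    "flux": [1.0, 0.2, 0.5, 0.2, 0.1],
}


class TestReadNetwork:
    def test_roundtrip_chain(self, tmp_path, chain):
        npath, fpath = write_tables(tmp_path, CHAIN_NODES, CHAIN_FLUXES)
        net = td.read_network(npath, fpath)
        assert net.S == 4
        assert net.node_ids == chain.node_ids
        np.testing.assert_allclose(net.F, chain.F)
        np.testing.assert_allclose(net.B, chain.B)
        # and the writer inverts the reader
        td.write_network(net, tmp_path / "n2.csv", tmp_path / "f2.csv")
        again = td.read_network(tmp_path / "n2.csv", tmp_path / "f2.csv")
        np.testing.assert_allclose(again.F, net.F)

    def test_self_loop_rejected(self, tmp_path):
        fluxes = {k: list(v) for k, v in CHAIN_FLUXES.items()}
        fluxes["source"].append("cons1")
        fluxes["target"].append("cons1")
        fluxes["flux"].append(0.1)
        npath, fpath = write_tables(tmp_path, CHAIN_NODES, fluxes)
        with pytest.raises(td.ValidationError, match="self-loop"):
            td.read_network(npath, fpath)

    def test_missing_category_column_is_format_error(self, tmp_path):
        nodes = {k: v for k, v in CHAIN_NODES.items() if k != "category"}
        npath, fpath = write_tables(tmp_path, nodes, CHAIN_FLUXES)
        with pytest.raises(td.FormatError, match="category"):
            td.read_network(npath, fpath)

    def test_unknown_node_in_flux_table(self, tmp_path):
        fluxes = {"source": ["prod", "ghost"], "target": ["cons1", "det"], "flux": [1.0, 0.1]}
        npath, fpath = write_tables(tmp_path, CHAIN_NODES, fluxes)
        with pytest.raises(td.FormatError, match="ghost"):
            td.read_network(npath, fpath)

    @pytest.mark.parametrize("column,value,err", [
        ("biomass", -1.0, "strictly positive"),
        ("gpp", -0.5, "negative"),
    ])
    def test_negative_quantities_rejected(self, tmp_path, column, value, err):
        nodes = {k: list(v) for k, v in CHAIN_NODES.items()}
        nodes[column][1 if column == "biomass" else 0] = value
        npath, fpath = write_tables(tmp_path, nodes, CHAIN_FLUXES)
        with pytest.raises(td.ValidationError, match=err):
            td.read_network(npath, fpath)

    def test_producer_with_inflow_rejected(self, tmp_path):
        fluxes = {"source": ["cons1"], "target": ["prod"], "flux": [0.1]}
        npath, fpath = write_tables(tmp_path, CHAIN_NODES, fluxes)
        with pytest.raises(td.ValidationError, match="producer"):
            td.read_network(npath, fpath)


class TestConnectance:
    def test_two_nodes_single_link(self):
        net = td.make_network(["a", "b"], ["a", "b"], ["producer", "detritus"],
                              [1.0, 1.0], [0.5, 0], [0, 0], [0, 0], [0, 0.5],
                              [[0, 0.5], [0, 0]])
        assert td.binary_connectance(net).C == pytest.approx(0.25)

    def test_complete_digraph(self):
        S = 5
        F = np.ones((S, S)) - np.eye(S)
        rep = td.binary_connectance(_loose_net(F))
        assert rep.L == S * (S - 1)
        assert rep.C == pytest.approx(S * (S - 1) / S**2)

    def test_three_cycle_equal_fluxes_cw_equals_third(self):
        F = np.zeros((3, 3))
        F[0, 1] = F[1, 2] = F[2, 0] = 2.5
        rep = td.weighted_connectance(_loose_net(F))
        assert rep.Cw == pytest.approx(1 / 3, abs=1e-12)
        assert rep.C == pytest.approx(1 / 3)

    def test_regular_equal_flux_web_cw_equals_c(self):
        # complete digraph with equal fluxes is in- and out-regular
        S = 4
        F = (np.ones((S, S)) - np.eye(S)) * 0.7
        rep = td.weighted_connectance(_loose_net(F))
        assert abs(rep.Cw - rep.C) <= 1e-12

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    def test_cw_invariant_to_uniform_rescaling(self, scale):
        F = np.array([[0, 3.0, 1.0], [0, 0, 2.0], [0.5, 0, 0]])
        base = td.weighted_connectance(_loose_net(F)).Cw
        scaled = td.weighted_connectance(_loose_net(F * scale)).Cw
        assert scaled == pytest.approx(base, rel=1e-12)
        # binary connectance never sees magnitudes at all
        assert td.binary_connectance(_loose_net(F * scale)).C == \
            td.binary_connectance(_loose_net(F)).C

    def test_zero_total_flux_is_error(self):
        net = td.make_network(["a", "b"], ["a", "b"], ["producer", "detritus"],
                              [1.0, 1.0], [0.5, 0], [0.5, 0], [0, 0], [0, 0],
                              np.zeros((2, 2)))
        with pytest.raises(td.ValidationError, match="zero"):
            td.weighted_connectance(net)


def _loose_net(F):
    """Wrap a bare flux matrix in a minimal valid network for descriptor tests.

    Node 0 is labelled detritus (satisfying the producer-or-detritus rule
    without banning inflows); the rest are consumers."""
    F = np.asarray(F, dtype=float)
    S = F.shape[0]
    cats = ["detritus"] + ["consumer"] * (S - 1)
    return td.make_network([f"n{i}" for i in range(S)], [f"n{i}" for i in range(S)],
                           cats, np.ones(S), np.zeros(S), np.zeros(S), np.zeros(S),
                           np.zeros(S), F)


class TestBalance:
    def test_balanced_fixture_residuals_tiny(self, chain):
        rep = td.check_balance(chain, tol=1e-12)
        assert rep.passed
        assert max(abs(v) for v in rep.residuals.values()) <= 1e-12

    def test_doubling_one_flux_fails_exactly_two_nodes(self, chain):
        F = chain.F.copy()
        F[chain.index("cons1"), chain.index("cons2")] *= 2
        rep = td.check_balance(chain.with_fluxes(F), tol=1e-9)
        assert not rep.passed
        failing = [n for n, r in rep.residuals.items() if abs(r) > 1e-9]
        assert sorted(failing) == ["cons1", "cons2"]

    def test_no_flux_gpp_equals_r_passes(self):
        net = td.make_network(["p", "d"], ["p", "d"], ["producer", "detritus"],
                              [1.0, 1.0], [0.3, 0], [0.3, 0], [0, 0], [0, 0],
                              np.zeros((2, 2)))
        assert td.check_balance(net).passed

    def test_balanced_web_is_fixed_point_of_avg2(self, chain):
        out = td.balance_avg2(chain, tol=1e-9)
        np.testing.assert_allclose(out.F, chain.F, rtol=1e-9)
        np.testing.assert_allclose(out.B, chain.B)  # stocks untouched

    def test_avg2_closes_perturbed_budget(self, chain):
        F = chain.F.copy()
        F[chain.index("prod"), chain.index("cons1")] *= 1.1  # 10% input surplus
        perturbed = chain.with_fluxes(F)
        assert not td.check_balance(perturbed).passed
        out = td.balance_avg2(perturbed, tol=1e-9)
        assert td.check_balance(out, tol=1e-6).passed
        assert np.all(out.F >= 0)
        assert np.all((out.F > 0) == (F > 0))  # flux signs preserved

    def test_avg2_idempotent(self, chain):
        F = chain.F.copy()
        F[0, 1] *= 1.2
        once = td.balance_avg2(chain.with_fluxes(F), tol=1e-9)
        twice = td.balance_avg2(once, tol=1e-9)
        np.testing.assert_allclose(twice.F, once.F, rtol=1e-7, atol=1e-15)

    def test_avg2_on_generated_perturbation(self, balanced20):
        rng = np.random.default_rng(0)
        F = balanced20.F * rng.uniform(0.9, 1.1, size=balanced20.F.shape)
        out = td.balance_avg2(balanced20.with_fluxes(F), tol=1e-9)
        assert td.check_balance(out, tol=1e-6).passed

    def test_structurally_infeasible_node(self):
        # consumer exports carbon but has no inflow, GPP or import
        net = td.make_network(
            ["p", "c", "d"], ["p", "c", "d"], ["producer", "consumer", "detritus"],
            [1.0, 1.0, 1.0], [0.5, 0, 0], [0.2, 0, 0], [0, 0, 0], [0, 0.3, 0],
            [[0, 0, 0.3], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(td.BalanceError, match="'c'"):
            td.balance_avg2(net)
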