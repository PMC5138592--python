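"""Reachability, essentiality and the four centrality measures."""

import math

import networkx as nx
import pytest

from cpgnet import (
    UsageError,
    betweenness,
    bowtieness,
    closeness,
    critical_in_flow,
    degree,
    essential_nodes,
    group_dispersion,
    reachable_pairs,
)
from cpgnet.paralogs import ParalogGroup

from oracles import essential_oracle, random_flow_dag


def chain():
    return nx.DiGraph([("L", "A"), ("A", "B"), ("B", "T")])


def diamond():
    return nx.DiGraph([("L", "A"), ("A", "T"), ("L", "B"), ("B", "T")])


class TestReachablePairs:
    def test_chain(self):
        assert reachable_pairs(chain(), {"L"}, {"T"}) == {("L", "T")}

    def test_two_ligands(self):
        g = nx.DiGraph([("L1", "A"), ("L2", "A"), ("A", "T")])
        assert reachable_pairs(g, {"L1", "L2"}, {"T"}) == {
            ("L1", "T"),
            ("L2", "T"),
        }

    def test_dual_role_node_never_pairs_with_itself(self):
        g = nx.DiGraph([("X", "A"), ("A", "X")])
        assert reachable_pairs(g, {"X"}, {"X"}) == frozenset()


class TestEssentialNodes:
    def test_unique_path_interiors(self):
        result = essential_nodes(chain(), {"L"}, {"T"})
        assert result.essential == {"A", "B"}
        assert result.broken_pairs["A"] == {("L", "T")}
        assert result.broken_pairs["B"] == {("L", "T")}

    def test_redundant_paths_nothing_essential(self):
        assert essential_nodes(diamond(), {"L"}, {"T"}).essential == frozenset()

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_simple_path_oracle(self, seed):
        g, ligands, tfs = random_flow_dag(seed)
        result = essential_nodes(g, ligands, tfs)
        oracle = essential_oracle(g, ligands, tfs)
        assert {v: set(p) for v, p in result.broken_pairs.items() if p} == oracle

    def test_essential_implies_positive_bowtieness(self):
        for seed in range(20):
            g, ligands, tfs = random_flow_dag(seed)
            ess = essential_nodes(g, ligands, tfs).essential
            bt = bowtieness(g, ligands, tfs)
            assert all(bt[v] > 0 for v in ess)


class TestCriticalInFlow:
    def test_union_over_tissues(self):
        results = [
            essential_nodes(chain(), {"L"}, {"T"}, tissue="heart"),
            essential_nodes(diamond(), {"L"}, {"T"}, tissue="liver"),
        ]
        assert critical_in_flow(results) == {"A", "B"}

    def test_empty_results_rejected(self):
        with pytest.raises(UsageError):
            critical_in_flow([])


class TestDegree:
    def test_chain_interior(self):
        assert degree(chain(), "A") == 2

    def test_reciprocal_edges_count_once(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        assert degree(g, "A") == 1

    def test_isolated(self):
        g = nx.DiGraph()
        g.add_node("X")
        assert degree(g, "X") == 0
        with pytest.raises(KeyError):
            degree(g, "missing")


class TestBetweenness:
    def test_chain_interior_values(self):
        assert betweenness(chain()) == {"L": 0.0, "A": 2.0, "B": 2.0, "T": 0.0}

    def test_outward_star_hub_zero(self):
        g = nx.DiGraph([("H", "A"), ("H", "B"), ("H", "C")])
        assert betweenness(g)["H"] == 0.0


class TestCloseness:
    def test_chain_end(self):
        assert closeness(chain(), "L") == pytest.approx(0.5)

    def test_complete_graph(self):
        g = nx.complete_graph(4, create_using=nx.DiGraph)
        assert all(closeness(g, v) == pytest.approx(1.0) for v in g)

    def test_disconnected_uses_own_component(self):
        g = nx.DiGraph([("A", "B")])
        g.add_nodes_from(["C", "D"])
        g.add_edge("C", "D")
        assert closeness(g, "A") == pytest.approx(1.0)

    def test_isolated_node_zero(self):
        g = nx.DiGraph()
        g.add_node("X")
        assert closeness(g, "X") == 0.0


class TestBowtieness:
    def test_unique_path(self):
        bt = bowtieness(chain(), {"L"}, {"T"})
        assert bt["A"] == bt["B"] == 1.0
        assert bt["L"] == bt["T"] == 0.0

    def test_two_equal_routes(self):
        bt = bowtieness(diamond(), {"L"}, {"T"})
        assert bt["A"] == bt["B"] == pytest.approx(0.5)

    def test_no_reachable_pair_all_zero(self):
        g = nx.DiGraph([("T", "L")])  # flow only against the roles
        assert set(bowtieness(g, {"L"}, {"T"}).values()) == {0.0}

    def test_unique_path_values_binary(self):
        # in graphs where every reachable pair has a unique shortest path and
        # only one pair exists, pooled bowtieness is 0 or 1
        bt = bowtieness(chain(), {"L"}, {"T"})
        assert set(bt.values()) <= {0.0, 1.0}


class TestPermutationEquivariance:
    def test_relabeling_commutes(self):
        g, ligands, tfs = random_flow_dag(3)
        mapping = {v: f"node_{i}" for i, v in enumerate(sorted(g))}
        h = nx.relabel_nodes(g, mapping)
        bt_g = bowtieness(g, ligands, tfs)
        bt_h = bowtieness(
            h, {mapping[l] for l in ligands}, {mapping[t] for t in tfs}
        )
        for v in g:
            assert bt_h[mapping[v]] == pytest.approx(bt_g[v], abs=1e-12)
        ess_g = essential_nodes(g, ligands, tfs).essential
        ess_h = essential_nodes(
            h, {mapping[l] for l in ligands}, {mapping[t] for t in tfs}
        ).essential
        assert ess_h == {mapping[v] for v in ess_g}


class TestGroupDispersion:
    def group(self, gid, members):
        return ParalogGroup(group_id=gid, members=frozenset(members), source="MERGED")

    def test_constant_values_zero_sd(self):
        sds = group_dispersion(
            [self.group("G", {"a", "b", "c"})], {"a": 1.0, "b": 1.0, "c": 1.0}
        )
        assert sds["G"] == 0.0

    def test_two_values_closed_form(self):
        sds = group_dispersion([self.group("G", {"a", "b"})], {"a": 0.0, "b": 2.0})
        assert sds["G"] == pytest.approx(math.sqrt(2))

    def test_single_present_member_omitted(self):
        sds = group_dispersion([self.group("G", {"a", "b"})], {"a": 1.0})
        assert "G" not in sds
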