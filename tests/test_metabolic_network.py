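"""Reaction-graph construction, compartment classification, centrality and
SBML round-tripping."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from metaboconstraint import metabolic_network as net
from metaboconstraint import synthetic_data as synth
from metaboconstraint.errors import FormatError
from metaboconstraint.metabolic_network import (
    CompartmentLabel,
    Metabolite,
    Reaction,
    Reconstruction,
)


def recon_of(reactions, compartments):
    mets = {}
    for rxn in reactions:
        for mid in rxn.metabolites:
            name, _, code = mid.rpartition("_")
            mets[mid] = Metabolite(mid, name, code)
    return Reconstruction(mets, {r.id: r for r in reactions})


class TestClassifyCompartment:
    def test_single_compartment_label(self, tiny_recon):
        assert (
            net.classify_compartment(
                tiny_recon.reactions["R3"], tiny_recon.metabolites
            )
            == CompartmentLabel.MITOCHONDRIA
        )

    def test_cross_compartment_is_transport(self, tiny_recon):
        assert (
            net.classify_compartment(
                tiny_recon.reactions["T1"], tiny_recon.metabolites
            )
            == CompartmentLabel.TRANSPORT
        )

    def test_external_label(self):
        r = Reaction("R", ["a_e"], ["b_e"])
        recon = recon_of([r], "e")
        assert (
            net.classify_compartment(r, recon.metabolites)
            == CompartmentLabel.EXTERNAL
        )

    def test_unresolvable_metabolite_raises(self, tiny_recon):
        bad = Reaction("B", ["ghost_c"], [])
        with pytest.raises(FormatError, match="ghost_c"):
            net.classify_compartment(bad, tiny_recon.metabolites)


class TestBuildReactionGraph:
    def test_two_irreversible_producers_share_no_edge(self):
        r1 = Reaction("R1", ["x_c"], ["m_c"], reversible=False)
        r2 = Reaction("R2", ["y_c"], ["m_c"], reversible=False)
        g = net.build_reaction_graph(recon_of([r1, r2], "c"))
        assert g.number_of_edges() == 0

    def test_producer_consumer_edge_allowed(self):
        r1 = Reaction("R1", ["x_c"], ["m_c"], reversible=False)
        r2 = Reaction("R2", ["m_c"], ["y_c"], reversible=False)
        g = net.build_reaction_graph(recon_of([r1, r2], "c"))
        assert g.has_edge("R1", "R2")
        assert g["R1"]["R2"]["metabolites"] == {"m_c"}

    def test_reversibility_lifts_the_side_rule(self):
        r1 = Reaction("R1", ["x_c"], ["m_c"], reversible=True)
        r2 = Reaction("R2", ["y_c"], ["m_c"], reversible=False)
        g = net.build_reaction_graph(recon_of([r1, r2], "c"))
        assert g.has_edge("R1", "R2")

    def test_same_name_different_compartment_never_joins(self):
        r1 = Reaction("R1", ["a_c"], ["m_c"], reversible=True)
        r2 = Reaction("R2", ["m_m"], ["b_m"], reversible=True)
        g = net.build_reaction_graph(recon_of([r1, r2], "cm"))
        assert g.number_of_edges() == 0

    def test_metabolite_on_both_sides_makes_no_self_edge(self):
        r = Reaction("R1", ["m_c"], ["m_c", "x_c"], reversible=False)
        g = net.build_reaction_graph(recon_of([r], "c"))
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 1

    def test_exclusion_is_monotone_in_edges(self):
        recon, _ = synth.gen_reconstruction(seed=1)
        base = net.build_reaction_graph(recon).number_of_edges()
        for mid in list(recon.metabolites)[::7]:
            fewer = net.build_reaction_graph(
                recon, excluded_metabolites=[mid]
            ).number_of_edges()
            assert fewer <= base

    def test_reaction_order_does_not_change_graph(self):
        recon, _ = synth.gen_reconstruction(seed=2)
        reordered = Reconstruction(
            recon.metabolites,
            dict(sorted(recon.reactions.items(), reverse=True)),
        )
        g1 = net.build_reaction_graph(recon)
        g2 = net.build_reaction_graph(reordered)
        assert set(g1.edges) == set(g2.edges)

    def test_isolated_reactions_stay_as_nodes(self, tiny_recon):
        g = net.build_reaction_graph(tiny_recon)
        assert set(g.nodes) == set(tiny_recon.reactions)


class TestCentrality:
    def test_degree_examples(self):
        triangle = nx.cycle_graph(3)
        assert set(net.degree(triangle).values()) == {2}
        star = nx.star_graph(4)
        deg = net.degree(star)
        assert deg[0] == 4 and all(deg[k] == 1 for k in range(1, 5))
        empty = nx.empty_graph(3)
        assert set(net.degree(empty).values()) == {0}

    @pytest.mark.parametrize(
        "graph,expected",
        [
            (nx.path_graph(3), {0: 0.0, 1: 1.0, 2: 0.0}),
            (nx.complete_graph(4), {k: 0.0 for k in range(4)}),
            (nx.star_graph(4), {0: 6.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}),
        ],
    )
    def test_betweenness_closed_forms(self, graph, expected):
        assert net.betweenness(graph) == pytest.approx(expected)

    def test_betweenness_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            ours = net.betweenness(g)
            oracle = brute_force_betweenness(g)
            for node in g.nodes:
                assert ours[node] == pytest.approx(oracle[node], abs=1e-9)

    def test_compartment_subgraph(self, tiny_recon):
        g = net.build_reaction_graph(tiny_recon)
        sub = net.compartment_subgraph(g, tiny_recon, CompartmentLabel.CYTOPLASM)
        assert set(sub.nodes) == {"R1", "R2"}
        empty = net.compartment_subgraph(g, tiny_recon, CompartmentLabel.GOLGI)
        assert empty.number_of_nodes() == 0


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Independent oracle: enumerate every shortest path for every pair."""
    btw = {v: 0.0 for v in g.nodes}
    for s, t in combinations(g.nodes, 2):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            continue
        paths = []
        stack = [(t, (t,))]
        while stack:
            v, path = stack.pop()
            if v == s:
                paths.append(path)
                continue
            for u in g[v]:
                if dist.get(u, -1) == dist[v] - 1:
                    stack.append((u, path + (u,)))
        for path in paths:
            for v in path[1:-1]:
                btw[v] += 1.0 / len(paths)
    return btw


class TestMergeCompartments:
    def test_instances_merge_by_name(self, tiny_recon):
        merged = net.merge_compartments(tiny_recon)
        assert "a" in merged.metabolites
        assert merged.reactions["T1"].substrates == ["a"]
        assert merged.reactions["T1"].products == ["a"]

    def test_genes_and_reversibility_preserved(self, tiny_recon):
        merged = net.merge_compartments(tiny_recon)
        for rid, rxn in tiny_recon.reactions.items():
            assert merged.reactions[rid].genes == rxn.genes
            assert merged.reactions[rid].reversible == rxn.reversible


class TestSBML:
    def test_round_trip_preserves_everything(self, tmp_path):
        recon, _ = synth.gen_reconstruction(seed=3)
        path = tmp_path / "recon.xml"
        net.write_sbml(recon, path)
        back = net.parse_reconstruction(path)
        assert set(back.metabolites) == set(recon.metabolites)
        assert set(back.reactions) == set(recon.reactions)
        for rid, rxn in recon.reactions.items():
            assert back.reactions[rid].reversible == rxn.reversible
            assert back.reactions[rid].genes == rxn.genes
            assert sorted(back.reactions[rid].substrates) == sorted(rxn.substrates)
            assert sorted(back.reactions[rid].products) == sorted(rxn.products)

    def test_compartments_survive_round_trip(self, tmp_path, tiny_recon):
        path = tmp_path / "tiny.xml"
        net.write_sbml(tiny_recon, path)
        back = net.parse_reconstruction(path)
        assert back.metabolites["a_m"].compartment == "m"

    def test_missing_gene_annotations_warn_not_fail(self, tmp_path, caplog):
        mets = {"a_c": Metabolite("a_c", "a", "c"), "b_c": Metabolite("b_c", "b", "c")}
        rxns = {"R1": Reaction("R1", ["a_c"], ["b_c"])}
        path = tmp_path / "nogenes.xml"
        net.write_sbml(Reconstruction(mets, rxns), path)
        with caplog.at_level("WARNING"):
            back = net.parse_reconstruction(path)
        assert back.reactions["R1"].genes == set()
        assert any("gene association" in m for m in caplog.messages)

    def test_unparseable_document_raises(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<notsbml/>")
        with pytest.raises(FormatError):
            net.parse_reconstruction(bad)
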