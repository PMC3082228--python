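"""Shared fixtures: tiny graphs, reconstructions and gene tables."""

from __future__ import annotations

import networkx as nx
import pytest

from metaboconstraint.metabolic_network import (
    Metabolite,
    Reaction,
    Reconstruction,
)
from metaboconstraint.orthology import Gene, HomologyHit


@pytest.fixture
def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g


@pytest.fixture
def bridged_triangles(two_triangles) -> nx.Graph:
    g = two_triangles.copy()
    g.add_edge(2, 3)
    return g


@pytest.fixture
def tiny_recon() -> Reconstruction:
    """Two cytosolic reactions sharing a metabolite, one mitochondrial,
    one transport reaction."""
    mets = {
        "a_c": Metabolite("a_c", "a", "c"),
        "b_c": Metabolite("b_c", "b", "c"),
        "c_c": Metabolite("c_c", "c", "c"),
        "a_m": Metabolite("a_m", "a", "m"),
        "d_m": Metabolite("d_m", "d", "m"),
    }
    rxns = {
        "R1": Reaction("R1", ["a_c"], ["b_c"], reversible=False, genes={"g1"}),
        "R2": Reaction("R2", ["b_c"], ["c_c"], reversible=False, genes={"g2", "g3"}),
        "R3": Reaction("R3", ["a_m"], ["d_m"], reversible=True, genes=set()),
        "T1": Reaction("T1", ["a_c"], ["a_m"], reversible=False, genes={"g4"}),
    }
    return Reconstruction(mets, rxns)


def make_gene(gid: str, genome: str, pos: int, chrom: str = "1") -> Gene:
    return Gene(gid, genome, chrom, pos)


def make_hit(g1: str, g2: str, e: float = 1e-30, pid: float = 0.8, ks=0.3):
    return HomologyHit(g1, g2, e, pid, ks)


@pytest.fixture
def fig_s2_toy():
    """Hand-traceable synteny toy: one seeded anchor pair, a neighbor pair
    resolvable only by propagation, and a pair exposed by edge deletion."""
    genes = [
        make_gene("a1", "G1", 0),
        make_gene("c1", "G1", 1),
        make_gene("e1", "G1", 2),
        make_gene("b1", "G2", 0),
        make_gene("d1", "G2", 1),
        make_gene("d2", "G2", 2),
    ]
    hits = [
        make_hit("a1", "b1"),
        make_hit("c1", "d1"),
        make_hit("c1", "d2"),
        make_hit("d2", "e1"),
    ]
    return genes, hits
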