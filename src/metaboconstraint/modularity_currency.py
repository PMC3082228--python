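"""Newman modularity, effective modularity against rewired nulls, and the
iterative currency-metabolite removal scan.

Currency metabolites (H+, ATP, water, ...) spuriously link unrelated
reactions.  Rather than a fixed list, they are identified structurally:
metabolites are removed in descending order of the number of graph edges
they support, and after each removal the effective modularity
dQ = Q(graph) - mean Q(rewired copies) is recomputed; the removal count
maximizing dQ defines the currency set.  Community structure is found with
greedy (CNM-style) agglomeration; the null model is degree-preserving
double-edge swapping.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .metabolic_network import (
    CompartmentLabel,
    Reconstruction,
    build_reaction_graph,
    classify_compartment,
    merge_compartments,
)

logger = logging.getLogger(__name__)

Partition = dict  # node -> community index


@dataclass
class TrajectoryStep:
    removed_metabolite: str | None  # None at step 0 (nothing removed yet)
    q: float
    mean_q_random: float

    @property
    def delta_q(self) -> float:
        return self.q - self.mean_q_random


@dataclass
class ModularityTrajectory:
    """dQ as a function of the number of removed metabolites."""

    steps: list[TrajectoryStep] = field(default_factory=list)

    @property
    def argmax_step(self) -> int:
        """Removal count maximizing dQ (earliest on ties)."""
        deltas = [s.delta_q for s in self.steps]
        return int(np.argmax(deltas))

    @property
    def removed_set(self) -> set[str]:
        """Metabolites removed up to and including the dQ-maximizing step."""
        k = self.argmax_step
        return {s.removed_metabolite for s in self.steps[1 : k + 1]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (i, s.removed_metabolite or "", s.q, s.mean_q_random, s.delta_q)
                for i, s in enumerate(self.steps)
            ],
            columns=["step", "metabolite", "q", "mean_q_random", "delta_q"],
        )


def modularity_q(graph: nx.Graph, partition: Partition) -> float:
    """Newman modularity Q = sum_i (e_ii/m - a_i^2) of a node partition."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if set(partition) != set(graph.nodes):
        raise ValueError("partition must cover exactly the graph's nodes")
    if graph.number_of_edges() == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    communities: dict[int, set] = {}
    for node, com in partition.items():
        communities.setdefault(com, set()).add(node)
    return nx.community.modularity(graph, communities.values())


def greedy_communities(graph: nx.Graph) -> tuple[Partition, float]:
    """Greedy agglomerative (CNM fast-greedy) community detection.

    Uses igraph's C implementation of the Clauset–Newman–Moore algorithm;
    when no subdivision beats the trivial single community (Q = 0, e.g. a
    complete graph) that trivial partition is returned.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("need at least one edge")
    import igraph as ig

    nodes = list(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges]
    )
    membership = g.community_fastgreedy().as_clustering().membership
    q = float(g.modularity(membership))
    if q < 0.0:
        return {node: 0 for node in nodes}, 0.0
    return {node: membership[index[node]] for node in nodes}, q


def rewire(graph: nx.Graph, n_swaps: int | None = None, seed: int = 0) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``n_swaps`` swaps (default 10x the edge count), each replacing
    edges (u,v),(x,y) by (u,x),(v,y); proposals that would create a
    self-loop or a parallel edge are skipped, so the result stays a simple
    graph with exactly the input's node set, edge count and degree sequence.
    Graphs too small to admit any swap are returned unchanged with a warning.
    """
    edges = [tuple(e) for e in graph.edges]
    m = len(edges)
    if n_swaps is None:
        n_swaps = 10 * m
    if m < 2 or graph.number_of_nodes() < 4 or n_swaps == 0:
        logger.warning("graph too small to rewire; returned unchanged")
        out = nx.Graph()
        out.add_nodes_from(graph.nodes)
        out.add_edges_from(edges)
        return out

    adjacency = {node: set(graph.neighbors(node)) for node in graph.nodes}
    rng = np.random.default_rng(seed)
    first = rng.integers(m, size=n_swaps)
    second = rng.integers(m, size=n_swaps)
    flip = rng.random(n_swaps) < 0.5
    for k in range(n_swaps):
        i, j = int(first[k]), int(second[k])
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if flip[k]:
            x, y = y, x
        if u == x or v == y:
            continue  # would create a self-loop
        if x in adjacency[u] or y in adjacency[v]:
            continue  # would create a parallel edge
        adjacency[u].remove(v)
        adjacency[v].remove(u)
        adjacency[x].remove(y)
        adjacency[y].remove(x)
        adjacency[u].add(x)
        adjacency[x].add(u)
        adjacency[v].add(y)
        adjacency[y].add(v)
        edges[i] = (u, x)
        edges[j] = (v, y)
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from(edges)
    return out


def effective_modularity(
    graph: nx.Graph, n_random: int = 1000, seed: int = 0
) -> tuple[float, float, float]:
    """Q of the graph, mean Q of ``n_random`` rewired copies, and their
    difference dQ (effective modularity)."""
    _, q = greedy_communities(graph)
    rng = np.random.default_rng(seed)
    q_random = []
    for _ in range(n_random):
        rewired = rewire(graph, seed=int(rng.integers(2**31)))
        _, qr = greedy_communities(rewired)
        q_random.append(qr)
    mean_q = float(np.mean(q_random))
    return q, mean_q, q - mean_q


def metabolite_edge_frequency(graph: nx.Graph) -> Counter:
    """Number of edges each metabolite supports in the current graph."""
    freq: Counter = Counter()
    for _, _, data in graph.edges(data=True):
        for mid in data["metabolites"]:
            freq[mid] += 1
    return freq


def currency_scan(
    recon: Reconstruction,
    variant: str = "compartmentalized",
    max_removals: int = 50,
    n_random: int = 1000,
    seed: int = 0,
    early_stop: int | None = None,
) -> ModularityTrajectory | dict[CompartmentLabel, ModularityTrajectory]:
    """Iterative removal of the most edge-frequent metabolite, tracking dQ.

    Variants: ``compartmentalized`` scans the full network with
    compartment-specific metabolite instances; ``noncompartmentalized``
    first merges instances across compartments (ATP in the cytoplasm equals
    ATP in the mitochondria); ``per-compartment`` scans each non-transport
    compartment's sub-reconstruction separately and returns a dict of
    trajectories.  Frequencies are re-ranked after every removal.  With
    ``early_stop`` = k the scan stops after k consecutive dQ decreases;
    by default the full trajectory up to ``max_removals`` is recorded and
    the argmax taken afterwards.
    """
    if variant == "noncompartmentalized":
        recon = merge_compartments(recon)
    elif variant == "per-compartment":
        result: dict[CompartmentLabel, ModularityTrajectory] = {}
        for label in CompartmentLabel:
            if label is CompartmentLabel.TRANSPORT:
                continue
            rids = [
                rid
                for rid, rxn in recon.reactions.items()
                if classify_compartment(rxn, recon.metabolites) == label
            ]
            if not rids:
                continue
            sub = Reconstruction(
                recon.metabolites, {rid: recon.reactions[rid] for rid in rids}
            )
            result[label] = currency_scan(
                sub, "compartmentalized", max_removals, n_random, seed, early_stop
            )
        return result
    elif variant != "compartmentalized":
        raise ValueError(f"unknown variant {variant!r}")

    rng = np.random.default_rng(seed)
    trajectory = ModularityTrajectory()
    removed: list[str] = []
    decreases = 0
    last_dq: float | None = None
    max_removals = min(max_removals, len(recon.metabolites))

    for step in range(max_removals + 1):
        graph = build_reaction_graph(recon, excluded_metabolites=removed)
        if graph.number_of_edges() == 0:
            break
        q, mean_q, dq = effective_modularity(
            graph, n_random=n_random, seed=int(rng.integers(2**31))
        )
        trajectory.steps.append(
            TrajectoryStep(removed[-1] if step else None, q, mean_q)
        )
        if last_dq is not None:
            decreases = decreases + 1 if dq < last_dq else 0
        last_dq = dq
        if early_stop is not None and decreases >= early_stop:
            break
        if step < max_removals:
            freq = metabolite_edge_frequency(graph)
            if not freq:
                break
            # most frequent; lexicographic tie-break for determinism
            target = max(sorted(freq), key=lambda mid: freq[mid])
            removed.append(target)
    return trajectory
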