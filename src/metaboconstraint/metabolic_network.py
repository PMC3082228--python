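"""Compartmentalized reaction-node graphs from metabolic reconstructions.

Reactions are nodes; two reactions are joined by an edge when they share a
compartment-specific metabolite, unless both reactions are irreversible and
the shared metabolite sits on the same side (substrate in both or product
in both) of each.  Because metabolite instances are compartment-specific,
edges never connect reactions in different compartments except through
transport reactions, which span two compartments and form their own
category.  The final graph is simple and undirected; directionality only
filters which shared metabolites support an edge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)


class CompartmentLabel(str, Enum):
    NUCLEUS = "nucleus"
    ENDOPLASMIC_RETICULUM = "endoplasmic_reticulum"
    EXTERNAL = "external"
    GOLGI = "golgi"
    CYTOPLASM = "cytoplasm"
    MITOCHONDRIA = "mitochondria"
    LYSOSOME = "lysosome"
    PEROXISOME = "peroxisome"
    TRANSPORT = "transport"


#: Compartment code -> label, mirroring common reconstruction dialects
#: (cytosol "c", mitochondria "m", nucleus "n", ER "r", Golgi "g",
#: extracellular "e", lysosome "l", peroxisome "x").
COMPARTMENT_CODES: dict[str, CompartmentLabel] = {
    "c": CompartmentLabel.CYTOPLASM,
    "m": CompartmentLabel.MITOCHONDRIA,
    "n": CompartmentLabel.NUCLEUS,
    "r": CompartmentLabel.ENDOPLASMIC_RETICULUM,
    "g": CompartmentLabel.GOLGI,
    "e": CompartmentLabel.EXTERNAL,
    "l": CompartmentLabel.LYSOSOME,
    "x": CompartmentLabel.PEROXISOME,
}


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str


@dataclass
class Reaction:
    id: str
    substrates: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    reversible: bool = False
    genes: set[str] = field(default_factory=set)

    @property
    def metabolites(self) -> set[str]:
        return set(self.substrates) | set(self.products)


@dataclass
class Reconstruction:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]

    @property
    def genes(self) -> set[str]:
        return set().union(*(r.genes for r in self.reactions.values())) if self.reactions else set()


def classify_compartment(
    reaction: Reaction, metabolites: Mapping[str, Metabolite]
) -> CompartmentLabel:
    """Single shared compartment of all species, or TRANSPORT if they differ."""
    compartments = set()
    for mid in reaction.metabolites:
        if mid not in metabolites:
            raise FormatError(f"unresolvable metabolite {mid} in {reaction.id}")
        compartments.add(metabolites[mid].compartment)
    if not compartments:
        raise FormatError(f"reaction {reaction.id} has no metabolites")
    if len(compartments) > 1:
        return CompartmentLabel.TRANSPORT
    code = compartments.pop()
    try:
        return COMPARTMENT_CODES[code]
    except KeyError:
        raise FormatError(f"unknown compartment code {code!r}") from None


def build_reaction_graph(
    recon: Reconstruction, excluded_metabolites: Iterable[str] = ()
) -> nx.Graph:
    """Reaction-node graph under the shared-metabolite / direction rule.

    Every reaction is a node (isolated ones included).  For each shared,
    non-excluded metabolite an edge is added unless both reactions are
    irreversible and the metabolite is a substrate in both or a product in
    both.  Parallel support collapses to one edge whose ``metabolites``
    attribute records the supporting metabolite ids; self-edges never arise.
    """
    excluded = set(excluded_metabolites)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(recon.reactions))

    users: dict[str, list[str]] = {}
    for rid in sorted(recon.reactions):
        for mid in recon.reactions[rid].metabolites:
            if mid not in excluded:
                users.setdefault(mid, []).append(rid)

    for mid, rids in sorted(users.items()):
        for i, r1 in enumerate(rids):
            rx1 = recon.reactions[r1]
            for r2 in rids[i + 1 :]:
                rx2 = recon.reactions[r2]
                if not rx1.reversible and not rx2.reversible:
                    same_side = (
                        mid in rx1.substrates and mid in rx2.substrates
                    ) or (mid in rx1.products and mid in rx2.products)
                    if same_side:
                        continue
                if graph.has_edge(r1, r2):
                    graph[r1][r2]["metabolites"].add(mid)
                else:
                    graph.add_edge(r1, r2, metabolites={mid})
    return graph


def degree(graph: nx.Graph) -> dict[str, int]:
    return dict(graph.degree())


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Brandes betweenness: per node, the summed fraction of shortest paths
    through it over all unordered endpoint pairs (unnormalized)."""
    return nx.betweenness_centrality(graph, normalized=False)


def compartment_subgraph(
    graph: nx.Graph, recon: Reconstruction, label: CompartmentLabel
) -> nx.Graph:
    """Induced subgraph on reactions classified to ``label``."""
    nodes = [
        rid
        for rid in graph.nodes
        if classify_compartment(recon.reactions[rid], recon.metabolites) == label
    ]
    return graph.subgraph(nodes).copy()


def merge_compartments(recon: Reconstruction) -> Reconstruction:
    """Drop compartment designations: instances of a metabolite merge by name.

    The merged reconstruction places every metabolite in a single pseudo
    compartment ``u``; reaction gene sets and reversibility are preserved.
    Used for the noncompartmentalized network variant.
    """
    metabolites = {}
    remap: dict[str, str] = {}
    for met in recon.metabolites.values():
        remap[met.id] = met.name
        metabolites.setdefault(met.name, Metabolite(met.name, met.name, "u"))
    reactions = {}
    for rxn in recon.reactions.values():
        reactions[rxn.id] = Reaction(
            rxn.id,
            substrates=sorted({remap[m] for m in rxn.substrates}),
            products=sorted({remap[m] for m in rxn.products}),
            reversible=rxn.reversible,
            genes=set(rxn.genes),
        )
    return Reconstruction(metabolites, reactions)


# --- SBML input/output -------------------------------------------------------

_GENE_ASSOC_RE = re.compile(r"GENE[ _]?ASSOCIATION:?\s*([^<\n]*)", re.IGNORECASE)
_GENE_TOKEN_RE = re.compile(r"[()]|\band\b|\bor\b", re.IGNORECASE)


def _parse_gene_association(notes: str) -> set[str]:
    match = _GENE_ASSOC_RE.search(notes)
    if not match:
        return set()
    tokens = _GENE_TOKEN_RE.sub(" ", match.group(1)).split()
    return {t for t in tokens if t}


def parse_reconstruction(source: str | Path) -> Reconstruction:
    """Read a compartmentalized reconstruction from an SBML file.

    Boundary species are ignored; species missing a compartment raise an
    error listing their ids; gene associations are read from the
    ``GENE_ASSOCIATION`` field of reaction notes (a warning is logged when no
    reaction carries one).
    """
    import libsbml

    doc = libsbml.readSBMLFromString(Path(source).read_text())
    if doc.getModel() is None:
        raise FormatError(f"not a parseable SBML document: {source}")
    model = doc.getModel()

    metabolites: dict[str, Metabolite] = {}
    missing: list[str] = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        comp = sp.getCompartment()
        if not comp:
            missing.append(sp.getId())
            continue
        metabolites[sp.getId()] = Metabolite(
            sp.getId(), sp.getName() or sp.getId(), comp
        )
    if missing:
        raise FormatError(f"species without compartment: {missing}")

    reactions: dict[str, Reaction] = {}
    any_genes = False
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        subs = [
            rx.getReactant(j).getSpecies()
            for j in range(rx.getNumReactants())
            if rx.getReactant(j).getSpecies() in metabolites
        ]
        prods = [
            rx.getProduct(j).getSpecies()
            for j in range(rx.getNumProducts())
            if rx.getProduct(j).getSpecies() in metabolites
        ]
        genes: set[str] = set()
        if rx.isSetNotes():
            genes = _parse_gene_association(rx.getNotesString())
        any_genes = any_genes or bool(genes)
        reactions[rx.getId()] = Reaction(
            rx.getId(), subs, prods, rx.getReversible(), genes
        )
    if reactions and not any_genes:
        logger.warning("no gene associations found in %s", source)
    return Reconstruction(metabolites, reactions)


def write_sbml(recon: Reconstruction, path: str | Path) -> None:
    """Write a Level 2 Version 4 SBML document for a reconstruction."""
    import libsbml

    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel("reconstruction")
    compartments = sorted({m.compartment for m in recon.metabolites.values()})
    for comp in compartments:
        c = model.createCompartment()
        c.setId(comp)
        c.setSize(1.0)
    for mid in sorted(recon.metabolites):
        met = recon.metabolites[mid]
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setInitialConcentration(1.0)
    for rid in sorted(recon.reactions):
        rxn = recon.reactions[rid]
        rx = model.createReaction()
        rx.setId(rxn.id)
        rx.setReversible(rxn.reversible)
        for mid in rxn.substrates:
            ref = rx.createReactant()
            ref.setSpecies(mid)
        for mid in rxn.products:
            ref = rx.createProduct()
            ref.setSpecies(mid)
        if rxn.genes:
            assoc = " or ".join(sorted(rxn.genes))
            rx.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>GENE_ASSOCIATION: {assoc}</p></body>"
            )
    libsbml.writeSBMLToFile(doc, str(path))


# --- tabular exports ---------------------------------------------------------

def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        (r1, r2, ";".join(sorted(data["metabolites"])))
        for r1, r2, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["reaction1", "reaction2", "supporting_metabolites"]).to_csv(
        path, sep="\t", index=False
    )


def node_table(graph: nx.Graph, recon: Reconstruction) -> pd.DataFrame:
    deg = degree(graph)
    btw = betweenness(graph)
    rows = [
        (
            rid,
            classify_compartment(recon.reactions[rid], recon.metabolites).value,
            deg[rid],
            btw[rid],
            ";".join(sorted(recon.reactions[rid].genes)),
        )
        for rid in sorted(graph.nodes)
    ]
    return pd.DataFrame(
        rows, columns=["reaction", "compartment", "degree", "betweenness", "genes"]
    )
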