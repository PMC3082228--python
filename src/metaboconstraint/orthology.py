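"""Synteny-propagating ortholog identification from pairwise homology hits.

Given gene-order tables for two genomes and a table of filtered homology
hits, the algorithm (i) collapses tandem duplicates — maximal runs of
immediately adjacent homologous genes — into single loci, (ii) seeds
ortholog pairs from unique reciprocal hits subject to a synonymous-distance
ceiling, and (iii) iteratively propagates orthology along chromosomes:
whenever the immediate neighbors of an accepted pair are themselves
homologous they are declared orthologs and their remaining homology edges
deleted, after which one-to-one seeding (now without the Ks criterion) is
repeated, until convergence.  Anchor-centric multi-genome ortholog sets are
assembled by joining the pairwise results on the anchor gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Filter thresholds used for the close primate comparisons (chimpanzee,
#: macaque vs human): E <= 1e-10, identity >= 50%, Ks < 0.5.
PRIMATE_THRESHOLDS = {"e_max": 1e-10, "pid_min": 0.50, "ks_max": 0.5}
#: Thresholds for all other genome comparisons: E <= 1e-9, identity >= 45%,
#: Ks < 0.75.
DEFAULT_THRESHOLDS = {"e_max": 1e-9, "pid_min": 0.45, "ks_max": 0.75}


@dataclass(frozen=True)
class Gene:
    """A gene with its genomic coordinates (ordinal position on a chromosome)."""

    id: str
    genome: str
    chromosome: str
    position: int
    cds: str | None = None


@dataclass(frozen=True)
class HomologyHit:
    """An undirected scored homology relationship between two genes."""

    gene1: str
    gene2: str
    e_value: float
    pid: float
    ks: float | None = None

    def __post_init__(self) -> None:
        if self.gene1 > self.gene2:  # canonical storage
            g1, g2 = self.gene1, self.gene2
            object.__setattr__(self, "gene1", g2)
            object.__setattr__(self, "gene2", g1)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)


@dataclass(frozen=True)
class OrthologPair:
    """An accepted ortholog pair with its provenance."""

    gene1: str
    gene2: str
    provenance: str  # "seed" or "propagated"


@dataclass
class OrthologSet:
    """An anchor gene together with its ortholog in each companion genome."""

    anchor: str
    members: dict[str, str] = field(default_factory=dict)  # genome -> gene id

    @property
    def size(self) -> int:
        return 1 + len(self.members)


def filter_hits(
    hits: Iterable[HomologyHit], e_max: float, pid_min: float
) -> list[HomologyHit]:
    """Keep hits with E-value <= ``e_max`` and identity >= ``pid_min``."""
    if e_max <= 0 or pid_min <= 0:
        raise ValueError("thresholds must be positive")
    return [h for h in hits if h.e_value <= e_max and h.pid >= pid_min]


def _runs_of_adjacent_homologs(
    genes: Sequence[Gene], hit_keys: set[tuple[str, str]]
) -> list[list[Gene]]:
    """Maximal runs of consecutive genes where each neighbor pair is homologous."""
    runs: list[list[Gene]] = []
    current: list[Gene] = []
    for gene in genes:
        if (
            current
            and gene.position == current[-1].position + 1
            and tuple(sorted((current[-1].id, gene.id))) in hit_keys
        ):
            current.append(gene)
        else:
            if len(current) > 1:
                runs.append(current)
            current = [gene]
    if len(current) > 1:
        runs.append(current)
    return runs


def collapse_tandem(
    genes: Iterable[Gene], hits: Iterable[HomologyHit]
) -> tuple[list[Gene], list[HomologyHit]]:
    """Merge tandem duplicates into single loci and re-express hits.

    Maximal runs of immediately adjacent, pairwise-homologous neighbors on
    one chromosome collapse to a locus represented by the lowest-position
    member; positions are renumbered contiguously and hits are aggregated at
    the locus level (min E-value, max identity, min Ks).
    """
    hits = list(hits)
    hit_keys = {h.key for h in hits}
    representative: dict[str, str] = {}
    by_chrom: dict[tuple[str, str], list[Gene]] = {}
    for gene in genes:
        by_chrom.setdefault((gene.genome, gene.chromosome), []).append(gene)

    loci: list[Gene] = []
    for (_genome, _chrom), chrom_genes in sorted(by_chrom.items()):
        chrom_genes.sort(key=lambda g: g.position)
        in_run: set[str] = set()
        for run in _runs_of_adjacent_homologs(chrom_genes, hit_keys):
            rep = run[0]  # lowest position
            for member in run:
                representative[member.id] = rep.id
                in_run.add(member.id)
        kept = [
            g
            for g in chrom_genes
            if g.id not in in_run or representative[g.id] == g.id
        ]
        for new_pos, gene in enumerate(kept):
            loci.append(replace(gene, position=new_pos))

    merged: dict[tuple[str, str], HomologyHit] = {}
    for hit in hits:
        g1 = representative.get(hit.gene1, hit.gene1)
        g2 = representative.get(hit.gene2, hit.gene2)
        if g1 == g2:
            continue  # intra-locus homology disappears
        key = tuple(sorted((g1, g2)))
        prev = merged.get(key)
        if prev is None:
            merged[key] = HomologyHit(g1, g2, hit.e_value, hit.pid, hit.ks)
        else:
            ks_vals = [v for v in (prev.ks, hit.ks) if v is not None]
            merged[key] = HomologyHit(
                g1,
                g2,
                min(prev.e_value, hit.e_value),
                max(prev.pid, hit.pid),
                min(ks_vals) if ks_vals else None,
            )
    return loci, sorted(merged.values(), key=lambda h: h.key)


def _cross_genome_neighbors(
    hits: Iterable[HomologyHit], genome_of: Mapping[str, str]
) -> dict[str, set[str]]:
    """gene id -> set of cross-genome homologs."""
    adj: dict[str, set[str]] = {}
    for hit in hits:
        if genome_of[hit.gene1] == genome_of[hit.gene2]:
            continue
        adj.setdefault(hit.gene1, set()).add(hit.gene2)
        adj.setdefault(hit.gene2, set()).add(hit.gene1)
    return adj


def seed_one_to_one(
    hits: Iterable[HomologyHit],
    genome_of: Mapping[str, str],
    ks_max: float | None = None,
    assigned: set[str] | None = None,
    provenance: str = "seed",
) -> list[OrthologPair]:
    """Unique reciprocal cross-genome hits, optionally Ks-limited.

    A pair (A, B) is seeded iff B is A's only cross-genome homolog and vice
    versa; with ``ks_max`` given, pairs lacking a Ks value are skipped with a
    warning.  Genes in ``assigned`` are excluded.
    """
    assigned = assigned or set()
    hit_by_key = {h.key: h for h in hits}
    adj = _cross_genome_neighbors(hit_by_key.values(), genome_of)
    pairs: list[OrthologPair] = []
    for g1 in sorted(adj):
        if g1 in assigned or len(adj[g1]) != 1:
            continue
        (g2,) = adj[g1]
        if g2 < g1 or g2 in assigned or len(adj[g2]) != 1:
            continue
        if ks_max is not None:
            hit = hit_by_key[tuple(sorted((g1, g2)))]
            if hit.ks is None:
                logger.warning("hit %s-%s lacks Ks; skipped in seeding", g1, g2)
                continue
            if hit.ks >= ks_max:
                continue
        pairs.append(OrthologPair(g1, g2, provenance))
    return pairs


def _neighbors_of(gene: Gene, order: Mapping[tuple[str, str, int], Gene]) -> list[Gene]:
    """Immediate left/right neighbors on the same chromosome (ends have one)."""
    out = []
    for delta in (-1, 1):
        n = order.get((gene.genome, gene.chromosome, gene.position + delta))
        if n is not None:
            out.append(n)
    return out


def propagate_neighbors(
    pairs: Sequence[OrthologPair],
    hits: Iterable[HomologyHit],
    genes: Iterable[Gene],
) -> tuple[list[OrthologPair], list[HomologyHit], bool]:
    """Iterate neighbor propagation and Ks-free re-seeding to convergence.

    Anchors are scanned in ascending (chromosome, position) order of their
    first-genome gene; when the neighbors of an anchor pair are homologous
    and both unassigned they become an ortholog pair and every other
    homology edge touching them is deleted.  Conflicting proposals in one
    sweep are resolved first-come.  Returns the full pair list (input pairs
    included), the pruned hit table and a convergence flag (always True on
    return; exposed for audit).
    """
    gene_list = list(genes)
    gene_by_id = {g.id: g for g in gene_list}
    genome_of = {g.id: g.genome for g in gene_list}
    order = {(g.genome, g.chromosome, g.position): g for g in gene_list}
    hit_by_key: dict[tuple[str, str], HomologyHit] = {h.key: h for h in hits}

    all_pairs: list[OrthologPair] = list(pairs)
    assigned: set[str] = {g for p in all_pairs for g in (p.gene1, p.gene2)}
    accepted_edges: set[tuple[str, str]] = {
        tuple(sorted((p.gene1, p.gene2))) for p in all_pairs
    }

    def delete_other_edges(gene_id: str) -> None:
        for key in [k for k in hit_by_key if gene_id in k]:
            if key not in accepted_edges:
                del hit_by_key[key]

    changed = True
    while changed:
        changed = False
        # deterministic anchor scan order
        anchor_order = sorted(
            all_pairs,
            key=lambda p: (
                gene_by_id[p.gene1].chromosome,
                gene_by_id[p.gene1].position,
                p.gene1,
            ),
        )
        for pair in anchor_order:
            a, b = gene_by_id[pair.gene1], gene_by_id[pair.gene2]
            for c in _neighbors_of(a, order):
                for d in _neighbors_of(b, order):
                    if c.id in assigned or d.id in assigned:
                        continue
                    key = tuple(sorted((c.id, d.id)))
                    if key not in hit_by_key:
                        continue
                    if genome_of[c.id] == genome_of[d.id]:
                        continue
                    all_pairs.append(OrthologPair(c.id, d.id, "propagated"))
                    assigned.update((c.id, d.id))
                    accepted_edges.add(key)
                    delete_other_edges(c.id)
                    delete_other_edges(d.id)
                    changed = True
        # re-seed one-to-one pairs without the Ks criterion
        new_seeds = seed_one_to_one(
            hit_by_key.values(), genome_of, ks_max=None, assigned=assigned,
            provenance="propagated",
        )
        for p in new_seeds:
            all_pairs.append(p)
            assigned.update((p.gene1, p.gene2))
            accepted_edges.add(tuple(sorted((p.gene1, p.gene2))))
            changed = True
    return all_pairs, sorted(hit_by_key.values(), key=lambda h: h.key), True


def find_orthologs(
    genes: Iterable[Gene],
    hits: Iterable[HomologyHit],
    e_max: float,
    pid_min: float,
    ks_max: float | None,
) -> list[OrthologPair]:
    """Full pairwise pipeline: filter, collapse tandems, seed, propagate."""
    kept = filter_hits(hits, e_max, pid_min)
    loci, locus_hits = collapse_tandem(genes, kept)
    genome_of = {g.id: g.genome for g in loci}
    seeds = seed_one_to_one(locus_hits, genome_of, ks_max=ks_max)
    pairs, _pruned, _ = propagate_neighbors(seeds, locus_hits, loci)
    return pairs


def assemble_sets(
    pairwise: Mapping[str, Sequence[OrthologPair]],
    anchor_genome: str,
    genome_of: Mapping[str, str],
    min_others: int = 5,
) -> list[OrthologSet]:
    """Join pairwise results on the anchor gene into multi-genome sets.

    ``pairwise`` maps each companion genome to its ortholog pairs against the
    anchor genome; anchor genes with orthologs in fewer than ``min_others``
    companion genomes are excluded (sets therefore have 6-8 members when
    seven companions are used with the default).
    """
    by_anchor: dict[str, dict[str, str]] = {}
    for genome, pairs in pairwise.items():
        for p in pairs:
            if genome_of[p.gene1] == anchor_genome:
                anchor, other = p.gene1, p.gene2
            elif genome_of[p.gene2] == anchor_genome:
                anchor, other = p.gene2, p.gene1
            else:
                continue
            by_anchor.setdefault(anchor, {})[genome] = other
    return [
        OrthologSet(anchor, members)
        for anchor, members in sorted(by_anchor.items())
        if len(members) >= min_others
    ]


# --- TSV interfaces ----------------------------------------------------------

def read_gene_order(path) -> list[Gene]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, comment="#")
    return [
        Gene(r.gene_id, r.genome, str(r.chromosome), int(r.position))
        for r in df.itertuples()
    ]


def read_hits(path) -> list[HomologyHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        HomologyHit(
            r.gene1,
            r.gene2,
            float(r.e_value),
            float(r.pid),
            None if pd.isna(r.ks) else float(r.ks),
        )
        for r in df.itertuples()
    ]


def write_pairs(pairs: Sequence[OrthologPair], path) -> None:
    pd.DataFrame(
        [(p.gene1, p.gene2, p.provenance) for p in pairs],
        columns=["gene1", "gene2", "provenance"],
    ).to_csv(path, sep="\t", index=False)


def write_sets(sets: Sequence[OrthologSet], path) -> None:
    rows = []
    for s in sets:
        for genome, gene in sorted(s.members.items()):
            rows.append((s.anchor, genome, gene, s.size))
    pd.DataFrame(rows, columns=["anchor", "genome", "ortholog", "set_size"]).to_csv(
        path, sep="\t", index=False
    )
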