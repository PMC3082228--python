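"""Codon-level machinery shared by the simulator and the counting estimator.

Provides the standard genetic code restricted to sense codons, Nei–Gojobori
site counts (synonymous / nonsynonymous sites per codon), pathway-averaged
difference tables for all codon pairs, and a Goldman–Yang-style 61-state
rate matrix with equal codon frequencies.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
#: The 61 sense codons of the standard code, lexicographic order.
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = dict(standard_dna_table.forward_table)

N_CODONS = len(SENSE_CODONS)  # 61


def _is_synonymous(c1: str, c2: str) -> bool:
    return AMINO_ACID[c1] == AMINO_ACID[c2]


def _single_nt_variants(codon: str):
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, codon[:pos] + nt + codon[pos + 1 :]


@lru_cache(maxsize=1)
def site_counts() -> tuple[np.ndarray, np.ndarray]:
    """Per-codon synonymous and nonsynonymous site counts (NG86).

    Each codon position contributes its fraction of synonymous
    single-nucleotide changes; changes to stop codons count as
    nonsynonymous.  s + n = 3 for every codon.
    """
    s = np.zeros(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        syn = sum(
            1
            for _, v in _single_nt_variants(codon)
            if v not in STOP_CODONS and _is_synonymous(codon, v)
        )
        s[i] = syn / 3.0
    return s, 3.0 - s


def _diff_positions(c1: str, c2: str) -> list[int]:
    return [k for k in range(3) if c1[k] != c2[k]]


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    All orders of the single-site substitutions are weighted equally;
    pathways passing through a stop codon are excluded unless every
    pathway does (then steps into/out of stops count as nonsynonymous).
    """
    positions = _diff_positions(c1, c2)
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            syn = (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and _is_synonymous(cur, nxt)
            )
            steps.append(syn)
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = float(np.mean([sum(steps) for steps in usable]))
    return sd, len(positions) - sd


@lru_cache(maxsize=1)
def pathway_tables() -> tuple[np.ndarray, np.ndarray]:
    """61x61 tables of pathway-averaged synonymous/nonsynonymous differences."""
    sd = np.zeros((N_CODONS, N_CODONS))
    nd = np.zeros((N_CODONS, N_CODONS))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i < j:
                s, n = _pathway_counts(c1, c2)
                sd[i, j] = sd[j, i] = s
                nd[i, j] = nd[j, i] = n
    return sd, nd


def rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """GY-style 61-state rate matrix, equal codon frequencies.

    Entries for single-nucleotide codon changes are proportional to
    kappa for transitions and omega for nonsynonymous changes; the
    matrix is scaled so one unit of branch length equals one expected
    substitution per codon.
    """
    q = np.zeros((N_CODONS, N_CODONS))
    for i, c1 in enumerate(SENSE_CODONS):
        for _, c2 in _single_nt_variants(c1):
            if c2 in STOP_CODONS:
                continue
            j = CODON_INDEX[c2]
            pos = _diff_positions(c1, c2)[0]
            rate = 1.0
            if (c1[pos], c2[pos]) in TRANSITIONS:
                rate *= kappa
            if not _is_synonymous(c1, c2):
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -np.mean(np.diag(q))
    if mean_rate > 0:
        q /= mean_rate
    return q


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon; '*' for stops, 'X' if ambiguous."""
    if codon in STOP_CODONS:
        return "*"
    return AMINO_ACID.get(codon, "X")
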